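"""PWM scanning of nucleotide sequences and the binary binding matrix.

Every window of a sequence (both strands by default) is scored by summed
per-position log2(frequency/background); a window is reported as a hit when
its score, rescaled to the fraction of the attainable score range
(``rel_score``), reaches the threshold.  Hits are reported in forward-strand
coordinates, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import BASE_INDEX, Motif

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = -2
_ENCODE[ord("n")] = -2


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence on one sequence.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``score`` is the log-odds sum in bits and ``rel_score`` its position in
    the [min, max] attainable score range.
    """

    seq_id: str
    tf_name: str
    start: int
    end: int
    strand: str
    score: float
    rel_score: float


@dataclass
class BindingMatrix:
    """Binary sequences x TFs presence table (the rule-mining transactions)."""

    seq_ids: list[str]
    tf_names: list[str]
    values: np.ndarray  # (n_seqs, n_tfs) of 0/1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.seq_ids, columns=self.tf_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingMatrix":
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binding matrix cells must be 0/1")
        return cls(list(df.index), list(df.columns), values.astype(np.int8))


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and N to -2; any other character is an error."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -1).any():
        bad = seq[int(np.argmax(arr == -1))]
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return arr


def scan_sequence(
    seq: str,
    motif: Motif,
    min_rel_score: float = 0.8,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """Score every window of ``seq`` against ``motif`` and return hits.

    Windows containing N are skipped.  A motif wider than the sequence
    yields an empty list.  Hits are sorted by start (then strand).
    """
    if not 0.0 <= min_rel_score <= 1.0:
        raise ValueError("min_rel_score must be in [0, 1]")
    encoded = encode_sequence(seq)
    w = motif.width
    if w > len(encoded):
        return []

    lo = motif.log_odds
    score_min, score_max = motif.min_score, motif.max_score
    span = score_max - score_min

    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    pos = np.arange(w)

    hits: list[MotifHit] = []

    def collect(matrix: np.ndarray, strand: str) -> None:
        scores = matrix[pos[None, :], safe].sum(axis=1)
        rel = (scores - score_min) / span if span > 0 else np.ones_like(scores)
        keep = np.flatnonzero(valid & (rel >= min_rel_score - 1e-12))
        for i in keep:
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    tf_name=motif.tf_name,
                    start=int(i),
                    end=int(i) + w,
                    strand=strand,
                    score=float(scores[i]),
                    rel_score=float(min(max(rel[i], 0.0), 1.0)),
                )
            )

    collect(lo, "+")
    if both_strands:
        collect(motif.reverse_complement_log_odds(), "-")
    hits.sort(key=lambda h: (h.start, h.strand, h.tf_name))
    return hits


def scan_fasta(
    fasta_path,
    motifs: list[Motif],
    min_rel_score: float = 0.8,
    both_strands: bool = True,
) -> tuple[list[MotifHit], list[str]]:
    """Scan every record of a FASTA file with every motif.

    Returns (all hits, ordered sequence ids).
    """
    all_hits: list[MotifHit] = []
    seq_ids: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq_ids.append(rec.id)
        seq = str(rec.seq).upper()
        for motif in motifs:
            all_hits.extend(
                scan_sequence(seq, motif, min_rel_score, both_strands, seq_id=rec.id)
            )
    return all_hits, seq_ids


def build_binding_matrix(
    hits: list[MotifHit], seq_ids: list[str], tf_names: list[str]
) -> BindingMatrix:
    """Collapse hits to a binary presence matrix in the given row/column order."""
    row = {s: i for i, s in enumerate(seq_ids)}
    col = {t: j for j, t in enumerate(tf_names)}
    values = np.zeros((len(seq_ids), len(tf_names)), dtype=np.int8)
    for h in hits:
        if h.seq_id not in row:
            raise KeyError(f"hit references unknown sequence id {h.seq_id!r}")
        if h.tf_name not in col:
            raise KeyError(f"hit references unknown TF {h.tf_name!r}")
        values[row[h.seq_id], col[h.tf_name]] = 1
    return BindingMatrix(list(seq_ids), list(tf_names), values)


# ---------------------------------------------------------------------------
# interchange

HITS_COLUMNS = ["seq_id", "tf_name", "start", "end", "strand", "score", "rel_score"]


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HITS_COLUMNS)


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [MotifHit(**{c: row[c] for c in HITS_COLUMNS}) for _, row in df.iterrows()]


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """BED6 with the score column as rel_score x 1000, integer-truncated to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(round(h.rel_score * 1000))
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.tf_name}\t{score}\t{h.strand}\n")


def write_matrix_tsv(matrix: BindingMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="seq_id")


def read_matrix_tsv(path) -> BindingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BindingMatrix.from_frame(df)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
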