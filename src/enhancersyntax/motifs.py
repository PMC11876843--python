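"""Binding-motif models and parsers.

A :class:`Motif` holds a position count matrix for one transcription factor
together with the pseudocount and background needed to turn it into a
log-odds position weight matrix (PWM).  Parsing of the two common public
matrix dialects (JASPAR 2022 ``>ID NAME`` blocks and TRANSFAC ``PO`` tables)
is delegated to :mod:`Bio.motifs`; scoring is done here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Default pseudocount, split across bases proportionally to the background.
DEFAULT_PSEUDOCOUNT = 0.8
#: Default uniform background base composition.
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif file does not parse in the declared dialect."""


@dataclass
class Motif:
    """Position count matrix for one TF plus scoring parameters.

    Parameters
    ----------
    tf_name:
        Transcription-factor label (upper-cased on construction).
    motif_id:
        Identifier of the source record (e.g. a JASPAR matrix id).
    counts:
        ``(width, 4)`` array of nonnegative base counts in A, C, G, T order.
    pseudocount:
        Total pseudocount added per position, split across bases in
        proportion to ``background``.
    background:
        Background base probabilities in A, C, G, T order; must sum to 1.
    """

    tf_name: str
    motif_id: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        self.tf_name = self.tf_name.upper()
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(
                f"motif {self.motif_id}: counts must be positions x 4, "
                f"got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError(
                f"motif {self.motif_id}: position with all-zero counts"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-position base frequencies after pseudocount smoothing.

        Each row sums to 1: ``(counts + pc*bg) / (rowsum + pc)``.
        """
        bg = np.asarray(self.background)
        smoothed = self.counts + self.pseudocount * bg[None, :]
        return smoothed / smoothed.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """``(width, 4)`` log2(freq / background) scoring matrix, in bits."""
        return np.log2(self.frequencies / np.asarray(self.background)[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Highest-count base at each position (ties broken A<C<G<T)."""
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))

    def reverse_complement_log_odds(self) -> np.ndarray:
        """Log-odds matrix for scoring the reverse strand on forward coordinates."""
        return self.log_odds[::-1, ::-1]


def load_motifs(path, fmt: str = "jaspar") -> list[Motif]:
    """Parse a JASPAR- or TRANSFAC-format motif file into :class:`Motif` objects.

    TF names are upper-cased; counts preserved exactly.  Raises
    :class:`MotifParseError` on malformed records and on duplicate motif ids.
    An empty file yields an empty list (with a warning logged).
    """
    if fmt not in ("jaspar", "transfac"):
        raise ValueError(f"unknown motif format: {fmt!r}")
    try:
        with open(path) as handle:
            records = list(bio_motifs.parse(handle, fmt.upper() if fmt == "transfac" else fmt))
    except MotifParseError:
        raise
    except Exception as exc:  # biopython raises bare ValueError/KeyError
        raise MotifParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    out: list[Motif] = []
    seen: set[str] = set()
    for rec in records:
        motif_id = getattr(rec, "matrix_id", None) or rec.get("AC", None) or rec.name
        name = rec.name or motif_id
        if motif_id in seen:
            raise MotifParseError(f"duplicate motif id {motif_id!r} in {path}")
        seen.add(motif_id)
        counts = np.column_stack([rec.counts[b] for b in ALPHABET])
        try:
            out.append(Motif(tf_name=name, motif_id=str(motif_id), counts=counts))
        except ValueError as exc:
            raise MotifParseError(f"record {motif_id!r}: {exc}") from exc
    if not out:
        log.warning("no motif records found in %s", path)
    return out


def write_jaspar(motifs: list[Motif], path) -> None:
    """Write motifs as JASPAR 2022 count blocks (``>ID NAME`` + 4 labeled rows)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for j, base in enumerate(ALPHABET):
                row = " ".join(f"{int(c) if float(c).is_integer() else c:>5}" for c in m.counts[:, j])
                fh.write(f"{base} [ {row} ]\n")
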