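"""Ordered-triad search over a genome-wide CRM catalog.

A CRM (cis-regulatory module) catalog arrives as BED4 intervals plus either
embedded sequences or a genome FASTA to slice them from.  Each CRM is
scanned with the three triad motifs and matched when a centre-TF site lies
strictly between a left-TF site and a right-TF site; the mirror orientation
(the same pattern read off the other strand) is accepted by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from pyfaidx import Fasta

from .motifs import Motif
from .scan import MotifHit, scan_sequence
from .syntax import find_adjacent_triads, ordered_sites


@dataclass(frozen=True)
class CRM:
    crm_id: str
    chrom: str
    start: int
    end: int
    sequence: str | None = None
    assembly: str = "hg19"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.crm_id}: start must be < end")


@dataclass(frozen=True)
class TriadQuery:
    """Ordered pattern left-centre-right, optionally mirrored/constrained."""

    left_tf: str
    center_tf: str
    right_tf: str
    require_adjacency: bool = False
    max_gap: int | None = None
    allow_mirror: bool = True

    def __post_init__(self):
        if len({self.left_tf, self.center_tf, self.right_tf}) != 3:
            raise ValueError("triad query needs three distinct TF names")
        if self.max_gap is not None and self.max_gap <= 0:
            raise ValueError("max_gap must be positive when set")

    @property
    def tfs(self) -> frozenset:
        return frozenset((self.left_tf, self.center_tf, self.right_tf))


@dataclass(frozen=True)
class TriadMatch:
    crm_id: str
    left: MotifHit
    center: MotifHit
    right: MotifHit

    @property
    def span(self) -> int:
        return self.right.end - self.left.start

    @property
    def order(self) -> tuple[str, str, str]:
        return (self.left.tf_name, self.center.tf_name, self.right.tf_name)


def read_catalog_bed(path, assembly: str = "hg19") -> list[CRM]:
    """BED4 catalog reader (chrom, start, end, crm_id); rejects duplicate ids."""
    crms: list[CRM] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 needs 4 columns")
            chrom, start, end, crm_id = fields[:4]
            if crm_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate crm_id {crm_id!r}")
            seen.add(crm_id)
            crms.append(CRM(crm_id, chrom, int(start), int(end), assembly=assembly))
    return crms


def extract_sequences(catalog: list[CRM], genome_fasta) -> list[CRM]:
    """Attach upper-cased half-open genome slices to each CRM."""
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    out = []
    for crm in catalog:
        if crm.chrom not in genome:
            raise KeyError(f"{crm.crm_id}: contig {crm.chrom!r} not in genome")
        contig = genome[crm.chrom]
        if crm.end > len(contig):
            raise ValueError(
                f"{crm.crm_id}: interval end {crm.end} beyond contig length {len(contig)}"
            )
        out.append(replace(crm, sequence=str(contig[crm.start : crm.end])))
    return out


def _ordered_matches(
    crm_id: str,
    left_hits: list[MotifHit],
    center_hits: list[MotifHit],
    right_hits: list[MotifHit],
    max_gap: int | None,
) -> list[TriadMatch]:
    """All (left, center, right) site triples in strict genomic order."""
    out = []
    for c in center_hits:
        for l in left_hits:
            if not l.start < c.start:
                continue
            if max_gap is not None and c.start - l.end > max_gap:
                continue
            for r in right_hits:
                if not c.start < r.start:
                    continue
                if max_gap is not None and r.start - c.end > max_gap:
                    continue
                out.append(TriadMatch(crm_id, l, c, r))
    return out


def scan_catalog(
    catalog: list[CRM],
    motifs: list[Motif],
    query: TriadQuery,
    min_rel_score: float = 0.8,
    both_strands: bool = True,
) -> list[TriadMatch]:
    """Matched CRMs, one best (smallest-span) match each, sorted by crm_id.

    ``require_adjacency`` restricts to triples with no intervening site of
    any of the three TFs; ``allow_mirror`` also accepts right-centre-left.
    """
    by_tf = {tf: None for tf in query.tfs}
    motif_map = {m.tf_name: m for m in motifs}
    missing = [tf for tf in by_tf if tf not in motif_map]
    if missing:
        raise KeyError(f"no motif supplied for TFs: {missing}")

    matches: list[TriadMatch] = []
    for crm in catalog:
        if crm.sequence is None:
            raise ValueError(
                f"{crm.crm_id}: CRM carries no sequence and no genome was provided"
            )
        hits: dict[str, list[MotifHit]] = {}
        for tf in query.tfs:
            hits[tf] = scan_sequence(
                crm.sequence, motif_map[tf], min_rel_score, both_strands, seq_id=crm.crm_id
            )
        orientations = [(query.left_tf, query.right_tf)]
        if query.allow_mirror:
            orientations.append((query.right_tf, query.left_tf))

        candidates: list[TriadMatch] = []
        if query.require_adjacency:
            sites = ordered_sites(
                hits[query.left_tf] + hits[query.center_tf] + hits[query.right_tf]
            )
            for occ in find_adjacent_triads(sites, set(query.tfs)):
                if occ.center.tf_name != query.center_tf:
                    continue
                if (occ.left.tf_name, occ.right.tf_name) not in orientations:
                    continue
                if query.max_gap is not None and (
                    occ.left_gap > query.max_gap or occ.right_gap > query.max_gap
                ):
                    continue
                candidates.append(TriadMatch(crm.crm_id, occ.left, occ.center, occ.right))
        else:
            for left_tf, right_tf in orientations:
                candidates.extend(
                    _ordered_matches(
                        crm.crm_id, hits[left_tf], hits[query.center_tf],
                        hits[right_tf], query.max_gap,
                    )
                )
        if candidates:
            matches.append(min(candidates, key=lambda m: (m.span, m.left.start)))
    matches.sort(key=lambda m: m.crm_id)
    return matches


def matches_to_frame(matches: list[TriadMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "crm_id": m.crm_id,
                "order": "-".join(m.order),
                "left_start": m.left.start, "left_end": m.left.end,
                "center_start": m.center.start, "center_end": m.center.end,
                "right_start": m.right.start, "right_end": m.right.end,
                "span": m.span,
            }
            for m in matches
        ],
        columns=[
            "crm_id", "order", "left_start", "left_end", "center_start",
            "center_end", "right_start", "right_end", "span",
        ],
    )


def write_matched_bed(matches: list[TriadMatch], catalog: list[CRM], path) -> None:
    """BED4 of the matched CRM subset (original genomic coordinates)."""
    by_id = {c.crm_id: c for c in catalog}
    with open(path, "w") as fh:
        for m in matches:
            c = by_id[m.crm_id]
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.crm_id}\n")
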