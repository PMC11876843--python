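"""Interval intersection of CRMs with epigenomic/validation tracks.

Reimplements the one-basepair-overlap intersection convention of standard
BED tooling over half-open coordinates, builds a binary CRM x track feature
matrix, and shortlists a core CRM set by feature-class membership.
Chromosome names are normalized ("chr1" and "1" match).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class IntervalTrack:
    name: str
    intervals: list[tuple[str, int, int, str | None]]
    source: str = ""

    def __post_init__(self):
        for chrom, start, end, _ in self.intervals:
            if start >= end:
                raise ValueError(f"track {self.name}: interval {chrom}:{start}-{end} empty")


@dataclass(frozen=True)
class OverlapRecord:
    crm_id: str
    track: str
    interval_id: str | None
    overlap_bp: int


@dataclass
class FeatureMatrix:
    """Binary CRM x track overlap indicators plus per-cell detail."""

    frame: pd.DataFrame  # crm_ids x track names, 0/1
    detail: dict[tuple[str, str], list[OverlapRecord]] = field(default_factory=dict)

    @property
    def crm_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def track_names(self) -> list[str]:
        return list(self.frame.columns)


def read_bed_track(path, name: str, source: str = "") -> IntervalTrack:
    """BED3/4/6 reader; comment/track lines ignored; errors carry line numbers."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            iv_id = fields[3] if len(fields) > 3 else None
            intervals.append((chrom, start, end, iv_id))
    return IntervalTrack(name, intervals, source)


def intersect(crms, track: IntervalTrack) -> list[OverlapRecord]:
    """All (CRM, interval) pairs overlapping by >= 1 bp, with overlap length."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, (chrom, start, end, iv_id) in enumerate(track.intervals):
        trees[normalize_chrom(chrom)].addi(start, end, iv_id if iv_id is not None else str(idx))
    out = []
    for crm in crms:
        tree = trees.get(normalize_chrom(crm.chrom))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(crm.start, crm.end)):
            bp = min(crm.end, iv.end) - max(crm.start, iv.begin)
            out.append(OverlapRecord(crm.crm_id, track.name, iv.data, bp))
    return out


def build_feature_matrix(crms, tracks: list[IntervalTrack]) -> FeatureMatrix:
    if not tracks:
        raise ValueError("at least one track required")
    crm_ids = [c.crm_id for c in crms]
    frame = pd.DataFrame(0, index=crm_ids, columns=[t.name for t in tracks], dtype=np.int8)
    detail: dict[tuple[str, str], list[OverlapRecord]] = defaultdict(list)
    for track in tracks:
        for rec in intersect(crms, track):
            frame.loc[rec.crm_id, track.name] = 1
            detail[(rec.crm_id, track.name)].append(rec)
    return FeatureMatrix(frame, dict(detail))


def collapse_classes(matrix: FeatureMatrix, class_map: dict[str, list[str]]) -> FeatureMatrix:
    """Union per-track columns into feature-class indicator columns.

    ``class_map`` maps class name -> member track names (e.g. three histone
    marks into one "histone" class).  Per-cell detail is not carried over.
    """
    cols = {}
    for cls, members in class_map.items():
        missing = [m for m in members if m not in matrix.frame.columns]
        if missing:
            raise KeyError(f"unknown tracks in class {cls!r}: {missing}")
        cols[cls] = matrix.frame[members].max(axis=1)
    return FeatureMatrix(pd.DataFrame(cols, index=matrix.frame.index))


def core_set(
    matrix: FeatureMatrix,
    required: list[str],
    mode: str = "k_of",
    k: int = 3,
) -> list[str]:
    """CRMs covered by all required tracks (``all_of``) or >= k of them (``k_of``)."""
    unknown = [t for t in required if t not in matrix.frame.columns]
    if unknown:
        raise KeyError(f"unknown track names: {unknown}")
    sub = matrix.frame[required]
    if mode == "all_of":
        keep = sub.sum(axis=1) == len(required)
    elif mode == "k_of":
        keep = sub.sum(axis=1) >= k
    else:
        raise ValueError(f"unknown core-set mode {mode!r}")
    return sorted(sub.index[keep])


def snp_overlap(crms, snps: list[tuple[str, str, int]]) -> list[tuple[str, str]]:
    """(crm_id, rsID) pairs for point SNPs falling inside CRMs.

    SNPs are (rsID, chrom, pos) with pos treated as a 1 bp half-open
    interval [pos, pos+1); a SNP at a CRM start is inside, at its end
    coordinate it is not.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for crm in crms:
        trees[normalize_chrom(crm.chrom)].addi(crm.start, crm.end, crm.crm_id)
    out = []
    for rsid, chrom, pos in snps:
        tree = trees.get(normalize_chrom(chrom))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(pos, pos + 1)):
            out.append((iv.data, rsid))
    return sorted(out)


def read_snps_tsv(path) -> list[tuple[str, str, int]]:
    """Two-column (rsID, chrom:pos) TSV; pos is 0-based."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rsid, loc = line.split("\t")
                chrom, pos = loc.rsplit(":", 1)
                out.append((rsid, chrom, int(pos)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad SNP line: {exc}") from exc
    return out
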