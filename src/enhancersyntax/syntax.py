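"""Motif-order grammar analysis: adjacent ordered triads, arrangement
frequencies, Fisher's exact arrangement tests and inter-site spacing.

An *adjacent triad* on a sequence is three consecutive sites in the ordered
site list (restricted to the analysis TF set) whose TFs are exactly the
three members of the triad — i.e. no intervening site of any analysed TF.
Spacing is measured edge-to-edge by default (gap between one site's end and
the next site's start); centre-to-centre is available behind a flag.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .scan import MotifHit


@dataclass(frozen=True)
class TriadOccurrence:
    """An adjacent, ordered site triple on one sequence."""

    seq_id: str
    left: MotifHit
    center: MotifHit
    right: MotifHit

    @property
    def left_gap(self) -> int:
        """bp between the left site's end and the centre site's start (>= 0)."""
        return max(0, self.center.start - self.left.end)

    @property
    def right_gap(self) -> int:
        return max(0, self.right.start - self.center.end)

    @property
    def order(self) -> tuple[str, str, str]:
        return (self.left.tf_name, self.center.tf_name, self.right.tf_name)


@dataclass
class ArrangementCounts:
    """Per-centre-TF sequence counts for one triad (one arrangement per sequence)."""

    triad: frozenset
    n_sequences: int
    per_center: dict[str, int]

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_sequences == 0:
            return {tf: 0.0 for tf in self.per_center}
        return {tf: c / self.n_sequences for tf, c in self.per_center.items()}


@dataclass
class SpacingSummary:
    pair: str
    n: int
    mean: float
    sd: float
    min_bp: int
    min_seq: str
    max_bp: int
    max_seq: str


def ordered_sites(hits: list[MotifHit], tf_set: set[str] | None = None) -> list[MotifHit]:
    """Sites of one sequence restricted to ``tf_set``, sorted by
    (start, end, tf_name).

    When several hits of the same TF share a start coordinate, only the
    highest-``rel_score`` one represents that site.
    """
    kept = [h for h in hits if tf_set is None or h.tf_name in tf_set]
    best: dict[tuple[int, str], MotifHit] = {}
    for h in kept:
        key = (h.start, h.tf_name)
        if key not in best or h.rel_score > best[key].rel_score:
            best[key] = h
    out = sorted(best.values(), key=lambda h: (h.start, h.end, h.tf_name))
    return out


def find_adjacent_triads(
    site_list: list[MotifHit], triad: set[str]
) -> list[TriadOccurrence]:
    """Consecutive site windows whose TFs are exactly the triad, one each."""
    triad = frozenset(triad)
    if len(triad) != 3:
        raise ValueError("triad must contain exactly three TF names")
    out = []
    for i in range(len(site_list) - 2):
        a, b, c = site_list[i : i + 3]
        if {a.tf_name, b.tf_name, c.tf_name} == triad:
            out.append(TriadOccurrence(a.seq_id, a, b, c))
    return out


def count_arrangements(
    occurrences_by_seq: dict[str, list[TriadOccurrence]], triad: set[str]
) -> ArrangementCounts:
    """One arrangement per sequence: the leftmost occurrence's centre TF.

    The study counts sequences, not occurrences, so a sequence carrying
    several differently-ordered triads contributes only its first (by
    coordinate).
    """
    triad = frozenset(triad)
    per_center = {tf: 0 for tf in sorted(triad)}
    n = 0
    for seq_id, occs in occurrences_by_seq.items():
        if not occs:
            continue
        first = min(occs, key=lambda o: (o.left.start, o.center.start, o.right.start))
        per_center[first.center.tf_name] += 1
        n += 1
    return ArrangementCounts(triad, n, per_center)


def group_occurrences(occurrences: list[TriadOccurrence]) -> dict[str, list[TriadOccurrence]]:
    grouped: dict[str, list[TriadOccurrence]] = defaultdict(list)
    for occ in occurrences:
        grouped[occ.seq_id].append(occ)
    return dict(grouped)


def fisher_arrangement_test(count_a: int, count_b: int, n: int) -> float:
    """Two-sided Fisher's exact p comparing two arrangement proportions.

    The 2x2 table is [[a, n-a], [b, n-b]]; two-sided by the standard
    minimum-likelihood rule (sum of hypergeometric outcomes no more probable
    than the observed table).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= count_a <= n and 0 <= count_b <= n):
        raise ValueError("counts must lie in [0, n]")
    table = [[count_a, n - count_a], [count_b, n - count_b]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def spacing_stats(
    occurrences: list[TriadOccurrence],
    center_to_center: bool = False,
    ddof: int = 1,
) -> list[SpacingSummary]:
    """Per adjacent-pair spacing summaries across occurrences.

    Pairs are labelled flank-centre (e.g. ``GATA3-FOXP2`` for the centre's
    right-hand neighbour GATA3).  ``ddof=1`` gives the sample standard
    deviation; ``ddof=0`` the population one.
    """
    gaps: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for occ in occurrences:
        if center_to_center:
            mid = lambda h: (h.start + h.end) // 2
            left_d = mid(occ.center) - mid(occ.left)
            right_d = mid(occ.right) - mid(occ.center)
        else:
            left_d, right_d = occ.left_gap, occ.right_gap
        gaps[f"{occ.left.tf_name}-{occ.center.tf_name}"].append((left_d, occ.seq_id))
        gaps[f"{occ.right.tf_name}-{occ.center.tf_name}"].append((right_d, occ.seq_id))

    out = []
    for pair in sorted(gaps):
        vals = np.array([g for g, _ in gaps[pair]], dtype=float)
        seqs = [s for _, s in gaps[pair]]
        i_min, i_max = int(vals.argmin()), int(vals.argmax())
        sd = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
        out.append(
            SpacingSummary(
                pair=pair,
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
                min_bp=int(vals[i_min]),
                min_seq=seqs[i_min],
                max_bp=int(vals[i_max]),
                max_seq=seqs[i_max],
            )
        )
    return out


def spacing_from_table(df: pd.DataFrame, ddof: int = 1) -> list[SpacingSummary]:
    """Spacing summaries from a distance table (columns: seq_id, pair, distance).

    This is the entry point for externally supplied per-pair distances, e.g.
    a supplementary spreadsheet exported as TSV.
    """
    out = []
    for pair, sub in df.groupby("pair"):
        vals = sub["distance"].to_numpy(dtype=float)
        seqs = sub["seq_id"].tolist()
        i_min, i_max = int(vals.argmin()), int(vals.argmax())
        sd = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
        out.append(
            SpacingSummary(
                pair=str(pair),
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
                min_bp=int(vals[i_min]),
                min_seq=seqs[i_min],
                max_bp=int(vals[i_max]),
                max_seq=seqs[i_max],
            )
        )
    return sorted(out, key=lambda s: s.pair)


def occurrences_to_frame(occurrences: list[TriadOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": o.seq_id,
                "order": "-".join(o.order),
                "left_start": o.left.start,
                "left_end": o.left.end,
                "center_start": o.center.start,
                "center_end": o.center.end,
                "right_start": o.right.start,
                "right_end": o.right.end,
                "left_gap": o.left_gap,
                "right_gap": o.right_gap,
            }
            for o in occurrences
        ],
        columns=[
            "seq_id", "order",
            "left_start", "left_end", "center_start", "center_end",
            "right_start", "right_end", "left_gap", "right_gap",
        ],
    )
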