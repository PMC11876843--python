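"""Per-CRM conservation means and clade-depth classification.

Conservation arrives as a per-base phastCons-style score track (values in
[0, 1]) in fixed-step text wiggle, or as a precomputed per-interval mean
table.  Mean scores are averaged over *covered* bases only — bases without
a score are excluded from both numerator and denominator, never
zero-filled.

Categories by mean score:

* primate            mean < 0.2
* mammalian          0.2 <= mean <= 0.5
* birds              0.5 <  mean <= 0.6
* amphibian_teleost  mean > 0.6

The first two cut-points follow the study's thresholds; the split of the
">0.5 non-mammalian" range into birds vs amphibians/teleosts follows its
finer sub-bins.  A three-category view (non_mammalian = birds +
amphibian_teleost) is derivable from the four-way one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("primate", "mammalian", "birds", "amphibian_teleost")


@dataclass
class ConservationRecord:
    crm_id: str
    mean_score: float | None
    category: str | None
    n_bases_covered: int


class WigTrack:
    """Per-base scores parsed from fixed-step text wiggle.

    Supports ``fixedStep chrom=.. start=.. step=.. [span=..]`` blocks with
    1-based starts (the wiggle convention); queries use 0-based half-open
    coordinates.
    """

    def __init__(self):
        self._blocks: dict[str, list[tuple[int, int, np.ndarray]]] = defaultdict(list)

    @classmethod
    def read(cls, path) -> "WigTrack":
        track = cls()
        chrom, pos, step, span = None, 0, 1, 1
        values: list[float] = []

        def flush():
            nonlocal values
            if chrom is not None and values:
                arr = np.array(values, dtype=float)
                if span == 1 and step == 1:
                    track._blocks[chrom].append((start0, step, arr))
                else:
                    # expand span/step>1 to per-base (small tracks only)
                    for i, v in enumerate(arr):
                        s = start0 + i * step
                        track._blocks[chrom].append((s, 1, np.full(span, v)))
            values = []

        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    flush()
                    kv = dict(f.split("=", 1) for f in line.split()[1:])
                    chrom = kv["chrom"]
                    start0 = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                elif chrom is None:
                    raise ValueError(f"{path}:{lineno}: data before fixedStep header")
                else:
                    values.append(float(line))
        flush()
        return track

    def add_block(self, chrom: str, start0: int, values: np.ndarray) -> None:
        self._blocks[chrom].append((start0, 1, np.asarray(values, dtype=float)))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._blocks):
                for start0, step, values in self._blocks[chrom]:
                    fh.write(f"fixedStep chrom={chrom} start={start0 + 1} step={step}\n")
                    for v in values:
                        fh.write(f"{v:.4f}\n")

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Covered per-base scores within [start, end), in base order."""
        out = np.full(end - start, np.nan)
        for b_start, step, values in self._blocks.get(chrom, ()):  # step==1 here
            b_end = b_start + len(values)
            lo, hi = max(start, b_start), min(end, b_end)
            if lo < hi:
                out[lo - start : hi - start] = values[lo - b_start : hi - b_start]
        return out[~np.isnan(out)]


def mean_score(chrom: str, start: int, end: int, track: WigTrack) -> tuple[float | None, int]:
    """Mean over covered bases; (None, 0) when nothing is covered."""
    vals = track.scores(chrom, start, end)
    if vals.size == 0:
        return None, 0
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("conservation scores must lie in [0, 1]")
    return float(vals.mean()), int(vals.size)


def classify(mean: float) -> str:
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"mean conservation score {mean} outside [0, 1]")
    if mean < 0.2:
        return "primate"
    if mean <= 0.5:
        return "mammalian"
    if mean <= 0.6:
        return "birds"
    return "amphibian_teleost"


def classify_catalog(crms, track: WigTrack) -> list[ConservationRecord]:
    """Mean + category per CRM from a per-base track."""
    out = []
    for crm in crms:
        mean, n = mean_score(crm.chrom, crm.start, crm.end, track)
        out.append(
            ConservationRecord(
                crm.crm_id, mean, classify(mean) if mean is not None else None, n
            )
        )
    return out


def records_from_table(df: pd.DataFrame) -> list[ConservationRecord]:
    """Records from a per-interval mean table (crm_id, chrom, start, end, mean_score)."""
    out = []
    for _, row in df.iterrows():
        mean = float(row["mean_score"])
        out.append(
            ConservationRecord(
                str(row["crm_id"]), mean, classify(mean),
                int(row["end"]) - int(row["start"]),
            )
        )
    return out


def summarize_catalog(records: list[ConservationRecord]) -> pd.DataFrame:
    """Per-category counts and computed fractions (uncategorized rows excluded)."""
    if not records:
        raise ValueError("no conservation records")
    counted = [r for r in records if r.category is not None]
    total = len(counted)
    rows = []
    for cat in CATEGORIES:
        n = sum(1 for r in counted if r.category == cat)
        rows.append({"category": cat, "count": n, "fraction": n / total if total else 0.0})
    return pd.DataFrame(rows)


def records_to_frame(records: list[ConservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "crm_id": r.crm_id,
                "mean_score": r.mean_score,
                "category": r.category,
                "n_bases_covered": r.n_bases_covered,
            }
            for r in records
        ]
    )
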