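"""Market-basket mining of TF co-occurrence.

Transactions are sequences, items are TF names, presence comes from the
binary binding matrix.  Frequent itemsets are found with a level-wise
Apriori search (exact supports, downward closure); association rules are
emitted for every antecedent/consequent split of every frequent itemset of
size >= 2 that clears the confidence threshold.

Metric definitions (for a rule A -> B over n transactions):

* support    = |A u B present| / n
* confidence = support(A u B) / support(A)
* lift       = confidence / support(B)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .scan import BindingMatrix


class NoMinimalCodeError(LookupError):
    """No association rule with the required number of distinct TFs exists."""


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    @property
    def n_items(self) -> int:
        return len(self.antecedent) + len(self.consequent)

    @property
    def items(self) -> frozenset:
        return self.antecedent | self.consequent

    def key(self) -> str:
        return "{%s}->{%s}" % (
            ",".join(sorted(self.antecedent)),
            ",".join(sorted(self.consequent)),
        )


@dataclass
class ItemsetTable:
    """Frequent itemsets with exact supports."""

    itemsets: list[tuple[frozenset, float]]
    min_support: float
    n_transactions: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {items: sup for items, sup in self.itemsets}

    def support_of(self, items: frozenset) -> float:
        return self._index[items]

    def __contains__(self, items: frozenset) -> bool:
        return items in self._index


def frequent_itemsets(matrix: BindingMatrix, min_support: float) -> ItemsetTable:
    """Level-wise Apriori enumeration of all itemsets with support >= threshold."""
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    n = len(matrix.seq_ids)
    if n == 0 or not matrix.tf_names:
        raise ValueError("empty binding matrix")

    cols = {tf: matrix.values[:, j].astype(bool) for j, tf in enumerate(matrix.tf_names)}
    found: list[tuple[frozenset, float]] = []
    # level 1
    level: dict[frozenset, np.ndarray] = {}
    for tf, v in cols.items():
        sup = v.sum() / n
        if sup >= min_support:
            level[frozenset([tf])] = v
            found.append((frozenset([tf]), sup))

    k = 1
    while level:
        # candidate generation: join sets sharing k-1 items, prune by closure
        keys = sorted(level, key=lambda s: tuple(sorted(s)))
        nxt: dict[frozenset, np.ndarray] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                cand = a | b
                if len(cand) != k + 1 or cand in nxt:
                    continue
                if any(cand - {item} not in level for item in cand):
                    continue
                v = level[a] & cols[next(iter(cand - a))]
                sup = v.sum() / n
                if sup >= min_support:
                    nxt[cand] = v
                    found.append((cand, sup))
        level = nxt
        k += 1

    found.sort(key=lambda t: (-t[1], len(t[0]), tuple(sorted(t[0]))))
    return ItemsetTable(found, min_support, n)


def derive_rules(
    itemsets: ItemsetTable, matrix: BindingMatrix, min_confidence: float
) -> list[AssociationRule]:
    """All antecedent/consequent splits of frequent itemsets passing confidence.

    Sorted by support desc, confidence desc, lift desc, then rule string.
    """
    if not 0.0 < min_confidence <= 1.0:
        raise ValueError("min_confidence must be in (0, 1]")
    rules: list[AssociationRule] = []
    for items, sup in itemsets.itemsets:
        if len(items) < 2:
            continue
        members = sorted(items)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                antecedent = frozenset(ante)
                consequent = items - antecedent
                confidence = sup / itemsets.support_of(antecedent)
                if confidence >= min_confidence - 1e-12:
                    lift = confidence / itemsets.support_of(consequent)
                    rules.append(
                        AssociationRule(antecedent, consequent, sup, confidence, lift)
                    )
    rules.sort(key=lambda r: (-r.support, -r.confidence, -r.lift, r.key()))
    return rules


def mine_rules(
    matrix: BindingMatrix, min_support: float = 0.1, min_confidence: float = 0.6
) -> list[AssociationRule]:
    """Convenience wrapper: itemsets then rules at the study's default thresholds."""
    return derive_rules(frequent_itemsets(matrix, min_support), matrix, min_confidence)


def select_minimal_code(
    rules: list[AssociationRule], min_items: int = 3
) -> AssociationRule:
    """The rule over >= ``min_items`` distinct TFs with the highest support,
    ties broken by confidence (then lift, then rule string)."""
    if not rules:
        raise ValueError("no rules supplied")
    eligible = [r for r in rules if r.n_items >= min_items]
    if not eligible:
        raise NoMinimalCodeError(
            f"no association rule involves >= {min_items} distinct TFs"
        )
    return min(eligible, key=lambda r: (-r.support, -r.confidence, -r.lift, r.key()))


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antecedent": ",".join(sorted(r.antecedent)),
                "consequent": ",".join(sorted(r.consequent)),
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "n_items": r.n_items,
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "lift", "n_items"],
    )


def write_rules_tsv(rules: list[AssociationRule], path) -> None:
    rules_to_frame(rules).to_csv(path, sep="\t", index=False)


def contrast_controls(
    pos_rules: list[AssociationRule], neg_rules: list[AssociationRule]
) -> pd.DataFrame:
    """Side-by-side rule table for a positive/negative dataset pair.

    Every rule seen in either list gets one row with both sets of metrics,
    metric deltas (positive minus negative, NaN where absent) and an
    ``exclusive_to_positive`` flag.
    """
    pos = {r.key(): r for r in pos_rules}
    neg = {r.key(): r for r in neg_rules}
    rows = []
    for key in sorted(set(pos) | set(neg)):
        p, q = pos.get(key), neg.get(key)
        ref = p or q
        rows.append(
            {
                "rule": key,
                "n_items": ref.n_items,
                "support_pos": p.support if p else np.nan,
                "confidence_pos": p.confidence if p else np.nan,
                "lift_pos": p.lift if p else np.nan,
                "support_neg": q.support if q else np.nan,
                "confidence_neg": q.confidence if q else np.nan,
                "lift_neg": q.lift if q else np.nan,
                "support_delta": (p.support - q.support) if p and q else np.nan,
                "confidence_delta": (p.confidence - q.confidence) if p and q else np.nan,
                "in_positive": p is not None,
                "in_negative": q is not None,
                "exclusive_to_positive": p is not None and q is None,
            }
        )
    return pd.DataFrame(rows)
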