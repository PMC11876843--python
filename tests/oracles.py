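"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (quadratic loops, exhaustive
enumeration, direct formulas) and shares no code with the package paths it
checks.
"""

from itertools import combinations
from math import comb

import numpy as np

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_log_odds(counts, pseudocount=0.8, background=(0.25, 0.25, 0.25, 0.25)):
    counts = np.asarray(counts, dtype=float)
    bg = np.asarray(background)
    freqs = (counts + pseudocount * bg) / (counts.sum(axis=1, keepdims=True) + pseudocount)
    return np.log2(freqs / bg)


def naive_scan(seq, counts, min_rel_score, both_strands=True,
               pseudocount=0.8, background=(0.25, 0.25, 0.25, 0.25)):
    """Score every window on both strands with plain Python loops.

    Returns a set of (start, end, strand, round(score, 9)).
    """
    lo = naive_log_odds(counts, pseudocount, background)
    w = lo.shape[0]
    smin = sum(min(row) for row in lo)
    smax = sum(max(row) for row in lo)
    out = set()

    def score_with(matrix, strand):
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            if "N" in window:
                continue
            s = sum(matrix[i][BASES.index(b)] for i, b in enumerate(window))
            rel = (s - smin) / (smax - smin)
            if rel >= min_rel_score - 1e-12:
                out.add((start, start + w, strand, round(s, 9)))

    score_with(lo, "+")
    if both_strands:
        score_with(lo[::-1, ::-1], "-")
    return out


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def brute_itemsets(matrix_values, items, min_support):
    """Exhaustive 2^k - 1 itemset enumeration with exact supports."""
    n = matrix_values.shape[0]
    out = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(range(len(items)), r):
            mask = np.ones(n, dtype=bool)
            for j in combo:
                mask &= matrix_values[:, j].astype(bool)
            sup = mask.sum() / n
            if sup >= min_support:
                out[frozenset(items[j] for j in combo)] = sup
    return out


def brute_rules(matrix_values, items, min_support, min_confidence):
    """All rules from exhaustively counted supports."""
    n = matrix_values.shape[0]

    def support(names):
        mask = np.ones(n, dtype=bool)
        for name in names:
            mask &= matrix_values[:, items.index(name)].astype(bool)
        return mask.sum() / n

    frequent = brute_itemsets(matrix_values, items, min_support)
    out = {}
    for itemset in frequent:
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                a = frozenset(ante)
                b = itemset - a
                conf = frequent[itemset] / support(a)
                if conf >= min_confidence - 1e-12:
                    out[(a, b)] = (frequent[itemset], conf, conf / support(b))
    return out


def fisher_two_sided(a, b, n):
    """Two-sided Fisher's exact p for [[a, n-a], [b, n-b]] by direct
    hypergeometric enumeration (minimum-likelihood rule), exact combinatorics."""
    k = a + b  # column-1 margin; population 2n, draws n

    def pmf(x):
        if x < max(0, k - n) or x > min(n, k):
            return 0.0
        return comb(n, x) * comb(n, k - x) / comb(2 * n, k)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n), min(n, k) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def quadratic_intersect(crms, intervals):
    """All-pairs interval overlap, half-open, with chr-prefix normalization."""
    def norm(c):
        return c[3:] if c.lower().startswith("chr") else c

    out = set()
    for crm in crms:
        for idx, (chrom, start, end, *rest) in enumerate(intervals):
            if norm(chrom) != norm(crm.chrom):
                continue
            bp = min(crm.end, end) - max(crm.start, start)
            if bp > 0:
                out.add((crm.crm_id, idx, bp))
    return out


def consecutive_window_triads(tf_sequence, triad):
    """Indices i where (site_i, site_i+1, site_i+2) cover the triad exactly."""
    out = []
    for i in range(len(tf_sequence) - 2):
        if set(tf_sequence[i : i + 3]) == set(triad) and len(set(tf_sequence[i : i + 3])) == 3:
            out.append(i)
    return out
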