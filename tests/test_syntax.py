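import numpy as np
import pytest

from enhancersyntax.scan import MotifHit
from enhancersyntax.syntax import (
    count_arrangements,
    find_adjacent_triads,
    fisher_arrangement_test,
    group_occurrences,
    ordered_sites,
    spacing_from_table,
    spacing_stats,
)

from .oracles import consecutive_window_triads, fisher_two_sided

TRIAD = {"HES5", "FOXP2", "GATA3"}


def hit(tf, start, width=10, seq_id="s1", rel=0.9):
    return MotifHit(seq_id, tf, start, start + width, "+", 10.0, rel)


def site_list(*tf_starts, seq_id="s1"):
    return ordered_sites([hit(tf, s, seq_id=seq_id) for tf, s in tf_starts])


class TestOrderedSites:
    def test_empty(self):
        assert ordered_sites([]) == []

    def test_same_start_ties_break_lexicographically(self):
        sites = site_list(("FOXP2", 5), ("ARX", 5))
        assert [s.tf_name for s in sites] == ["ARX", "FOXP2"]

    def test_tf_filter(self):
        sites = ordered_sites([hit("A", 0), hit("B", 20)], tf_set={"B"})
        assert [s.tf_name for s in sites] == ["B"]

    def test_shuffled_equals_sorted_oracle(self, rng):
        tfs = list("ABCDE")
        hits = [hit(rng.choice(tfs), int(rng.integers(0, 500))) for _ in range(60)]
        got = ordered_sites(hits)
        # oracle: dedup same (start, tf) by max rel, then plain sort
        dedup = {}
        for h in hits:
            k = (h.start, h.tf_name)
            if k not in dedup or h.rel_score > dedup[k].rel_score:
                dedup[k] = h
        expected = sorted(dedup.values(), key=lambda h: (h.start, h.end, h.tf_name))
        assert got == expected

    def test_same_position_keeps_best_rel_score(self):
        a = hit("FOXP2", 5, rel=0.85)
        b = hit("FOXP2", 5, rel=0.95)
        assert ordered_sites([a, b]) == [b]


class TestAdjacentTriads:
    def test_direct_adjacency_detected(self):
        occs = find_adjacent_triads(
            site_list(("HES5", 0), ("FOXP2", 50), ("GATA3", 100)), TRIAD
        )
        assert len(occs) == 1
        assert occs[0].order == ("HES5", "FOXP2", "GATA3")
        assert occs[0].left_gap == 50 - 10
        assert occs[0].right_gap == 100 - 60

    def test_intervening_site_blocks_adjacency(self):
        occs = find_adjacent_triads(
            site_list(("HES5", 0), ("SOX2", 30), ("FOXP2", 50), ("GATA3", 100)), TRIAD
        )
        assert occs == []

    def test_bad_triad_size_rejected(self):
        with pytest.raises(ValueError):
            find_adjacent_triads([], {"A", "B"})

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_consecutive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tfs = ["HES5", "FOXP2", "GATA3", "SOX2", "OTX2"]
        order = [str(rng.choice(tfs)) for _ in range(30)]
        sites = site_list(*[(tf, i * 20) for i, tf in enumerate(order)])
        got = [s.left.start // 20 for s in find_adjacent_triads(sites, TRIAD)]
        assert got == consecutive_window_triads(order, TRIAD)


class TestArrangements:
    def test_paper_style_frequencies(self):
        """Counts 10/4/2 of 16 give 62.5% / 25% / 12.5%."""
        occs = {}
        centers = ["FOXP2"] * 10 + ["HES5"] * 4 + ["GATA3"] * 2
        for i, center in enumerate(centers):
            flanks = sorted(TRIAD - {center})
            occs[f"s{i}"] = [
                find_adjacent_triads(
                    site_list((flanks[0], 0), (center, 50), (flanks[1], 100), seq_id=f"s{i}"),
                    TRIAD,
                )[0]
            ]
        arr = count_arrangements(occs, TRIAD)
        assert arr.n_sequences == 16
        assert arr.per_center == {"FOXP2": 10, "GATA3": 2, "HES5": 4}
        assert arr.frequencies == {"FOXP2": 0.625, "GATA3": 0.125, "HES5": 0.25}

    def test_leftmost_occurrence_wins(self):
        sites = site_list(
            ("HES5", 0), ("FOXP2", 30), ("GATA3", 60), ("HES5", 90), ("GATA3", 120),
        )
        occs = find_adjacent_triads(sites, TRIAD)
        assert len(occs) >= 2  # FOXP2-centred then HES5-centred
        arr = count_arrangements(group_occurrences(occs), TRIAD)
        assert arr.per_center["FOXP2"] == 1
        assert arr.n_sequences == 1


class TestFisher:
    def test_printed_arrangement_pvalues(self):
        assert fisher_arrangement_test(10, 2, 16) == pytest.approx(0.0091, abs=5e-5)
        assert fisher_arrangement_test(10, 4, 16) == pytest.approx(0.0732, abs=5e-5)

    def test_symmetric_table_gives_one(self):
        for k, n in [(3, 10), (0, 5), (7, 7)]:
            assert fisher_arrangement_test(k, k, n) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(1, 31))
            a, b = int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1))
            assert fisher_arrangement_test(a, b, n) == pytest.approx(
                fisher_two_sided(a, b, n), abs=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_arrangement_test(1, 1, 0)
        with pytest.raises(ValueError):
            fisher_arrangement_test(5, 1, 4)


class TestSpacing:
    def one_occurrence(self, left_gap=35, right_gap=60):
        sites = site_list(
            ("HES5", 0), ("FOXP2", 10 + left_gap), ("GATA3", 20 + left_gap + right_gap)
        )
        return find_adjacent_triads(sites, TRIAD)

    def test_single_occurrence_degenerate_stats(self):
        stats = {s.pair: s for s in spacing_stats(self.one_occurrence())}
        assert set(stats) == {"HES5-FOXP2", "GATA3-FOXP2"}
        hes5 = stats["HES5-FOXP2"]
        assert hes5.mean == hes5.min_bp == hes5.max_bp == 35
        assert hes5.sd == 0.0
        assert stats["GATA3-FOXP2"].mean == 60

    def test_empty_input_empty_summary(self):
        assert spacing_stats([]) == []

    def test_uniform_gap_monte_carlo_moments(self, rng):
        """Mean of n=200 uniform(50, 250) gaps lies within 3 sigma of 150."""
        occs = []
        for i in range(200):
            lg, rg = rng.integers(50, 251, size=2)
            occs.extend(
                find_adjacent_triads(
                    site_list(
                        ("HES5", 0), ("FOXP2", 10 + lg), ("GATA3", 20 + lg + rg),
                        seq_id=f"s{i}",
                    ),
                    TRIAD,
                )
            )
        stats = {s.pair: s for s in spacing_stats(occs)}
        se = (200**2 / 12) ** 0.5 / (200**0.5)
        for pair in ("HES5-FOXP2", "GATA3-FOXP2"):
            assert abs(stats[pair].mean - 150) < 3 * se
            assert stats[pair].n == 200

    def test_center_to_center_exceeds_edge_to_edge(self):
        edge = {s.pair: s.mean for s in spacing_stats(self.one_occurrence())}
        c2c = {s.pair: s.mean for s in spacing_stats(self.one_occurrence(), center_to_center=True)}
        for pair in edge:
            assert c2c[pair] == edge[pair] + 10  # site width

    def test_spacing_from_distance_table(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "seq_id": ["hs240", "hs957", "hs1"],
                "pair": ["GATA3-FOXP2", "GATA3-FOXP2", "GATA3-FOXP2"],
                "distance": [35, 504, 100],
            }
        )
        (s,) = spacing_from_table(df)
        assert (s.min_bp, s.min_seq) == (35, "hs240")
        assert (s.max_bp, s.max_seq) == (504, "hs957")
        assert s.mean == pytest.approx(np.mean([35, 504, 100]))
        assert s.sd == pytest.approx(np.std([35, 504, 100], ddof=1))
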