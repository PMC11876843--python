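from collections import Counter

import numpy as np
import pytest

from enhancersyntax.conservation import classify_catalog
from enhancersyntax.genome import TriadQuery, scan_catalog
from enhancersyntax.simulate import (
    CATEGORY_SCORE_RANGES,
    TRIAD,
    SimulationConfig,
    generate_crm_catalog,
    generate_enhancers,
    generate_negative_controls,
    generate_tracks_and_scores,
    make_motif_set,
)


class TestConfig:
    def test_bad_mixture_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            SimulationConfig(category_weights={"primate": 0.5, "mammalian": 0.6})

    def test_bad_center_split_rejected(self):
        with pytest.raises(ValueError, match="entre"):
            SimulationConfig(p_center={"FOXP2": 0.9, "HES5": 0.9, "GATA3": 0.1})

    def test_coverage_fraction_above_one_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SimulationConfig(track_coverage={"H3K4me1": 1.2})


class TestEnhancerGenerator:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=5, n_positive=10)
        a, truth_a = generate_enhancers(cfg)
        b, truth_b = generate_enhancers(SimulationConfig(seed=5, n_positive=10))
        assert a == b
        assert truth_a.equals(truth_b)

    def test_degenerate_triad_always_planted_with_fixed_gaps(self):
        cfg = SimulationConfig(
            seed=3, n_positive=12, p_triad=1.0,
            p_center={"FOXP2": 1.0, "HES5": 0.0, "GATA3": 0.0},
            gap_range=(50, 50),
        )
        motifs = make_motif_set(seed=3)
        motif_map = {m.tf_name: m for m in motifs}
        records, truth = generate_enhancers(cfg, motifs)
        seqs = dict(records)
        triad_rows = truth[truth.role == "triad"]
        assert set(triad_rows.seq_id) == set(seqs)  # every sequence has a triad
        for _, row in triad_rows.iterrows():
            planted = seqs[row.seq_id][row.start : row.end]
            assert planted == motif_map[row.tf].consensus
        # centre is always FOXP2 and gaps are exactly 50 bp
        for seq_id, grp in triad_rows.groupby("seq_id"):
            grp = grp.sort_values("start")
            assert grp.iloc[1].tf == "FOXP2"
            assert grp.iloc[1].start - grp.iloc[0].end == 50
            assert grp.iloc[2].start - grp.iloc[1].end == 50

    def test_no_triad_when_probability_zero(self):
        cfg = SimulationConfig(seed=4, n_positive=15, p_triad=0.0)
        _, truth = generate_enhancers(cfg)
        assert (truth.role != "triad").all()

    def test_oversized_triad_block_rejected(self):
        cfg = SimulationConfig(seed=1, n_positive=5, seq_length=200, p_triad=1.0)
        with pytest.raises(ValueError, match="seq_length"):
            generate_enhancers(cfg)

    def test_triad_cooccurrence_rate_near_planted(self):
        cfg = SimulationConfig(seed=8)
        _, truth = generate_enhancers(cfg)
        n_with = truth[truth.role == "triad"].seq_id.nunique()
        # binomial 99% band around p = 0.28, n = 160
        sd = (0.28 * 0.72 / cfg.n_positive) ** 0.5
        assert abs(n_with / cfg.n_positive - 0.28) < 3 * sd


class TestNegativeControls:
    def test_reproducible_and_background_only(self):
        cfg = SimulationConfig(seed=2, n_negative=20, seq_length=500)
        a = generate_negative_controls(cfg)
        b = generate_negative_controls(cfg)
        assert a == b
        assert all(len(s) == 500 for _, s in a)

    def test_gc_skewed_background_composition(self):
        cfg = SimulationConfig(
            seed=6, n_negative=40, seq_length=2000,
            background=(0.15, 0.35, 0.35, 0.15),
        )
        seqs = "".join(s for _, s in generate_negative_controls(cfg))
        freqs = Counter(seqs)
        total = len(seqs)
        for base, expected in zip("ACGT", cfg.background):
            assert abs(freqs[base] / total - expected) < 0.02


class TestCatalogGenerator:
    def test_zero_planted_yields_no_matches(self):
        cfg = SimulationConfig(seed=9, n_crms=40, n_planted=0)
        motifs = make_motif_set(seed=9)
        catalog, _, truth = generate_crm_catalog(cfg, motifs)
        assert not truth.planted.any()
        assert scan_catalog(catalog, motifs, TriadQuery(*TRIAD)) == []

    def test_fixed_seed_rerun_identical(self):
        cfg = SimulationConfig(seed=10, n_crms=30, n_planted=5)
        cat_a, contigs_a, truth_a = generate_crm_catalog(cfg)
        cat_b, contigs_b, truth_b = generate_crm_catalog(cfg)
        assert contigs_a == contigs_b
        assert [c.sequence for c in cat_a] == [c.sequence for c in cat_b]
        assert truth_a.equals(truth_b)

    def test_crms_are_disjoint_and_within_contigs(self):
        cfg = SimulationConfig(seed=10, n_crms=30, n_planted=5)
        catalog, contigs, _ = generate_crm_catalog(cfg)
        by_chrom = {}
        for c in catalog:
            assert c.end <= len(contigs[c.chrom])
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestTracksAndScores:
    def setup_method(self):
        self.cfg = SimulationConfig(seed=13, n_crms=100, n_planted=0)
        self.catalog, _, _ = generate_crm_catalog(self.cfg)

    def test_full_coverage_track_covers_everything(self):
        cfg = SimulationConfig(seed=13, track_coverage={"DNase_HS": 1.0})
        tracks, _, truth = generate_tracks_and_scores(cfg, self.catalog)
        assert truth["DNase_HS"].all()
        assert len(tracks[0].intervals) == len(self.catalog)

    def test_coverage_fractions_respected(self):
        tracks, _, truth = generate_tracks_and_scores(self.cfg, self.catalog)
        for name, frac in self.cfg.track_coverage.items():
            assert truth[name].sum() == round(frac * len(self.catalog))

    def test_scores_respect_category_bounds_so_classifier_is_exact(self):
        _, wig, truth = generate_tracks_and_scores(self.cfg, self.catalog)
        records = {r.crm_id: r for r in classify_catalog(self.catalog, wig)}
        for _, row in truth.iterrows():
            lo, hi = CATEGORY_SCORE_RANGES[row.category]
            assert lo <= row.mean_score <= hi
            assert records[row.crm_id].category == row.category

    def test_category_mixture_recovered_within_multinomial_band(self):
        big = SimulationConfig(seed=14, n_crms=600, n_planted=0)
        catalog, _, _ = generate_crm_catalog(big)
        _, _, truth = generate_tracks_and_scores(big, catalog)
        counts = truth.category.value_counts()
        n = len(catalog)
        for cat, w in big.category_weights.items():
            sd = (w * (1 - w) / n) ** 0.5
            assert abs(counts.get(cat, 0) / n - w) < 4 * sd + 1e-9


class TestEndToEndRecovery:
    def test_mining_recovers_planted_triad_rule(self):
        """scan -> mine on one default-condition replicate finds the triad."""
        from enhancersyntax import build_binding_matrix, mine_rules, select_minimal_code
        from enhancersyntax.scan import scan_sequence

        cfg = SimulationConfig(seed=42)
        motifs = make_motif_set(seed=42)
        records, _ = generate_enhancers(cfg, motifs)
        hits = []
        for seq_id, seq in records:
            for m in motifs:
                hits.extend(scan_sequence(seq, m, 0.8, seq_id=seq_id))
        matrix = build_binding_matrix(
            hits, [s for s, _ in records], [m.tf_name for m in motifs]
        )
        code = select_minimal_code(mine_rules(matrix))
        assert code.items == frozenset(TRIAD)
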