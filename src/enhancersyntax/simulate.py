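"""Synthetic study inputs with known ground truth.

Generates every input the pipeline consumes: positive enhancer sequences
with a planted co-occurring TF triad (controlled co-occurrence rate, centre
split and spacing distribution), pure-background negative controls, a
genome-wide CRM catalog with a planted ordered-triad subset, epigenomic
interval tracks covering chosen CRM fractions, and a per-base conservation
track drawn from a chosen clade-category mixture.

Default parameters emulate the statistical structure the analysis targets:
the triad co-occurs in 28% of positives, the centre-TF split is
0.625/0.25/0.125, spacings are uniform on [35, 504] bp, and the
conservation mixture and track coverages mirror the fractions the study
reports for its 2614-CRM shortlist.  Planted sites use motif consensus
strings, so recovery does not depend on the scan threshold; a degraded-site
mode samples from the PWM instead.

Each generator consumes its own child RNG stream spawned from the master
seed, so e.g. growing the sequence set does not perturb track sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CRM
from .motifs import ALPHABET, Motif
from .overlap import IntervalTrack
from .conservation import WigTrack

#: The triad whose syntax the analysis characterizes.
TRIAD = ("HES5", "FOXP2", "GATA3")

#: Synthetic stand-ins for the remainder of a 23-TF forebrain-relevant set.
OTHER_TFS = (
    "SOX2", "OTX2", "PAX6", "EMX2", "DLX2", "NKX2-1", "LHX2", "FOXG1",
    "ARX", "SIX3", "GSX2", "ASCL1", "NEUROD2", "TBR1", "EOMES", "POU3F2",
    "MEF2C", "RFX4", "ZIC2", "BARHL2",
)

ALL_TFS = TRIAD + OTHER_TFS

#: Conservation-category mixture weights mirroring the reported
#: 2051/414/21/128 split of 2614 triad-bearing CRMs.
DEFAULT_CATEGORY_WEIGHTS = {
    "primate": 2051 / 2614,
    "mammalian": 414 / 2614,
    "birds": 21 / 2614,
    "amphibian_teleost": 128 / 2614,
}

#: Score ranges per category, kept strictly inside the classification bins.
CATEGORY_SCORE_RANGES = {
    "primate": (0.01, 0.19),
    "mammalian": (0.21, 0.49),
    "birds": (0.51, 0.59),
    "amphibian_teleost": (0.61, 0.95),
}

#: Track coverage fractions mirroring the reported per-track overlap rates.
DEFAULT_TRACK_COVERAGE = {
    "H3K4me1": 0.22,
    "H3K4me2": 0.25,
    "H3K27ac": 0.25,
    "DNase_HS": 0.95,
    "GATA3_ChIP": 0.89,
    "FOXP2_ChIP": 0.065,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator suite; defaults are the study conditions."""

    seed: int = 0
    n_positive: int = 160
    n_negative: int = 100
    seq_length: int = 1500
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # triad co-occurrence structure
    p_triad: float = 0.28
    p_center: dict[str, float] = field(
        default_factory=lambda: {"FOXP2": 0.625, "HES5": 0.25, "GATA3": 0.125}
    )
    gap_range: tuple[int, int] = (35, 504)
    # independent per-TF planting probabilities (on top of triad planting);
    # the triad TFs keep modest independent marginals so that scattered
    # (non-syntactic) co-occurrence exists but stays well below the planted
    # triad rate
    marginals: dict[str, float] = field(
        default_factory=lambda: {
            "HES5": 0.30, "FOXP2": 0.15, "GATA3": 0.15,
            **{tf: 0.25 for tf in OTHER_TFS},
        }
    )
    degraded_sites: bool = False  # sample planted sites from the PWM
    # CRM catalog
    n_crms: int = 500
    n_planted: int = 120
    crm_length: int = 800
    crm_gap: int = 200
    n_contigs: int = 5
    catalog_gap_range: tuple[int, int] = (35, 200)
    # tracks and conservation
    track_coverage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACK_COVERAGE)
    )
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )

    def __post_init__(self):
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ValueError("category weights must sum to 1")
        if not abs(sum(self.p_center.values()) - 1.0) < 1e-9:
            raise ValueError("centre probabilities must sum to 1")
        for name, frac in self.track_coverage.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"track {name}: coverage fraction must be in [0, 1]")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent child RNG per generator stage."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("motifs", "enhancers", "negatives", "catalog", "tracks")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def make_motif_set(
    tf_names: tuple[str, ...] = ALL_TFS,
    seed: int = 0,
    width_range: tuple[int, int] = (12, 16),
    dominant_count: int = 97,
) -> list[Motif]:
    """Sharp synthetic count matrices, one per TF.

    Each position has one dominant base (count ``dominant_count``) and 1 for
    the rest, giving high-information motifs whose chance hit rate at the
    default scan threshold is low (roughly 0.01-0.1 expected chance
    presences per 1.5 kb sequence) — as expected for curated TF motif models.
    """
    rng = np.random.default_rng(seed)
    motifs = []
    for i, tf in enumerate(tf_names):
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        consensus = rng.integers(0, 4, size=width)
        counts = np.ones((width, 4))
        counts[np.arange(width), consensus] = dominant_count
        motifs.append(Motif(tf_name=tf, motif_id=f"SYN{i:04d}", counts=counts))
    return motifs


def _random_seq(rng: np.random.Generator, length: int, background) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(background))


def _decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def _site_string(motif: Motif, rng: np.random.Generator, degraded: bool) -> str:
    if not degraded:
        return motif.consensus
    freqs = motif.frequencies
    return "".join(
        ALPHABET[rng.choice(4, p=freqs[i] / freqs[i].sum())] for i in range(motif.width)
    )


def _place_site(
    seq: np.ndarray, site: str, start: int, occupied: list[tuple[int, int]]
) -> None:
    seq[start : start + len(site)] = [ALPHABET.index(b) for b in site]
    occupied.append((start, start + len(site)))


def _free_position(
    rng: np.random.Generator, seq_len: int, width: int,
    occupied: list[tuple[int, int]], tries: int = 200,
) -> int | None:
    for _ in range(tries):
        s = int(rng.integers(0, seq_len - width + 1))
        if all(s + width <= a or s >= b for a, b in occupied):
            return s
    return None


def generate_enhancers(
    config: SimulationConfig, motifs: list[Motif] | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Positive sequences with planted structure, plus a truth table.

    Truth rows: seq_id, tf, start, end, strand, role (``triad``/``marginal``)
    and, on triad rows, the planted order string.
    """
    motifs = motifs if motifs is not None else make_motif_set(seed=config.seed)
    motif_map = {m.tf_name: m for m in motifs}
    rng = config.streams()["enhancers"]
    centers = sorted(config.p_center)
    center_p = [config.p_center[c] for c in centers]

    records: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(config.n_positive):
        seq_id = f"pos_{i:04d}"
        seq = _random_seq(rng, config.seq_length, config.background)
        occupied: list[tuple[int, int]] = []
        planted_triad = rng.random() < config.p_triad
        triad_span: tuple[int, int] | None = None
        if planted_triad:
            center = centers[int(rng.choice(len(centers), p=center_p))]
            flanks = [tf for tf in TRIAD if tf != center]
            if rng.random() < 0.5:
                flanks = flanks[::-1]
            order = (flanks[0], center, flanks[1])
            sites = [_site_string(motif_map[tf], rng, config.degraded_sites) for tf in order]
            gaps = rng.integers(config.gap_range[0], config.gap_range[1] + 1, size=2)
            block = len(sites[0]) + gaps[0] + len(sites[1]) + gaps[1] + len(sites[2])
            if block > config.seq_length:
                raise ValueError(
                    f"planted triad block ({block} bp) exceeds seq_length "
                    f"{config.seq_length}; increase seq_length"
                )
            start = int(rng.integers(0, config.seq_length - block + 1))
            pos = start
            for tf, site, gap in zip(order, sites, (gaps[0], gaps[1], 0)):
                _place_site(seq, site, pos, occupied)
                truth_rows.append(
                    {
                        "seq_id": seq_id, "tf": tf, "start": pos,
                        "end": pos + len(site), "strand": "+",
                        "role": "triad", "order": "-".join(order),
                    }
                )
                pos += len(site) + int(gap)
            triad_span = (start, pos)
        for tf, p in config.marginals.items():
            if rng.random() >= p:
                continue
            site = _site_string(motif_map[tf], rng, config.degraded_sites)
            # an independent triad-member site inside the planted block would
            # silently rewrite the planted arrangement, contradicting the
            # recorded truth; keep triad TFs out of the block
            exclude = occupied
            if triad_span is not None and tf in TRIAD:
                exclude = occupied + [triad_span]
            s = _free_position(rng, config.seq_length, len(site), exclude)
            if s is None:
                continue
            _place_site(seq, site, s, occupied)
            truth_rows.append(
                {
                    "seq_id": seq_id, "tf": tf, "start": s, "end": s + len(site),
                    "strand": "+", "role": "marginal", "order": "",
                }
            )
        records.append((seq_id, _decode(seq)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "tf", "start", "end", "strand", "role", "order"],
    )
    return records, truth


def generate_negative_controls(config: SimulationConfig) -> list[tuple[str, str]]:
    """Pure-background sequences; motif matches arise only by chance."""
    rng = config.streams()["negatives"]
    return [
        (f"neg_{i:04d}", _decode(_random_seq(rng, config.seq_length, config.background)))
        for i in range(config.n_negative)
    ]


def generate_crm_catalog(
    config: SimulationConfig, motifs: list[Motif] | None = None
) -> tuple[list[CRM], dict[str, str], pd.DataFrame]:
    """Synthetic genome + CRM catalog with a planted ordered-triad subset.

    Returns (catalog with sequences attached, contig sequences, truth table
    flagging planted crm_ids).  Planted CRMs carry consensus sites in
    HES5-FOXP2-GATA3 order with gaps from ``catalog_gap_range``.
    """
    motifs = motifs if motifs is not None else make_motif_set(seed=config.seed)
    motif_map = {m.tf_name: m for m in motifs}
    rng = config.streams()["catalog"]

    per_contig = int(np.ceil(config.n_crms / config.n_contigs))
    contig_len = per_contig * (config.crm_length + config.crm_gap) + config.crm_gap

    planted_ids = set(
        rng.choice(config.n_crms, size=config.n_planted, replace=False).tolist()
    )
    contigs: dict[str, np.ndarray] = {}
    catalog: list[CRM] = []
    truth_rows = []
    idx = 0
    for ci in range(config.n_contigs):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, contig_len, config.background)
        for j in range(per_contig):
            if idx >= config.n_crms:
                break
            start = config.crm_gap + j * (config.crm_length + config.crm_gap)
            end = start + config.crm_length
            crm_id = f"{chrom}_crm_{idx}"
            planted = idx in planted_ids
            if planted:
                order = TRIAD  # HES5-FOXP2-GATA3
                sites = [motif_map[tf].consensus for tf in order]
                gaps = rng.integers(
                    config.catalog_gap_range[0], config.catalog_gap_range[1] + 1, size=2
                )
                block = sum(map(len, sites)) + int(gaps.sum())
                if block > config.crm_length:
                    raise ValueError("planted triad exceeds crm_length")
                pos = start + int(rng.integers(0, config.crm_length - block + 1))
                for site, gap in zip(sites, (int(gaps[0]), int(gaps[1]), 0)):
                    seq[pos : pos + len(site)] = [ALPHABET.index(b) for b in site]
                    pos += len(site) + gap
            catalog.append(CRM(crm_id, chrom, start, end))
            truth_rows.append({"crm_id": crm_id, "planted": planted})
            idx += 1
        contigs[chrom] = seq

    contig_strs = {c: _decode(s) for c, s in contigs.items()}
    catalog = [
        CRM(c.crm_id, c.chrom, c.start, c.end, contig_strs[c.chrom][c.start : c.end])
        for c in catalog
    ]
    return catalog, contig_strs, pd.DataFrame(truth_rows, columns=["crm_id", "planted"])


def generate_tracks_and_scores(
    config: SimulationConfig, crms: list[CRM]
) -> tuple[list[IntervalTrack], WigTrack, pd.DataFrame]:
    """Epigenomic tracks covering configured CRM fractions + conservation track.

    Each track samples ``round(fraction * n)`` CRMs without replacement and
    covers each with one interval (the CRM padded by 50 bp).  Per-CRM
    conservation categories are drawn from the configured mixture; per-base
    scores are constant at the CRM's drawn mean, emitted as fixed-step
    wiggle.  Truth records category and track memberships per CRM.
    """
    rng = config.streams()["tracks"]
    n = len(crms)
    truth = pd.DataFrame({"crm_id": [c.crm_id for c in crms]})

    tracks: list[IntervalTrack] = []
    for name, frac in config.track_coverage.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"track {name}: fraction {frac} > 1")
        k = int(round(frac * n))
        chosen = set(rng.choice(n, size=k, replace=False).tolist())
        intervals = [
            (c.chrom, max(0, c.start - 50), c.end + 50, f"{name}_{i}")
            for i, c in enumerate(crms)
            if i in chosen
        ]
        tracks.append(IntervalTrack(name, intervals, source="synthetic"))
        truth[name] = [i in chosen for i in range(n)]

    cats = sorted(config.category_weights)
    weights = [config.category_weights[c] for c in cats]
    drawn = rng.choice(len(cats), size=n, p=weights)
    wig = WigTrack()
    categories, means = [], []
    for c, k in zip(crms, drawn):
        cat = cats[int(k)]
        lo, hi = CATEGORY_SCORE_RANGES[cat]
        mean = float(rng.uniform(lo, hi))
        wig.add_block(c.chrom, c.start, np.full(c.end - c.start, round(mean, 4)))
        categories.append(cat)
        means.append(round(mean, 4))
    truth["category"] = categories
    truth["mean_score"] = means
    return tracks, wig, truth
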