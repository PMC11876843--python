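"""End-to-end orchestration of the discovery and shortlisting workflows,
with manifest logging so identical inputs provably give identical outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation as cons
from . import genome, mining, overlap, scan, syntax
from .motifs import load_motifs

log = logging.getLogger(__name__)

#: Default feature-class grouping used before core-set membership logic.
DEFAULT_CLASS_MAP = {
    "histone": ["H3K4me1", "H3K4me2", "H3K27ac"],
    "dnase": ["DNase_HS"],
    "tf_chip": ["GATA3_ChIP", "FOXP2_ChIP"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def record_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def record_output(self, path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def record_stage(self, name: str, elapsed: float) -> None:
        self.stages.append({"stage": name, "seconds": round(elapsed, 3)})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


class _Timer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.record_stage(self.name, time.perf_counter() - self.t0)
        if exc_type is not None:
            log.error("stage %s failed: %s", self.name, exc)
        else:
            log.info("stage %s: done", self.name)
        return False


def run_discovery(
    positive_fasta,
    negative_fasta,
    motif_file,
    out_dir,
    motif_format: str = "jaspar",
    min_rel_score: float = 0.8,
    min_support: float = 0.1,
    min_confidence: float = 0.6,
    triad: tuple[str, str, str] = ("HES5", "FOXP2", "GATA3"),
    analysis_tfs: list[str] | None = None,
) -> dict:
    """scan -> matrix -> mine (both datasets) -> contrast -> syntax.

    Emits rules tables, the contrast report, arrangement counts with
    Fisher p-values, the spacing summary and the selected minimal-code rule
    under ``out_dir``; returns the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {
        "positive_fasta": str(positive_fasta), "negative_fasta": str(negative_fasta),
        "motif_file": str(motif_file), "motif_format": motif_format,
        "min_rel_score": min_rel_score, "min_support": min_support,
        "min_confidence": min_confidence, "triad": list(triad),
    }
    manifest = RunManifest(config=config)
    for p in (positive_fasta, negative_fasta, motif_file):
        manifest.record_input(p)

    motifs = load_motifs(motif_file, motif_format)
    tf_names = [m.tf_name for m in motifs]

    with _Timer(manifest, "scan"):
        pos_hits, pos_ids = scan.scan_fasta(positive_fasta, motifs, min_rel_score)
        neg_hits, neg_ids = scan.scan_fasta(negative_fasta, motifs, min_rel_score)
        pos_matrix = scan.build_binding_matrix(pos_hits, pos_ids, tf_names)
        neg_matrix = scan.build_binding_matrix(neg_hits, neg_ids, tf_names)
    scan.write_hits_tsv(pos_hits, out / "hits_positive.tsv")
    scan.write_hits_tsv(neg_hits, out / "hits_negative.tsv")
    scan.write_matrix_tsv(pos_matrix, out / "matrix_positive.tsv")
    scan.write_matrix_tsv(neg_matrix, out / "matrix_negative.tsv")

    with _Timer(manifest, "mine"):
        pos_rules = mining.mine_rules(pos_matrix, min_support, min_confidence)
        neg_rules = mining.mine_rules(neg_matrix, min_support, min_confidence)
        contrast = mining.contrast_controls(pos_rules, neg_rules)
    mining.write_rules_tsv(pos_rules, out / "rules_positive.tsv")
    mining.write_rules_tsv(neg_rules, out / "rules_negative.tsv")
    contrast.to_csv(out / "contrast.tsv", sep="\t", index=False)

    try:
        if not pos_rules:
            raise mining.NoMinimalCodeError("no association rules at these thresholds")
        minimal = mining.select_minimal_code(pos_rules)
        minimal_payload = {
            "antecedent": sorted(minimal.antecedent),
            "consequent": sorted(minimal.consequent),
            "support": minimal.support,
            "confidence": minimal.confidence,
            "lift": minimal.lift,
        }
    except mining.NoMinimalCodeError as exc:
        minimal, minimal_payload = None, {"error": str(exc)}

    with _Timer(manifest, "syntax"):
        analysis_set = set(analysis_tfs) if analysis_tfs else set(tf_names)
        by_seq: dict[str, list[scan.MotifHit]] = {s: [] for s in pos_ids}
        for h in pos_hits:
            by_seq[h.seq_id].append(h)
        occurrences = []
        for seq_id in pos_ids:
            sites = syntax.ordered_sites(by_seq[seq_id], analysis_set)
            occurrences.extend(syntax.find_adjacent_triads(sites, set(triad)))
        grouped = syntax.group_occurrences(occurrences)
        arrangements = syntax.count_arrangements(grouped, set(triad))
        spacing = syntax.spacing_stats(occurrences)
        fisher = {}
        if arrangements.n_sequences > 0:
            ranked = sorted(arrangements.per_center.items(), key=lambda kv: -kv[1])
            top = ranked[0]
            for tf, count in ranked[1:]:
                fisher[f"{top[0]}_vs_{tf}"] = syntax.fisher_arrangement_test(
                    top[1], count, arrangements.n_sequences
                )

    syntax.occurrences_to_frame(occurrences).to_csv(
        out / "triad_occurrences.tsv", sep="\t", index=False
    )
    pd.DataFrame([s.__dict__ for s in spacing]).to_csv(
        out / "spacing.tsv", sep="\t", index=False
    )
    with open(out / "arrangements.json", "w") as fh:
        json.dump(
            {
                "triad": sorted(arrangements.triad),
                "n_sequences_with_adjacent_triad": arrangements.n_sequences,
                "per_center": arrangements.per_center,
                "frequencies": arrangements.frequencies,
                "fisher_p": fisher,
            },
            fh,
            indent=2,
        )
    with open(out / "minimal_code.json", "w") as fh:
        json.dump(minimal_payload, fh, indent=2)

    for name in (
        "hits_positive.tsv", "hits_negative.tsv", "matrix_positive.tsv",
        "matrix_negative.tsv", "rules_positive.tsv", "rules_negative.tsv",
        "contrast.tsv", "triad_occurrences.tsv", "spacing.tsv",
        "arrangements.json", "minimal_code.json",
    ):
        manifest.record_output(out / name)
    manifest.write(out / "manifest.json")

    return {
        "pos_rules": pos_rules, "neg_rules": neg_rules, "contrast": contrast,
        "minimal_code": minimal, "arrangements": arrangements,
        "spacing": spacing, "fisher": fisher, "occurrences": occurrences,
        "pos_matrix": pos_matrix, "neg_matrix": neg_matrix,
    }


def run_shortlist(
    catalog_bed,
    out_dir,
    motif_file,
    genome_fasta=None,
    motif_format: str = "jaspar",
    triad: tuple[str, str, str] = ("HES5", "FOXP2", "GATA3"),
    min_rel_score: float = 0.8,
    max_gap: int | None = None,
    conservation_wig=None,
    conservation_table=None,
    track_beds: dict[str, str] | None = None,
    class_map: dict[str, list[str]] | None = None,
    core_mode: str = "k_of",
    core_k: int = 3,
) -> dict:
    """genome scan -> conservation classification -> overlap -> core set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {
        "catalog_bed": str(catalog_bed), "genome_fasta": str(genome_fasta),
        "motif_file": str(motif_file), "triad": list(triad),
        "min_rel_score": min_rel_score, "max_gap": max_gap,
        "core_mode": core_mode, "core_k": core_k,
    }
    manifest = RunManifest(config=config)
    manifest.record_input(catalog_bed)
    manifest.record_input(motif_file)

    motifs = load_motifs(motif_file, motif_format)
    catalog = genome.read_catalog_bed(catalog_bed)
    if genome_fasta is not None:
        catalog = genome.extract_sequences(catalog, genome_fasta)
    query = genome.TriadQuery(triad[0], triad[1], triad[2], max_gap=max_gap)

    with _Timer(manifest, "genome_scan"):
        matches = genome.scan_catalog(catalog, motifs, query, min_rel_score)
    matched_ids = {m.crm_id for m in matches}
    matched_crms = [c for c in catalog if c.crm_id in matched_ids]
    genome.write_matched_bed(matches, catalog, out / "matched.bed")
    genome.matches_to_frame(matches).to_csv(out / "matches.tsv", sep="\t", index=False)

    records, summary = [], None
    if conservation_wig is not None or conservation_table is not None:
        with _Timer(manifest, "conservation"):
            if conservation_wig is not None:
                track = cons.WigTrack.read(conservation_wig)
                records = cons.classify_catalog(matched_crms, track)
            else:
                records = cons.records_from_table(
                    pd.read_csv(conservation_table, sep="\t")
                )
            summary = cons.summarize_catalog(records)
        cons.records_to_frame(records).to_csv(out / "conservation.tsv", sep="\t", index=False)
        summary.to_csv(out / "conservation_summary.tsv", sep="\t", index=False)

    matrix = core = None
    if track_beds:
        with _Timer(manifest, "overlap"):
            tracks = [overlap.read_bed_track(p, name) for name, p in track_beds.items()]
            matrix = overlap.build_feature_matrix(matched_crms, tracks)
            cmap = class_map or {
                k: [t for t in v if t in matrix.frame.columns]
                for k, v in DEFAULT_CLASS_MAP.items()
            }
            cmap = {k: v for k, v in cmap.items() if v}
            classes = overlap.collapse_classes(matrix, cmap)
            core = overlap.core_set(
                classes, list(classes.frame.columns), mode=core_mode, k=core_k
            )
        matrix.frame.to_csv(out / "feature_matrix.tsv", sep="\t", index_label="crm_id")
        (out / "core_crms.txt").write_text("\n".join(core) + ("\n" if core else ""))
    else:
        log.warning("no tracks supplied; feature matrix and core set skipped")

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.record_output(p)
    manifest.write(out / "manifest.json")

    return {
        "matches": matches, "matched_crms": matched_crms,
        "conservation": records, "conservation_summary": summary,
        "feature_matrix": matrix, "core_set": core,
    }
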