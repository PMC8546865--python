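"""End-to-end orchestration of the mining pipeline on a synthetic study.

Stages: curated-catalog clustering -> homolog expansion and model library ->
catalog scoring (environmental + control) -> per-gene deduplication ->
negative-control PR calibration -> final hit filtering -> truth-table
evaluation. Each stage is the corresponding module's public API; this module
only wires them together and computes ground-truth metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import aggregate, calibrate, library, search, synthetic


@dataclass
class PipelineResult:
    study: synthetic.SyntheticStudy
    representatives: list[library.EnzymeRecord]
    models: list[library.ProfileModelGroup]
    manifest: pd.DataFrame
    env_dedup: search.HitTable
    control_dedup: search.HitTable
    calibrations: dict[str, calibrate.CalibrationResult]
    final: search.HitTable
    metrics: dict[str, float]


def curated_records(study: synthetic.SyntheticStudy) -> list[library.EnzymeRecord]:
    return [
        library.EnzymeRecord(mid, seq, fam.plastic_type, fam.compound_class)
        for fam in study.families
        for mid, seq in zip(fam.member_ids, fam.member_seqs)
    ]


def family_of_model(manifest: pd.DataFrame) -> Mapping[str, str]:
    """model_id -> source family, via the representative's id prefix."""
    return {
        row.model_id: row.representative_id.rsplit("_m", 1)[0]
        for row in manifest.itertuples(index=False)
    }


def evaluate_against_truth(
    result_final: search.HitTable,
    env_dedup: search.HitTable,
    truth: pd.DataFrame,
    manifest: pd.DataFrame,
    calibrations: Mapping[str, calibrate.CalibrationResult],
    evalue_max: float,
) -> dict[str, float]:
    """Ground-truth precision/recall/retention metrics for a synthetic run."""
    truth_idx = truth.set_index("gene_id")
    fam_of = family_of_model(manifest)

    final_genes = result_final.frame["gene_id"]
    if len(final_genes):
        precision = float(truth_idx.loc[final_genes, "is_homolog"].mean())
    else:
        precision = float("nan")

    planted = truth_idx[truth_idx["is_homolog"]]
    dedup = env_dedup.frame.set_index("gene_id")
    recalled = 0
    for gid, row in planted.iterrows():
        if gid not in dedup.index:
            continue
        hit = dedup.loc[gid]
        if hit["evalue"] <= evalue_max and fam_of[hit["model_id"]] == row["source_family"]:
            recalled += 1
    recall = recalled / len(planted) if len(planted) else float("nan")

    families = sorted(planted["source_family"].unique())
    retained_models = {m for m, c in calibrations.items() if c.retained}
    fams_with_model = {
        fam_of[m] for m in retained_models
    }
    family_retention = (
        sum(f in fams_with_model for f in families) / len(families) if families else float("nan")
    )
    # fraction of the whole library (models without hits count as not retained)
    retained_over_library = len(retained_models) / len(manifest) if len(manifest) else float("nan")
    return {
        "final_hit_precision": precision,
        "planted_recall": recall,
        "family_retention": family_retention,
        "retained_model_fraction": retained_over_library,
        "n_final_hits": float(len(result_final)),
        "n_planted": float(len(planted)),
    }


def run_pipeline(
    cfg: synthetic.GeneratorConfig,
    cluster_cutoff: float = 0.95,
    expand_evalue: float = 1e-10,
    filter_cfg: calibrate.FilterConfig = calibrate.FilterConfig(),
    evalue_report_max: float = 10.0,
    n_decoys: int = 10_000,
    study: synthetic.SyntheticStudy | None = None,
) -> PipelineResult:
    if study is None:
        study = synthetic.generate_study(cfg)
    records = curated_records(study)

    clusters = library.cluster_sequences(records, cluster_cutoff)
    rec_by_id = {r.id: r for r in records}
    reps = [rec_by_id[c.representative_id] for c in clusters]

    expanded = library.expand_homologs(
        reps,
        [(r.id, r.sequence) for r in records],
        evalue_max=expand_evalue,
        n_decoys=min(n_decoys, 2000),
        seed=cfg.seed,
    )
    models = library.build_library(reps, expanded)
    manifest = library.library_manifest(models)

    env_catalog = [(gid, seq) for gid, _sid, seq in study.environmental_genes()]
    sample_of = {gid: sid for gid, sid, _ in study.environmental_genes()}
    env_raw = search.score_catalog(
        models, env_catalog, evalue_report_max, origin="environmental",
        sample_of=sample_of, n_decoys=n_decoys, seed=cfg.seed,
    )
    ctrl_raw = search.score_catalog(
        models, study.control_catalog, evalue_report_max, origin="control",
        sample_of=lambda g: "control", n_decoys=n_decoys, seed=cfg.seed + 1,
    )
    env_dedup = search.deduplicate_hits(env_raw)
    ctrl_dedup = search.deduplicate_hits(ctrl_raw)

    labeled = calibrate.label_scores(env_dedup, ctrl_dedup)
    calibrations = calibrate.calibrate_all(labeled, filter_cfg)
    final = calibrate.filter_hits(env_dedup, calibrations, filter_cfg)

    metrics = evaluate_against_truth(
        final, env_dedup, study.truth, manifest, calibrations, filter_cfg.evalue_max
    )
    return PipelineResult(
        study, reps, models, manifest, env_dedup, ctrl_dedup, calibrations, final, metrics
    )


def per_sample_hit_counts(result: PipelineResult) -> pd.Series:
    """Final filtered hits per sample, zero-filled over all samples."""
    counts = result.final.frame.groupby("sample_id").size()
    all_samples = result.study.metadata["sample_id"]
    return counts.reindex(all_samples, fill_value=0).rename("n_hits")
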