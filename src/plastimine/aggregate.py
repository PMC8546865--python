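"""Aggregation of filtered hits into reporting units.

Per-sample summaries (hits, degradable plastic types, polymer/additive
split), per-dataset summaries with hits-per-gene ratios, overall and mean
rows, EC annotation coverage, and per-genome-bin plastic profiles.

The module also packages the summary counts of the four published
metagenome collections (global ocean, global topsoil, Australian and Chinese
topsoil surveys) so the dataset-level arithmetic — additive shares, totals,
mean rows, hits-per-gene — can be recomputed from printed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .search import HitTable

#: profile models built / retained by the published survey's library
INITIAL_MODEL_COUNT = 1201
RETAINED_MODEL_COUNT = 121

SAMPLE_COLUMNS = [
    "sample_id", "n_hits", "n_plastic_types", "n_polymer_hits", "n_additive_hits", "dataset",
]
DATASET_COLUMNS = [
    "dataset", "n_genes", "n_samples", "n_models_hit", "n_hits",
    "n_plastic_types", "n_polymer_hits", "n_additive_hits", "hits_per_gene",
]


def load_study_counts() -> pd.DataFrame:
    """Per-dataset summary counts of the published global survey."""
    with resources.files("plastimine.data").joinpath("study_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _annotated_hits(final: HitTable, manifest: pd.DataFrame) -> pd.DataFrame:
    lib = manifest[["model_id", "plastic_type", "compound_class"]]
    merged = final.frame.merge(lib, on="model_id", how="left", validate="many_to_one")
    if merged["plastic_type"].isna().any():
        missing = merged.loc[merged["plastic_type"].isna(), "model_id"].unique()
        raise KeyError(f"hits reference models absent from manifest: {missing[:5]}")
    return merged


def summarize_samples(
    final: HitTable,
    manifest: pd.DataFrame,
    sample_to_dataset: Mapping[str, str],
    all_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample hit counts, distinct plastic types and the
    polymer/additive split. Samples missing from ``sample_to_dataset`` are an
    error; pass ``all_samples`` to include zero-hit samples explicitly."""
    merged = _annotated_hits(final, manifest)
    unknown = set(merged["sample_id"]) - set(sample_to_dataset)
    if unknown:
        raise KeyError(f"hits from unknown samples: {sorted(unknown)[:5]}")
    rows = []
    for sid, grp in merged.groupby("sample_id", sort=True):
        rows.append(
            (
                sid,
                len(grp),
                grp["plastic_type"].nunique(),
                int((grp["compound_class"] == "polymer").sum()),
                int((grp["compound_class"] == "additive").sum()),
                sample_to_dataset[sid],
            )
        )
    if all_samples is not None:
        seen = {r[0] for r in rows}
        for sid in all_samples:
            if sid not in seen:
                rows.append((sid, 0, 0, 0, 0, sample_to_dataset[sid]))
        rows.sort(key=lambda r: r[0])
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def summarize_datasets(
    samples: pd.DataFrame,
    gene_counts: Mapping[str, int],
    models_hit: Mapping[str, int] | None = None,
    types_hit: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-dataset aggregation of sample summaries.

    ``models_hit``/``types_hit`` supply the distinct-model and distinct-type
    counts per dataset (they are not recoverable from sample rows alone);
    when omitted, plastic types fall back to the per-sample maximum and
    models to NaN.
    """
    rows = []
    for dataset, grp in samples.groupby("dataset", sort=True):
        n_genes = int(gene_counts[dataset])
        if n_genes <= 0:
            raise ValueError(f"gene count for {dataset!r} must be positive")
        n_hits = int(grp["n_hits"].sum())
        rows.append(
            (
                dataset,
                n_genes,
                len(grp),
                (models_hit or {}).get(dataset, np.nan),
                n_hits,
                (types_hit or {}).get(dataset, int(grp["n_plastic_types"].max()) if len(grp) else 0),
                int(grp["n_polymer_hits"].sum()),
                int(grp["n_additive_hits"].sum()),
                n_hits / n_genes,
            )
        )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def dataset_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Dataset summary rows from a pre-counted table (e.g. the packaged
    published counts): adds the hits_per_gene ratio."""
    out = counts.copy()
    out["hits_per_gene"] = out["n_hits"] / out["n_genes"]
    return out[[c for c in DATASET_COLUMNS if c in out.columns]]


def with_total_and_mean(per_dataset: pd.DataFrame, n_types_total: int | None = None) -> pd.DataFrame:
    """Append a summed 'total' row and an arithmetic 'mean' row.

    The mean row is the plain average of the per-dataset values; the total
    row sums the count columns and recomputes hits-per-gene from the summed
    counts.
    """
    df = per_dataset.copy()
    count_cols = ["n_genes", "n_samples", "n_hits", "n_polymer_hits", "n_additive_hits"]
    total = {c: df[c].sum() for c in count_cols}
    total["dataset"] = "total"
    total["n_models_hit"] = np.nan
    total["n_plastic_types"] = n_types_total if n_types_total is not None else df["n_plastic_types"].max()
    total["hits_per_gene"] = total["n_hits"] / total["n_genes"]
    mean = {c: df[c].mean() for c in count_cols + ["n_models_hit", "n_plastic_types", "hits_per_gene"]}
    mean["dataset"] = "mean"
    return pd.concat([df, pd.DataFrame([total, mean])], ignore_index=True)


def additive_share_pct(per_dataset: pd.DataFrame, datasets: Sequence[str]) -> int:
    """Additive hits as an integer-rounded percentage of all hits over the
    given datasets."""
    sub = per_dataset[per_dataset["dataset"].isin(datasets)]
    return int(round(100.0 * sub["n_additive_hits"].sum() / sub["n_hits"].sum()))


def headline_numbers(per_dataset: pd.DataFrame | None = None) -> dict[str, float]:
    """Dataset-level arithmetic of the published survey, recomputed from the
    packaged per-dataset counts and library sizes."""
    counts = dataset_table_from_counts(per_dataset if per_dataset is not None else load_study_counts())
    soil = [d for d in counts["dataset"] if d.startswith("soil")]
    ocean = [d for d in counts["dataset"] if not d.startswith("soil")]
    full = with_total_and_mean(counts)
    total_row = full[full["dataset"] == "total"].iloc[0]
    mean_row = full[full["dataset"] == "mean"].iloc[0]
    ocean_row = counts[counts["dataset"].isin(ocean)]
    return {
        "soil_additive_share_pct": additive_share_pct(counts, soil),
        "ocean_additive_share_pct": additive_share_pct(counts, ocean),
        "total_hits": int(total_row["n_hits"]),
        "soil_hits": int(counts[counts["dataset"].isin(soil)]["n_hits"].sum()),
        "total_additive_hits": int(total_row["n_additive_hits"]),
        "mean_dataset_hits": int(round(mean_row["n_hits"])),
        "ocean_hits_per_gene": round_sig(float(ocean_row["n_hits"].sum() / ocean_row["n_genes"].sum()), 3),
        "retained_model_fraction_pct": int(round(100.0 * RETAINED_MODEL_COUNT / INITIAL_MODEL_COUNT)),
    }


@dataclass
class AnnotationCoverage:
    fraction_annotated: float
    fraction_by_class: dict[str, float]
    ec_top_level_histogram: dict[str, int]
    n_malformed: int


def annotation_coverage(
    final: HitTable, annotations: pd.DataFrame, manifest: pd.DataFrame
) -> AnnotationCoverage:
    """EC annotation coverage of the final hits.

    Unmapped genes count as unannotated; rows whose EC string does not start
    with an integer top-level class are skipped and counted as malformed.
    """
    merged = _annotated_hits(final, manifest)
    ec_of: dict[str, str] = {}
    n_malformed = 0
    for row in annotations.itertuples(index=False):
        top = str(row.ec).split(".", 1)[0]
        if not top.isdigit():
            n_malformed += 1
            continue
        ec_of[row.gene_id] = str(row.ec)
    annotated = merged["gene_id"].map(lambda g: g in ec_of)
    frac = float(annotated.mean()) if len(merged) else 0.0
    by_class = {}
    for cls, grp in merged.groupby("compound_class"):
        by_class[str(cls)] = float(grp["gene_id"].map(lambda g: g in ec_of).mean())
    hist: dict[str, int] = {}
    for gid in merged.loc[annotated, "gene_id"]:
        top = ec_of[gid].split(".", 1)[0]
        hist[top] = hist.get(top, 0) + 1
    return AnnotationCoverage(frac, by_class, dict(sorted(hist.items())), n_malformed)


def genome_bin_profiles(
    final: HitTable,
    manifest: pd.DataFrame,
    gene_to_bin: pd.DataFrame,
    bin_to_taxon: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-genome-bin hit counts and plastic-type sets, plus the
    types-per-bin histogram. Hits on unbinned genes are excluded from
    profiles (they remain in the overall hit totals upstream)."""
    merged = _annotated_hits(final, manifest)
    binned = merged.merge(gene_to_bin, on="gene_id", how="inner")
    taxon = bin_to_taxon.set_index("bin_id")["taxon_path"]
    rows = []
    for bin_id, grp in binned.groupby("bin_id", sort=True):
        types = sorted(grp["plastic_type"].unique())
        rows.append((bin_id, taxon.get(bin_id, ""), len(grp), ";".join(types), len(types)))
    profiles = pd.DataFrame(
        rows, columns=["bin_id", "taxon_path", "n_hits", "plastic_types", "n_plastic_types"]
    )
    histogram = (
        profiles["n_plastic_types"].value_counts().sort_index()
        if len(profiles)
        else pd.Series(dtype=int)
    )
    return profiles, histogram
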