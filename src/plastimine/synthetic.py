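"""Synthetic study generator.

Emulates the inputs of a global metagenome survey for plastic-degrading
enzymes: a curated catalog of enzyme families with known within-family
divergence, per-sample environmental gene catalogs with planted homologues,
a negative-control catalog of composition-matched decoys (standing in for a
habitat assumed free of the target function), geolocated sample metadata
with a latent pollution field, and several pollution surveys measuring that
field on different, monotonically distorted scales.

Everything is driven by a single integer seed; independent, tagged RNG
streams keep each stage reproducible on its own. The ground truth (which
genes are homologues, and of which family) is recorded in a truth table so
search, calibration and correlation recovery can all be scored exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

#: plastic type -> compound class; polymers and phthalate-based additives.
PLASTIC_TYPES: tuple[tuple[str, str], ...] = (
    ("PET", "polymer"),
    ("PU", "polymer"),
    ("PHB", "polymer"),
    ("PLA", "polymer"),
    ("PBAT", "polymer"),
    ("PEG", "polymer"),
    ("PE", "polymer"),
    ("PBS", "polymer"),
    ("PVA", "polymer"),
    ("PHO", "polymer"),
    ("phthalate", "additive"),
    ("PA", "additive"),
    ("DBP", "additive"),
    ("TP", "additive"),
)

OCEAN_REGIONS = (
    "North_Atlantic",
    "South_Atlantic",
    "North_Pacific",
    "South_Pacific",
    "Indian_Ocean",
    "Mediterranean",
    "Red_Sea",
    "Southern_Ocean",
)

#: depth layers: surface, deep chlorophyll maximum, mesopelagic.
DEPTH_LAYERS = ("SRF", "DCM", "MES")

# distinct stream tags so each generator stage has its own substream
_TAG_FAMILIES = 11
_TAG_CATALOGS = 12
_TAG_METADATA = 13
_TAG_SURVEYS = 14
_TAG_ANNOTATIONS = 15
_TAG_BINS = 16


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults are the conditions every end-to-end test runs under: 20 enzyme
    families of 4 curated members each at 0.2 substitutions/site from their
    ancestor, 40 geolocated samples of 100 predicted genes with on average
    20% planted homologues, a 2000-gene control catalog (half background,
    half composition-matched decoys), and 4 pollution surveys whose pooled
    field couples to planted counts at Spearman 0.5.
    """

    seed: int = 1
    n_families: int = 20
    family_size: int = 4
    seq_length: int = 200
    within_family_divergence: float = 0.2
    n_samples: int = 40
    genes_per_sample: int = 100
    planted_fraction: float = 0.2
    control_genes: int = 2000
    target_rho: float = 0.5
    n_surveys: int = 4
    survey_scale_factors: tuple[float, ...] = (1.0, 10.0, 250.0, 1000.0)
    # marginal spread (sd, in genes) of the planted-count coupling
    count_spread: float = 8.0
    # sd of the multiplicative survey measurement noise (latent-field units)
    survey_noise: float = 0.05
    # coordinate jitter of survey points around their sample (degrees)
    survey_jitter_deg: float = 0.3

    def __post_init__(self) -> None:
        counts = {
            "n_families": self.n_families,
            "family_size": self.family_size,
            "seq_length": self.seq_length,
            "n_samples": self.n_samples,
            "genes_per_sample": self.genes_per_sample,
            "control_genes": self.control_genes,
            "n_surveys": self.n_surveys,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.within_family_divergence < 1.0:
            raise ValueError("within_family_divergence must be in [0, 1)")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if abs(self.target_rho) > 1.0:
            raise ValueError("target_rho must be in [-1, 1]")
        if len(self.survey_scale_factors) < self.n_surveys:
            raise ValueError("need a scale factor per survey")
        if any(s <= 0 for s in self.survey_scale_factors):
            raise ValueError("survey_scale_factors must be positive")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EnzymeFamily:
    family_id: str
    plastic_type: str
    compound_class: str
    ancestor: str
    member_ids: list[str]
    member_seqs: list[str]


@dataclass
class SyntheticStudy:
    """Bundle of all generated pipeline inputs plus ground truth."""

    config: GeneratorConfig
    families: list[EnzymeFamily]
    catalogs: dict[str, list[tuple[str, str]]]  # sample_id -> [(gene_id, seq)]
    control_catalog: list[tuple[str, str]]
    truth: pd.DataFrame  # gene_id, is_homolog, source_family
    metadata: pd.DataFrame
    surveys: list[pd.DataFrame]
    planted_counts: pd.Series  # per sample_id

    @property
    def curated_records(self) -> list[tuple[str, str]]:
        return [
            (mid, seq)
            for fam in self.families
            for mid, seq in zip(fam.member_ids, fam.member_seqs)
        ]

    def environmental_genes(self) -> list[tuple[str, str, str]]:
        """(gene_id, sample_id, sequence) over all sample catalogs."""
        return [
            (gid, sid, seq)
            for sid, genes in self.catalogs.items()
            for gid, seq in genes
        ]


def _rng(cfg: GeneratorConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, N_AA, size=length)


def _mutate(encoded: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position i.i.d. at the given rate, always to a
    different residue (uniform over the remaining 19)."""
    out = encoded.copy()
    mask = rng.random(encoded.size) < divergence
    n_mut = int(mask.sum())
    if n_mut:
        offsets = rng.integers(1, N_AA, size=n_mut)
        out[mask] = (out[mask] + offsets) % N_AA
    return out


def decode(encoded: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in encoded)


def encode(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def generate_enzyme_families(cfg: GeneratorConfig) -> list[EnzymeFamily]:
    """Ancestral sequences plus family members diverged by i.i.d. substitution.

    Each family carries a plastic-type label and its polymer/additive class,
    cycled through the catalog of known degradable types.
    """
    rng = _rng(cfg, _TAG_FAMILIES)
    families: list[EnzymeFamily] = []
    for k in range(cfg.n_families):
        ptype, pclass = PLASTIC_TYPES[k % len(PLASTIC_TYPES)]
        ancestor = _random_protein(rng, cfg.seq_length)
        fid = f"F{k:03d}"
        member_ids, member_seqs = [], []
        for m in range(cfg.family_size):
            member = _mutate(ancestor, cfg.within_family_divergence, rng)
            member_ids.append(f"{fid}_m{m}")
            member_seqs.append(decode(member))
        families.append(
            EnzymeFamily(fid, ptype, pclass, decode(ancestor), member_ids, member_seqs)
        )
    return families


def _coupled_planted_counts(
    field_values: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample planted-homologue counts with population Spearman
    target_rho to the latent field.

    A Gaussian copula on the field ranks: the latent count variable has
    Pearson correlation 2*sin(pi*rho_s/6) with the field's normal scores, so
    its population Spearman against the field equals target_rho for any
    field marginal. Counts are a monotone (rounded) map of that latent
    variable; at |target_rho| = 1 the map is strictly rank-preserving so the
    empirical Spearman is exactly +/-1.
    """
    n = field_values.size
    mu = cfg.planted_fraction * cfg.genes_per_sample
    ranks = rankdata(field_values, method="ordinal")
    if abs(cfg.target_rho) == 1.0:
        # strictly rank-preserving integer counts: exact Spearman +/-1 as
        # long as genes_per_sample can hold start + n - 1
        r = ranks if cfg.target_rho > 0 else n + 1 - ranks
        start = max(0, int(round(mu)) - (n - 1) // 2)
        counts = np.minimum(start + r - 1.0, cfg.genes_per_sample)
    else:
        rho_pearson = 2.0 * math.sin(math.pi * cfg.target_rho / 6.0)
        g = norm.ppf((ranks - 0.5) / n)
        eps = rng.standard_normal(n)
        latent = rho_pearson * g + math.sqrt(1.0 - rho_pearson**2) * eps
        counts = np.clip(np.round(mu + cfg.count_spread * latent), 0, cfg.genes_per_sample)
    return counts.astype(int)


def generate_catalogs(
    cfg: GeneratorConfig,
    families: Sequence[EnzymeFamily],
    metadata: pd.DataFrame | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str]], pd.DataFrame, pd.Series]:
    """Environmental catalogs with planted homologues plus a control catalog.

    Returns (catalogs, control_catalog, truth_table, planted_counts).
    If ``metadata`` (with its latent pollution field) is given, per-sample
    planted counts are coupled to the field at the configured Spearman
    strength; otherwise every sample receives the constant
    round(planted_fraction * genes_per_sample).

    The control catalog contains only background sequences plus "near
    decoys": residue shuffles of family members, i.e. composition-matched
    negatives with no positional homology.
    """
    if not families:
        raise ValueError("families must be non-empty")
    rng = _rng(cfg, _TAG_CATALOGS)
    sample_ids = [f"S{j:04d}" for j in range(cfg.n_samples)]
    if metadata is not None:
        field_values = metadata.set_index("sample_id").loc[sample_ids, "latent_field"].to_numpy()
        counts = _coupled_planted_counts(field_values, cfg, rng)
    else:
        counts = np.full(cfg.n_samples, round(cfg.planted_fraction * cfg.genes_per_sample), dtype=int)

    ancestors = [encode(f.ancestor) for f in families]
    catalogs: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple[str, bool, str | None]] = []
    for sid, c in zip(sample_ids, counts):
        genes: list[tuple[str, str]] = []
        fam_choice = rng.integers(0, len(families), size=c)
        for g in range(cfg.genes_per_sample):
            gid = f"{sid}_g{g:05d}"
            if g < c:
                k = int(fam_choice[g])
                seq = decode(_mutate(ancestors[k], cfg.within_family_divergence, rng))
                truth_rows.append((gid, True, families[k].family_id))
            else:
                seq = decode(_random_protein(rng, cfg.seq_length))
                truth_rows.append((gid, False, None))
            genes.append((gid, seq))
        catalogs[sid] = genes

    control: list[tuple[str, str]] = []
    n_background = cfg.control_genes // 2
    member_pool = [encode(s) for f in families for s in f.member_seqs]
    for g in range(cfg.control_genes):
        gid = f"CTRL_g{g:05d}"
        if g < n_background:
            seq = decode(_random_protein(rng, cfg.seq_length))
        else:
            src = member_pool[(g - n_background) % len(member_pool)]
            seq = decode(rng.permutation(src))
        control.append((gid, seq))
        truth_rows.append((gid, False, None))

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "is_homolog", "source_family"])
    if truth["gene_id"].duplicated().any():
        raise AssertionError("duplicate gene ids in truth table")
    planted = pd.Series(counts, index=pd.Index(sample_ids, name="sample_id"), name="planted_count")
    return catalogs, control, truth, planted


def generate_geo_metadata(cfg: GeneratorConfig) -> pd.DataFrame:
    """Geolocated sample metadata with depth layers, habitats, covariates
    and a smooth latent pollution field.

    The field is a superposition of a few broad Gaussian bumps over the
    globe (so nearby coordinates see similar values) plus a small white
    component that guarantees untied values.
    """
    rng = _rng(cfg, _TAG_METADATA)
    n = cfg.n_samples
    sample_ids = [f"S{j:04d}" for j in range(n)]
    lat = rng.uniform(-65.0, 65.0, size=n)
    lon = rng.uniform(-180.0, 180.0, size=n)

    layer = rng.choice(DEPTH_LAYERS, size=n, p=(0.45, 0.33, 0.22))
    depth = np.empty(n)
    depth[layer == "SRF"] = 5.0
    depth[layer == "DCM"] = np.clip(rng.normal(71.0, 41.0, size=(layer == "DCM").sum()), 10.0, 200.0)
    depth[layer == "MES"] = np.clip(rng.normal(600.0, 220.0, size=(layer == "MES").sum()), 201.0, 1200.0)

    habitat = rng.choice(OCEAN_REGIONS, size=n)

    n_bumps = 4
    centers_lat = rng.uniform(-60.0, 60.0, size=n_bumps)
    centers_lon = rng.uniform(-180.0, 180.0, size=n_bumps)
    widths = rng.uniform(20.0, 50.0, size=n_bumps)
    amps = rng.uniform(0.5, 1.5, size=n_bumps)
    field = np.zeros(n)
    for cl, cg, w, a in zip(centers_lat, centers_lon, widths, amps):
        dlon = np.minimum(np.abs(lon - cg), 360.0 - np.abs(lon - cg))
        d2 = (lat - cl) ** 2 + dlon**2
        field += a * np.exp(-d2 / (2.0 * w**2))
    field += 0.25 * rng.standard_normal(n)

    temperature = 25.0 - 18.0 * (depth / 1200.0) - 0.15 * np.abs(lat) + rng.normal(0, 1.0, n)
    salinity = 35.0 + rng.normal(0, 0.8, n)
    nitrate = np.clip(1.0 + 20.0 * depth / 1200.0 + rng.normal(0, 2.0, n), 0.0, None)

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lat": lat,
            "lon": lon,
            "depth_m": depth,
            "layer": layer,
            "habitat": habitat,
            "temperature": temperature,
            "salinity": salinity,
            "nitrate": nitrate,
            "latent_field": field,
        }
    )


def generate_pollution_surveys(
    cfg: GeneratorConfig, metadata: pd.DataFrame
) -> list[pd.DataFrame]:
    """Noisy, scale-distorted surveys of the latent field.

    Samples are dealt round-robin to surveys, so the union of surveys covers
    every sample; each survey point sits at jittered coordinates near its
    sample and measures ``scale_k * exp(gamma_k * (field + noise))`` — a
    strictly monotone, survey-specific distortion of the latent field.
    """
    if metadata.empty:
        raise ValueError("metadata must be non-empty")
    rng = _rng(cfg, _TAG_SURVEYS)
    gammas = (0.6, 1.0, 1.4, 0.8, 1.2, 0.9)
    surveys: list[pd.DataFrame] = []
    n = len(metadata)
    assign = np.arange(n) % cfg.n_surveys
    for k in range(cfg.n_surveys):
        sub = metadata.iloc[assign == k]
        gamma = gammas[k % len(gammas)]
        scale = cfg.survey_scale_factors[k]
        noise = cfg.survey_noise * rng.standard_normal(len(sub))
        value = scale * np.exp(gamma * (sub["latent_field"].to_numpy() + noise))
        jit_lat = rng.uniform(-cfg.survey_jitter_deg, cfg.survey_jitter_deg, len(sub))
        jit_lon = rng.uniform(-cfg.survey_jitter_deg, cfg.survey_jitter_deg, len(sub))
        surveys.append(
            pd.DataFrame(
                {
                    "survey_id": f"SURVEY{k}",
                    "lat": np.clip(sub["lat"].to_numpy() + jit_lat, -90.0, 90.0),
                    "lon": sub["lon"].to_numpy() + jit_lon,
                    "value": value,
                }
            ).reset_index(drop=True)
        )
    return surveys


def generate_annotations(
    cfg: GeneratorConfig, truth: pd.DataFrame, annotated_fraction: float = 0.41
) -> pd.DataFrame:
    """Partial gene -> EC annotation table over the homologous genes.

    Top-level EC classes are drawn with hydrolases/oxidoreductases dominant,
    mirroring what orthology mapping typically assigns to depolymerases.
    """
    rng = _rng(cfg, _TAG_ANNOTATIONS)
    homologs = truth.loc[truth["is_homolog"], "gene_id"].to_numpy()
    n_ann = int(round(annotated_fraction * homologs.size))
    chosen = rng.choice(homologs, size=n_ann, replace=False)
    top = rng.choice([1, 3, 4], size=n_ann, p=(0.3, 0.55, 0.15))
    ecs = [f"{t}.{rng.integers(1, 5)}.{rng.integers(1, 5)}.{rng.integers(1, 40)}" for t in top]
    return pd.DataFrame({"gene_id": np.sort(chosen), "ec": ecs})


def generate_genome_bins(
    cfg: GeneratorConfig, truth: pd.DataFrame, binned_fraction: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene -> genome-bin and bin -> taxonomy tables (partial binning)."""
    rng = _rng(cfg, _TAG_BINS)
    homologs = np.sort(truth.loc[truth["is_homolog"], "gene_id"].to_numpy())
    n_binned = int(round(binned_fraction * homologs.size))
    chosen = rng.choice(homologs, size=n_binned, replace=False)
    n_bins = max(2, cfg.n_samples // 2)
    bin_of = rng.integers(0, n_bins, size=n_binned)
    gene2bin = pd.DataFrame(
        {"gene_id": chosen, "bin_id": [f"BIN{b:03d}" for b in bin_of]}
    ).sort_values("gene_id", ignore_index=True)
    phyla = ["Proteobacteria", "Bacteroidetes", "Firmicutes", "Actinobacteria", "Cyanobacteria"]
    classes = ["Alphaproteobacteria", "Gammaproteobacteria"]
    rows = []
    for b in range(n_bins):
        phylum = phyla[int(rng.integers(0, len(phyla)))]
        taxon = (
            f"{phylum};{classes[int(rng.integers(0, 2))]}"
            if phylum == "Proteobacteria"
            else phylum
        )
        rows.append((f"BIN{b:03d}", taxon))
    bin2tax = pd.DataFrame(rows, columns=["bin_id", "taxon_path"])
    return gene2bin, bin2tax


def generate_study(cfg: GeneratorConfig) -> SyntheticStudy:
    """Run every generator stage in dependency order under one seed."""
    families = generate_enzyme_families(cfg)
    metadata = generate_geo_metadata(cfg)
    catalogs, control, truth, planted = generate_catalogs(cfg, families, metadata)
    surveys = generate_pollution_surveys(cfg, metadata)
    return SyntheticStudy(cfg, families, catalogs, control, truth, metadata, surveys, planted)


# ---------------------------------------------------------------------------
# serialization

def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    """FASTA wrapped at 60 columns (plain text, locale-independent)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_tsv(path, frame: pd.DataFrame, seed: int) -> None:
    """TSV with a '#seed=<int>' provenance header line."""
    with open(path, "w") as fh:
        fh.write(f"#seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
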