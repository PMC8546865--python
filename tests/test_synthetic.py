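"""Generator behavior: determinism, divergence control, truth-table
consistency, geographic metadata, and the count-to-field coupling."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastimine.library import pairwise_identity
from plastimine.stats import spearman
from plastimine.synthetic import (
    AMINO_ACIDS,
    GeneratorConfig,
    generate_catalogs,
    generate_enzyme_families,
    generate_geo_metadata,
    generate_pollution_surveys,
    generate_study,
    write_fasta,
)


def fasta_bytes(records):
    buf = io.StringIO()
    for rid, seq in records:
        buf.write(f">{rid}\n")
        for i in range(0, len(seq), 60):
            buf.write(seq[i : i + 60] + "\n")
    return buf.getvalue()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"within_family_divergence": 1.0},
            {"within_family_divergence": -0.1},
            {"planted_fraction": 1.5},
            {"target_rho": 1.2},
            {"n_families": 0},
            {"survey_scale_factors": (1.0, -2.0, 3.0, 4.0)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)


class TestFamilies:
    def test_zero_divergence_members_equal_ancestor(self):
        cfg = GeneratorConfig(seed=3, n_families=2, family_size=3, within_family_divergence=0.0)
        for fam in generate_enzyme_families(cfg):
            assert all(s == fam.ancestor for s in fam.member_seqs)

    def test_fixed_seed_byte_identical_fasta(self, tiny_cfg):
        a = generate_study(tiny_cfg)
        b = generate_study(tiny_cfg)
        assert fasta_bytes(a.curated_records) == fasta_bytes(b.curated_records)
        env_a = [(g, s) for g, _sid, s in a.environmental_genes()]
        env_b = [(g, s) for g, _sid, s in b.environmental_genes()]
        assert fasta_bytes(env_a) == fasta_bytes(env_b)
        assert fasta_bytes(a.control_catalog) == fasta_bytes(b.control_catalog)

    def test_divergence_matches_binomial_expectation(self):
        # substitution rate 0.2 on 200 residues: identity to the ancestor
        # should average 0.8 within a 3-sigma band of the binomial sd
        cfg = GeneratorConfig(seed=5, n_families=10, family_size=3, seq_length=200)
        fams = generate_enzyme_families(cfg)
        idents = [
            pairwise_identity(m, f.ancestor) for f in fams for m in f.member_seqs
        ]
        assert abs(np.mean(idents) - 0.8) < 0.06

    def test_alphabet_and_labels(self, tiny_study):
        for fam in tiny_study.families:
            assert fam.plastic_type
            assert fam.compound_class in ("polymer", "additive")
            assert set(fam.ancestor) <= set(AMINO_ACIDS)


class TestCatalogs:
    def test_planted_fraction_zero_means_no_homologs(self):
        cfg = GeneratorConfig(
            seed=2, n_families=2, family_size=2, seq_length=60,
            n_samples=3, genes_per_sample=10, planted_fraction=0.0, control_genes=10,
        )
        fams = generate_enzyme_families(cfg)
        _, _, truth, planted = generate_catalogs(cfg, fams)
        assert truth["is_homolog"].sum() == 0
        assert (planted == 0).all()

    def test_planted_fraction_one_plants_every_gene(self):
        cfg = GeneratorConfig(
            seed=2, n_families=2, family_size=2, seq_length=60,
            n_samples=3, genes_per_sample=10, planted_fraction=1.0, control_genes=10,
        )
        fams = generate_enzyme_families(cfg)
        catalogs, _, truth, planted = generate_catalogs(cfg, fams)
        assert (planted == 10).all()
        env_ids = {g for genes in catalogs.values() for g, _ in genes}
        assert truth.set_index("gene_id").loc[sorted(env_ids), "is_homolog"].all()

    def test_truth_table_covers_exactly_all_genes(self, tiny_study):
        catalog_ids = {g for genes in tiny_study.catalogs.values() for g, _ in genes}
        catalog_ids |= {g for g, _ in tiny_study.control_catalog}
        truth_ids = set(tiny_study.truth["gene_id"])
        assert truth_ids == catalog_ids
        assert not tiny_study.truth["gene_id"].duplicated().any()

    def test_decoys_less_similar_than_planted_homologs(self):
        # composition-matched decoys must sit below the planted homologues
        # in identity to any family member
        cfg = GeneratorConfig(
            seed=9, n_families=2, family_size=2, seq_length=150,
            n_samples=2, genes_per_sample=12, planted_fraction=0.5, control_genes=12,
        )
        fams = generate_enzyme_families(cfg)
        catalogs, control, truth, _ = generate_catalogs(cfg, fams)
        members = [s for f in fams for s in f.member_seqs]
        homolog_ids = set(truth.loc[truth["is_homolog"], "gene_id"])
        planted_seqs = [
            s for genes in catalogs.values() for g, s in genes if g in homolog_ids
        ]
        decoys = control[cfg.control_genes // 2 :]  # second half are shuffles
        best_decoy = max(
            pairwise_identity(d, m) for _, d in decoys for m in members
        )
        planted_median = np.median(
            [max(pairwise_identity(p, m) for m in members) for p in planted_seqs]
        )
        assert best_decoy < planted_median


class TestGeoMetadata:
    def test_coordinates_in_range_and_row_count(self):
        cfg = GeneratorConfig(seed=4, n_samples=5, n_families=1, family_size=1)
        meta = generate_geo_metadata(cfg)
        assert len(meta) == 5
        assert meta["lat"].between(-90, 90).all()
        assert meta["lon"].between(-180, 180).all()

    def test_depth_layers_ordered(self):
        cfg = GeneratorConfig(seed=4, n_samples=200, n_families=1, family_size=1)
        meta = generate_geo_metadata(cfg)
        by_layer = meta.groupby("layer")["depth_m"].mean()
        assert by_layer["SRF"] < by_layer["DCM"] < by_layer["MES"]

    def test_latent_field_reproducible(self):
        cfg = GeneratorConfig(seed=8, n_samples=20, n_families=1, family_size=1)
        a = generate_geo_metadata(cfg)
        b = generate_geo_metadata(cfg)
        assert np.array_equal(a["latent_field"], b["latent_field"])


class TestCountCoupling:
    def test_exact_rank_coupling_at_rho_one(self):
        cfg = GeneratorConfig(
            seed=1, n_samples=50, n_families=2, family_size=2, seq_length=60,
            genes_per_sample=100, planted_fraction=0.3, control_genes=10, target_rho=1.0,
        )
        fams = generate_enzyme_families(cfg)
        meta = generate_geo_metadata(cfg)
        _, _, _, planted = generate_catalogs(cfg, fams, meta)
        res = spearman(meta["latent_field"].to_numpy(), planted.to_numpy())
        assert res.rho == pytest.approx(1.0, abs=1e-12)

    def test_near_zero_rho_under_null(self):
        cfg = GeneratorConfig(
            seed=6, n_samples=60, n_families=2, family_size=2, seq_length=60,
            genes_per_sample=100, control_genes=10, target_rho=0.0,
        )
        fams = generate_enzyme_families(cfg)
        meta = generate_geo_metadata(cfg)
        _, _, _, planted = generate_catalogs(cfg, fams, meta)
        res = spearman(meta["latent_field"].to_numpy(), planted.to_numpy())
        assert abs(res.rho) < 0.3

    def test_coupling_converges_at_large_n(self):
        cfg = GeneratorConfig(
            seed=1, n_samples=500, n_families=2, family_size=2, seq_length=60,
            genes_per_sample=100, control_genes=10, target_rho=0.5,
        )
        fams = generate_enzyme_families(cfg)
        meta = generate_geo_metadata(cfg)
        _, _, _, planted = generate_catalogs(cfg, fams, meta)
        res = spearman(meta["latent_field"].to_numpy(), planted.to_numpy())
        assert res.rho == pytest.approx(0.5, abs=0.05)


class TestSurveys:
    def test_every_sample_covered_and_values_positive(self, tiny_cfg, tiny_study):
        total_points = sum(len(s) for s in tiny_study.surveys)
        assert total_points == tiny_cfg.n_samples
        assert len(tiny_study.surveys) == tiny_cfg.n_surveys
        for s in tiny_study.surveys:
            assert (s["value"] > 0).all()

    def test_scale_factors_shift_magnitudes_not_ranks(self):
        cfg = GeneratorConfig(
            seed=13, n_samples=40, n_families=1, family_size=1,
            n_surveys=2, survey_scale_factors=(1.0, 1000.0), survey_noise=0.0,
        )
        meta = generate_geo_metadata(cfg)
        surveys = generate_pollution_surveys(cfg, meta)
        assert surveys[1]["value"].median() > 100 * surveys[0]["value"].median()


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40),
    other=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40),
)
def test_pairwise_identity_properties(seq, other):
    assert pairwise_identity(seq, seq) == pytest.approx(1.0)
    ab = pairwise_identity(seq, other)
    ba = pairwise_identity(other, seq)
    assert 0.0 <= ab <= 1.0
    assert ab == pytest.approx(ba, abs=1e-12)
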