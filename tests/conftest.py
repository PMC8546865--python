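import pytest

from plastimine import pipeline
from plastimine.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def tiny_cfg() -> GeneratorConfig:
    """Small study: fast enough for unit tests, big enough to separate
    planted homologues from background."""
    return GeneratorConfig(
        seed=11,
        n_families=4,
        family_size=3,
        seq_length=120,
        n_samples=8,
        genes_per_sample=30,
        planted_fraction=0.2,
        control_genes=200,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    return generate_study(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_run(tiny_cfg):
    return pipeline.run_pipeline(tiny_cfg, n_decoys=2000)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at generator defaults (20 families, divergence 0.2,
    40 samples, composition-matched control decoys)."""
    return pipeline.run_pipeline(GeneratorConfig(seed=1))
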