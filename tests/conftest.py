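import logging

import pytest

from symbgc.synthetic_data import ScenarioConfig, build_scenario

logging.getLogger("symbgc").setLevel(logging.ERROR)


def small_scenario_config(seed: int = 1, **overrides) -> ScenarioConfig:
    """A scaled-down scenario for fast tests (~0.5 s to build)."""
    params = dict(
        seed=seed,
        host_length=60_000,
        n_host_contigs=10,
        bgc_length=8_000,
        depth=40.0,
        read_length=100,
        insert_mean=250.0,
        insert_sd=25.0,
        n_genes={
            "annotated": 15,
            "hypothetical": 15,
            "pseudogene": 8,
            "ribosomal": 12,
            "bgc": 12,
        },
        gene_length_range=(60, 120),
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def tiny_scenario_config(seed: int = 1, **overrides) -> ScenarioConfig:
    """Minimal scenario for seed sweeps (~0.2 s to build)."""
    params = dict(
        seed=seed,
        host_length=24_000,
        n_host_contigs=8,
        bgc_length=4_000,
        depth=30.0,
        read_length=100,
        insert_mean=250.0,
        insert_sd=25.0,
        n_genes={
            "annotated": 6,
            "hypothetical": 6,
            "pseudogene": 4,
            "ribosomal": 6,
            "bgc": 6,
        },
        gene_length_range=(60, 100),
    )
    params.update(overrides)
    return ScenarioConfig(**params)


@pytest.fixture(scope="session")
def default_bundle():
    """The default scenario at seed 1 (the acceptance workhorse)."""
    return build_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    return build_scenario(small_scenario_config(seed=1))


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    """Small scenario written to disk for file-format round-trip tests."""
    outdir = tmp_path_factory.mktemp("scenario")
    bundle = build_scenario(small_scenario_config(seed=1), outdir=outdir)
    return bundle
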