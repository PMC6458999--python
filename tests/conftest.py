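import pytest

from pasfactory.pipeline import RunConfig, run_pipeline
from pasfactory.synthetic import SimConfig, simulate_genome


def tiny_config(seed: int = 11) -> SimConfig:
    """A 60-gene chromosome with proportionally scaled planted effects."""
    return SimConfig(
        n_genes=60, chrom_length=2_200_000,
        n_shifted=8, n_attenuated=9, n_de_up=4, n_de_down=4,
        n_shared_regions=12, n_unique_regions=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """(genome, genes, ledger) for a small simulated chromosome."""
    return simulate_genome(tiny_config())


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study conditions (200 genes)."""
    return run_pipeline(RunConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_run():
    """Full pipeline run on the small chromosome (for determinism/CLI tests)."""
    cfg = RunConfig(sim=tiny_config(), seed=11)
    return run_pipeline(cfg)


@pytest.fixture()
def tiny_cfg():
    return tiny_config()
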