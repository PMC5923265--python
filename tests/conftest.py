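import pytest

from divatac import cli
from divatac.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small synthetic dataset for unit-level checks."""
    out = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(
        seed=11,
        n_genes=120,
        regions_per_gene=8,
        n_motifs_up=2,
        n_motifs_down=2,
        occurrences_per_motif=20,
    )
    return cfg, simulate(cfg, out)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic configuration (seed 7)."""
    out = tmp_path_factory.mktemp("default_run")
    for stage in cli._ALL_ORDER:
        cli._STAGES[stage]({}, out, None)
    return out
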