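import pytest

from beepan.sim import PangenomeSimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A reduced pangenome (2 groups x 3 strains, 40 core + 15 accessory)."""
    cfg = PangenomeSimConfig(seed=7, core_families=40, accessory_families=15)
    return simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The full default study pangenome (200 core + 150 accessory, seed 1)."""
    return simulate_pangenome(PangenomeSimConfig(seed=1))
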