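import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from estpoly import GenotypePanel, SimConfig
from estpoly.simdata import simulate_panel, simulate_pileup


@pytest.fixture(scope="session")
def panel3():
    return GenotypePanel(("RILpool", "inbredA", "inbredB"))


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete simulated panel shared across tests."""
    cfg = SimConfig(seed=424243, n_contigs=12, contig_length=1500)
    sim = simulate_panel(cfg)
    pileups = simulate_pileup(sim)
    return sim, pileups


@pytest.fixture(scope="session")
def sim_full():
    """The study-scale simulation: 100 contigs x 2 kb, 3 samples, 40x, 0.5% error."""
    cfg = SimConfig(seed=1729)
    sim = simulate_panel(cfg)
    pileups = simulate_pileup(sim)
    return sim, pileups
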