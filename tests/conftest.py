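import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the bruteforce oracles

from fragrank.chem import build_metabolite_graph, parse_molecule
from fragrank.fixtures import (
    SyntheticConfig,
    default_tables,
    make_recovery_graphs,
    simulate_training_set,
)
from fragrank.fraggraph import build_fragmentation_graph
from fragrank.model import train


@pytest.fixture(scope="session")
def ethanol_graph():
    return build_metabolite_graph(parse_molecule("CCO", "ethanol"))


@pytest.fixture(scope="session")
def ethanol_fg(ethanol_graph):
    return build_fragmentation_graph(ethanol_graph)


@pytest.fixture(scope="session")
def sim_setup():
    """Small simulated training world shared across model/search tests."""
    config = SyntheticConfig(seed=7)
    cond, null = default_tables()
    graphs = make_recovery_graphs(config, 8)
    return config, cond, null, graphs


@pytest.fixture(scope="session")
def small_model(sim_setup):
    config, cond, null, graphs = sim_setup
    pairs = simulate_training_set(graphs, cond, null, config, seed=11, n_spectra=300)
    return train(pairs, pseudocount=1.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
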