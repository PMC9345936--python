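import numpy as np
import pytest

from endoflux import pipeline, synthdata
from endoflux.netcore import MetabolicNetwork


@pytest.fixture(scope="session")
def toy_net():
    return synthdata.make_toy_network()


@pytest.fixture(scope="session")
def toy_catalogue():
    return synthdata.toy_activity_catalogue()


@pytest.fixture(scope="session")
def toy_mapping():
    return synthdata.toy_transport_mapping()


@pytest.fixture(scope="session")
def baseline_q(toy_net, toy_mapping):
    """Measured-transport quartiles, sampled once for the whole suite."""
    return pipeline.baseline_quartiles(
        toy_net, n_samples=1000, seed=0,
        transport_ids=sorted(set(toy_mapping["reaction_id"])),
    )


def chain_network(uptake_cap=5.0):
    """EX_A -> (A -> B) -> EX_B linear chain; uptake of A capped."""
    S = np.array(
        [
            # EX_A  R_AB  EX_B
            [-1.0, -1.0, 0.0],  # A
            [0.0, 1.0, -1.0],  # B
        ]
    )
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "R_AB", "EX_B"],
        S=S,
        lb=np.array([-uptake_cap, 0.0, 0.0]),
        ub=np.array([0.0, 1000.0, 1000.0]),
        transport_ids=["EX_A", "EX_B"],
    )


def branch_network(uptake_cap=4.0):
    """A -> B + C with uptake of A capped; two secretion routes."""
    S = np.array(
        [
            # EX_A  R1  EX_B  EX_C
            [-1.0, -1.0, 0.0, 0.0],  # A
            [0.0, 1.0, -1.0, 0.0],  # B
            [0.0, 1.0, 0.0, -1.0],  # C
        ]
    )
    return MetabolicNetwork(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=["EX_A", "R1", "EX_B", "EX_C"],
        S=S,
        lb=np.array([-uptake_cap, 0.0, 0.0, 0.0]),
        ub=np.array([0.0, 1000.0, 1000.0, 1000.0]),
        transport_ids=["EX_A", "EX_B", "EX_C"],
    )


@pytest.fixture
def chain_net():
    return chain_network()


@pytest.fixture
def branch_net():
    return branch_network()
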