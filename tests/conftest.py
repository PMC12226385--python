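import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None, deadline=None)
settings.load_profile("deterministic")

from cprnet.agent_decision import AgentState
from cprnet.expectation_hsm import HeuristicState, HsmParams, SnapshotHistory
from cprnet.network_gen import NetworkModel
from cprnet.payoff_model import default_affine, default_incentives


@pytest.fixture
def incentives():
    return default_incentives()


@pytest.fixture
def affine():
    return default_affine()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_agent(degree=4, strategy=1, perceived_n=0.5, z0=0.5, ledger=None,
               current=1, agent_id=0):
    return AgentState(
        id=agent_id,
        degree=degree,
        strategy=strategy,
        perceived_n=perceived_n,
        history=SnapshotHistory.cold_start(z0),
        heuristics=HeuristicState.cold_start(z0, current),
        ledger=ledger,
    )


@pytest.fixture
def agent_factory():
    return make_agent


def star_network(n_leaves: int) -> NetworkModel:
    """Hub node 0 connected to leaves 1..n_leaves."""
    P = n_leaves + 1
    indptr = np.concatenate([[0, n_leaves], n_leaves + np.arange(1, P)])
    indices = np.concatenate([np.arange(1, P), np.zeros(n_leaves, dtype=np.int64)])
    degrees = np.concatenate([[n_leaves], np.ones(n_leaves, dtype=np.int64)])
    is_hub = np.zeros(P, dtype=bool)
    is_hub[0] = True
    return NetworkModel(
        node_count=P, attachment_count=1,
        indptr=indptr.astype(np.int64), indices=indices.astype(np.int64),
        degrees=degrees.astype(np.int64),
        initial_node_ids=np.arange(1, P, dtype=np.int64), is_hub=is_hub,
    )


@pytest.fixture
def star10():
    return star_network(9)
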