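import numpy as np
import pytest

from gutflow import (
    CommunitySample,
    CrossFeedingNetwork,
    FlowParameters,
    IntakeProfile,
)


@pytest.fixture
def chain_net():
    """A -> m1 -> B -> m2 food chain fed by m0; m2 has no consumer."""
    return CrossFeedingNetwork(
        species=["A", "B"],
        metabolites=["m0", "m1", "m2"],
        consumption_edges=[("A", "m0"), ("B", "m1")],
        production_edges=[("A", "m1"), ("B", "m2")],
    )


@pytest.fixture
def chain_sample():
    return CommunitySample("chain", {"A": 0.5, "B": 0.5})


@pytest.fixture
def chain_intake():
    return IntakeProfile({"m0": 1.0})


@pytest.fixture
def single_species_net():
    """One species eats the intake, secretes one inedible byproduct."""
    return CrossFeedingNetwork(
        species=["A"],
        metabolites=["m0", "m1"],
        consumption_edges=[("A", "m0")],
        production_edges=[("A", "m1")],
    )


def random_instance(rng, n_species=None, n_metabolites=None, allow_sink=True):
    """A random network + sample + intake + parameters for property tests."""
    S = n_species or int(rng.integers(3, 61))
    M = n_metabolites or int(rng.integers(4, 81))
    species = [f"s{k}" for k in range(S)]
    metabolites = [f"m{k}" for k in range(M)]
    ec, ep = set(), set()
    for sp in species:
        for m in rng.choice(M, size=int(rng.integers(1, min(M, 5) + 1)), replace=False):
            ec.add((sp, metabolites[m]))
        n_out = int(rng.integers(0 if allow_sink else 1, min(M, 5) + 1))
        for m in rng.choice(M, size=n_out, replace=False):
            ep.add((sp, metabolites[m]))
    net = CrossFeedingNetwork(species, metabolites, ec, ep)
    ab = rng.dirichlet(np.ones(S))
    sample = CommunitySample("rand", dict(zip(species, ab)))
    n_intake = int(rng.integers(1, min(M, 10) + 1))
    picks = rng.choice(M, size=n_intake, replace=False)
    amounts = rng.uniform(0.1, 1.0, size=n_intake)
    intake = IntakeProfile({metabolites[m]: float(a) for m, a in zip(picks, amounts)})
    params = FlowParameters(
        f=float(rng.uniform(0.1, 0.99)), n_levels=int(rng.integers(1, 11))
    )
    return net, sample, intake, params
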