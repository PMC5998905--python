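"""Shared fixtures: tiny hand-built networks and a standard planted scenario."""

from __future__ import annotations

import numpy as np
import pytest

from fluxshift.network import MetabolicNetwork, Metabolite, Reaction
from fluxshift.synthetic import make_network, make_scenario


@pytest.fixture(scope="session")
def scenario():
    """Noiseless 4-sample planted scenario (session-wide, read-only)."""
    return make_scenario(seed=11)


@pytest.fixture()
def chain_network() -> MetabolicNetwork:
    """EX_in -> A -> B -> EX_out with uptake capacity 10 (single route)."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_in", {"A": 1.0}, 0.0, 10.0),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_out", {"B": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns)


@pytest.fixture()
def branch_network() -> MetabolicNetwork:
    """A -> B directly or via C; uptake capacity 10; all irreversible."""
    mets = [Metabolite(m) for m in ("A", "B", "C")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0.0, 1000.0),
        Reaction("R_CB", {"C": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicNetwork(mets, rxns)


def random_flagged_instance(rng: np.random.Generator, max_flags: int = 6):
    """Small random network plus random +-1 reaction flags (shared helper)."""
    n_chains = int(rng.integers(1, 3))
    n_branch = int(rng.integers(max(0, n_chains - 1), 3))
    net = make_network(
        n_chains,
        n_branch,
        float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**31)),
        chain_length_range=(3, 4),
    )
    rxn_ids = [r.id for r in net.reactions]
    m = min(int(rng.integers(2, max_flags + 1)), len(rxn_ids))
    chosen = rng.choice(len(rxn_ids), size=m, replace=False)
    states = {rxn_ids[i]: int(rng.choice([-1, 1])) for i in sorted(chosen)}
    return net, states
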