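"""Naive reference implementations used as cross-checks.

These deliberately avoid the production code paths: the iMAT objective is
recomputed by exhaustively enumerating which flagged reactions to satisfy
(and in which direction) and testing plain LP feasibility of the implied
bound tightenings, and the hypergeometric upper tail is summed from exact
binomial coefficients.  They are exponential/quadratic and only meant for
small instances in tests and validation runs.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb
from typing import Mapping

from .fba import is_feasible
from .network import MetabolicNetwork

__all__ = ["brute_force_imat_objective", "hypergeometric_tail_exact"]


def brute_force_imat_objective(
    network: MetabolicNetwork,
    states: Mapping[str, int],
    epsilon: float = 1.0,
) -> int:
    """Maximum number of satisfiable expression flags, by enumeration.

    For every subset of flagged reactions (largest first) and every
    direction assignment of the highly-expressed members, tighten the
    bounds accordingly (|v| >= epsilon for high, v = 0 for low) and test LP
    feasibility; the first feasible subset size is the optimum.
    """
    flagged = sorted((r, s) for r, s in states.items() if s != 0)
    directions: list[list[tuple[float, float]]] = []
    for rid, state in flagged:
        rxn = network.reaction(rid)
        if state == 1:
            opts = [(max(rxn.lower_bound, epsilon), rxn.upper_bound)]
            if rxn.lower_bound < 0:
                opts.append((rxn.lower_bound, min(rxn.upper_bound, -epsilon)))
        else:
            opts = [(0.0, 0.0)]
        directions.append(opts)

    m = len(flagged)
    for size in range(m, 0, -1):
        for chosen in combinations(range(m), size):
            for combo in product(*(directions[i] for i in chosen)):
                overrides = {
                    flagged[i][0]: bounds for i, bounds in zip(chosen, combo)
                }
                if is_feasible(network, overrides):
                    return size
    return 0 if is_feasible(network, {}) else 0


def hypergeometric_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact combinatorial sum."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom
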