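"""Linear-programming services: steady-state feasibility, FVA, rate limiting.

All LPs share the constraint set of flux balance analysis — S.v = 0 with
per-reaction bounds — and are solved with HiGHS (scipy.optimize.linprog),
which is deterministic for a fixed problem.  No biomass objective is
imposed anywhere: flux variability analysis here is purely feasibility
based, because the expression-integration workflow it supports does not
predefine an objective function.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .network import MetabolicNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .imat import TissueModel

__all__ = [
    "InfeasibleError",
    "solve_lp",
    "is_feasible",
    "fva",
    "rate_limiting",
]

_ROUND_DECIMALS = 9  # output rounding: keeps files byte-stable, kills -0.0


class InfeasibleError(RuntimeError):
    """The steady-state constraint set admits no flux vector."""


def _effective_bounds(
    network: MetabolicNetwork,
    bound_overrides: Mapping[str, tuple[float, float]] | None,
) -> list[tuple[float, float]]:
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    if bound_overrides:
        index = network.reaction_index
        for rid, (lb, ub) in bound_overrides.items():
            bounds[index[rid]] = (lb, ub)
    return bounds


def solve_lp(
    network: MetabolicNetwork,
    c: np.ndarray,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
):
    """Minimize c.v subject to S.v = 0 and (possibly overridden) bounds."""
    S = csr_matrix(network.stoichiometric_matrix)
    bounds = _effective_bounds(network, bound_overrides)
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )


def is_feasible(
    network: MetabolicNetwork,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> bool:
    """Whether any steady-state flux vector satisfies the (overridden) bounds."""
    res = solve_lp(network, np.zeros(len(network)), bound_overrides)
    return res.status == 0


def fva(
    network: MetabolicNetwork,
    fixed_constraints: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction (minflux, maxflux).

    Solves 2|R| LPs (minimize and maximize each flux) over S.v = 0 and
    bounds, optionally tightened by ``fixed_constraints`` (reaction id ->
    (lb, ub)).  Results are clipped into the reaction bounds and rounded to
    9 decimals so repeated runs serialize identically.
    """
    n = len(network)
    if not is_feasible(network, fixed_constraints):
        raise InfeasibleError("network has no steady-state flux solution")
    bounds = _effective_bounds(network, fixed_constraints)
    out: dict[str, tuple[float, float]] = {}
    c = np.zeros(n)
    for j, rxn in enumerate(network.reactions):
        lo_b, hi_b = bounds[j]
        c[j] = 1.0
        res_min = solve_lp(network, c, fixed_constraints)
        c[j] = -1.0
        res_max = solve_lp(network, c, fixed_constraints)
        c[j] = 0.0
        if res_min.status != 0 or res_max.status != 0:
            raise InfeasibleError(f"FVA LP failed for reaction {rxn.id}")
        vmin = float(np.clip(round(res_min.fun, _ROUND_DECIMALS), lo_b, hi_b))
        vmax = float(np.clip(round(-res_max.fun, _ROUND_DECIMALS), lo_b, hi_b))
        if vmin > vmax:  # numerical crossing at equality
            vmin = vmax = (vmin + vmax) / 2
        out[rxn.id] = (vmin + 0.0, vmax + 0.0)
    return out


def rate_limiting(
    model: "TissueModel",
    network: MetabolicNetwork,
    tol: float = 1e-6,
    include_reverse: bool = False,
) -> set[str]:
    """Reactions whose simulated flux attains its upper bound (rate-limiting).

    A reaction saturating its flux capacity cannot carry more flux, so it
    limits the pathway it sits on.  Uses the generic network's bounds.
    Reactions with a non-positive upper bound are skipped (zero flux
    trivially "attains" ub = 0 without any saturation meaning).  With
    ``include_reverse`` reactions pinned at a negative lower bound are
    reported too.
    """
    limited: set[str] = set()
    for rid, v in model.fluxes.items():
        rxn = network.reaction(rid)
        if rxn.upper_bound > tol and v >= rxn.upper_bound - tol:
            limited.add(rid)
        elif include_reverse and rxn.lower_bound < -tol and v <= rxn.lower_bound + tol:
            limited.add(rid)
    return limited
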