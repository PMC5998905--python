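"""iMAT: context-specific model extraction by expression-consistency MILP.

Given trilean reaction states derived from expression (R_H highly
expressed, R_L lowly expressed), iMAT finds a steady-state flux vector
maximizing the number of reactions whose flux activity agrees with their
state: a reaction in R_H counts as satisfied when it carries flux of
magnitude at least ``epsilon`` (in either direction if reversible), a
reaction in R_L when it carries zero flux.  No biomass or other objective
function is required.  The tissue-specific model is then the set of
reactions active in the resulting flux distribution.

The MILP uses one binary per direction of each flagged reaction with the
standard bound-shifted (big-M) linearization of the activation
implications.  Because MILP solvers are free to return any flux vertex of
the optimal face, the returned flux vector is canonicalized: the integer
assignment is fixed and a second LP minimizes the total absolute flux
(sum |v_r|), making outputs reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix, hstack, identity, lil_matrix, vstack

from .expression import ExpressionStateMap
from .gpr import evaluate_gpr
from .network import MetabolicNetwork

__all__ = [
    "ImatError",
    "ImatSolution",
    "TissueModel",
    "reaction_states",
    "solve_imat",
    "extract_tissue_model",
    "active_set_overlap",
]

_ROUND_DECIMALS = 9


class ImatError(RuntimeError):
    """Solver failure or invalid use of an iMAT solution."""


@dataclass
class ImatSolution:
    """Outcome of one iMAT solve.

    ``objective`` counts expression-consistent reactions
    (= |satisfied_high| + |satisfied_low|); ``fluxes`` is the canonicalized
    (minimum total absolute flux) optimal steady-state flux vector.
    """

    fluxes: dict[str, float]
    objective: int
    satisfied_high: set[str]
    satisfied_low: set[str]
    status: str  # "optimal" | "infeasible" | "time-limit"
    epsilon: float = 1.0


@dataclass
class TissueModel:
    """Tissue-specific model: the active-reaction subnetwork and its fluxes."""

    tissue: str
    active_reactions: set[str]
    fluxes: dict[str, float]
    epsilon: float
    source_states: dict[str, int] = field(default_factory=dict)


def reaction_states(
    network: MetabolicNetwork,
    gene_states: ExpressionStateMap,
    sample: str,
) -> dict[str, int]:
    """Map one sample's gene states through each reaction's GPR.

    AND = min, OR = max over {-1, 0, +1}; reactions with an empty GPR
    (exchanges, spontaneous reactions) are unconstrained (0).
    """
    states = gene_states.states(sample)
    return {
        rxn.id: evaluate_gpr(rxn.gpr, states) for rxn in network.reactions
    }


def _build_milp(
    network: MetabolicNetwork,
    states: Mapping[str, int],
    epsilon: float,
):
    """Assemble (c, integrality, bounds, constraints, binary column map)."""
    n = len(network)
    lb, ub = network.bounds_arrays()
    high = [network.reaction_index[r] for r, s in states.items() if s == 1]
    low = [network.reaction_index[r] for r, s in states.items() if s == -1]
    high.sort()
    low.sort()

    binary_cols: list[tuple[str, int]] = []  # (kind, reaction index)
    rows: list[dict[int, float]] = []
    row_lo: list[float] = []
    row_hi: list[float] = []

    def add_row(coeffs: dict[int, float], lo: float, hi: float) -> None:
        rows.append(coeffs)
        row_lo.append(lo)
        row_hi.append(hi)

    for j in high:
        yp = n + len(binary_cols)
        binary_cols.append(("high_fwd", j))
        # yp = 1  =>  v_j >= epsilon   (yp = 0 leaves v_j >= lb_j)
        add_row({j: 1.0, yp: lb[j] - epsilon}, lb[j], np.inf)
        if lb[j] < 0:
            ym = n + len(binary_cols)
            binary_cols.append(("high_rev", j))
            # ym = 1  =>  v_j <= -epsilon
            add_row({j: 1.0, ym: ub[j] + epsilon}, -np.inf, ub[j])
            add_row({yp: 1.0, ym: 1.0}, -np.inf, 1.0)
    for j in low:
        y = n + len(binary_cols)
        binary_cols.append(("low", j))
        # y = 1  =>  v_j = 0
        add_row({j: 1.0, y: ub[j]}, -np.inf, ub[j])
        add_row({j: 1.0, y: lb[j]}, lb[j], np.inf)

    nb = len(binary_cols)
    total = n + nb
    A = lil_matrix((len(rows), total))
    for i, coeffs in enumerate(rows):
        for col, val in coeffs.items():
            A[i, col] = val
    S = network.stoichiometric_matrix
    S_ext = hstack([S, csr_matrix((S.shape[0], nb))]).tocsr()

    constraints = [
        LinearConstraint(S_ext, 0.0, 0.0),
    ]
    if rows:
        constraints.append(LinearConstraint(A.tocsr(), row_lo, row_hi))

    c = np.zeros(total)
    c[n:] = -1.0  # maximize number of satisfied flags
    integrality = np.zeros(total)
    integrality[n:] = 1
    var_bounds = Bounds(
        np.concatenate([lb, np.zeros(nb)]),
        np.concatenate([ub, np.ones(nb)]),
    )
    return c, integrality, var_bounds, constraints, binary_cols


def _min_abs_flux_lp(
    network: MetabolicNetwork,
    overrides: Mapping[str, tuple[float, float]],
) -> np.ndarray | None:
    """Minimize sum |v| over S.v = 0 with the given bound overrides."""
    n = len(network)
    lb, ub = network.bounds_arrays()
    for rid, (lo, hi) in overrides.items():
        j = network.reaction_index[rid]
        lb[j], ub[j] = lo, hi
    S = network.stoichiometric_matrix
    m = S.shape[0]
    # variables [v, t]; minimize 1.t with t >= v and t >= -v
    A_eq = hstack([S, csr_matrix((m, n))]).tocsr()
    eye = identity(n, format="csr")
    A_ub = vstack([hstack([eye, -eye]), hstack([-eye, -eye])]).tocsr()
    c = np.concatenate([np.zeros(n), np.ones(n)])
    t_hi = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n), t_hi))
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(m),
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def solve_imat(
    network: MetabolicNetwork,
    states: Mapping[str, int],
    epsilon: float = 1.0,
    time_limit: float = 60.0,
) -> ImatSolution:
    """Solve the iMAT MILP for one sample's reaction states.

    Parameters
    ----------
    states
        Reaction id -> trilean state; +1 joins R_H, -1 joins R_L, 0 is
        unconstrained.  Keys must be network reaction ids.
    epsilon
        Activation threshold (flux units): the minimum |flux| for a
        reaction in R_H to count as active.  Must be positive and should be
        well below the R_H reactions' capacity.
    time_limit
        MILP wall-clock limit in seconds; on hitting it the best incumbent
        (if any) is returned with status ``"time-limit"``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    unknown = set(states) - set(network.reaction_index)
    if unknown:
        raise KeyError(f"states reference unknown reactions {sorted(unknown)[:5]}")
    high_ids = [r for r, s in states.items() if s == 1]
    if high_ids:
        cap = min(
            max(abs(network.reaction(r).upper_bound), abs(network.reaction(r).lower_bound))
            for r in high_ids
        )
        if epsilon >= cap:
            warnings.warn(
                f"epsilon={epsilon} is not below the smallest R_H capacity {cap}; "
                "those reactions can never be satisfied",
                stacklevel=2,
            )

    c, integrality, var_bounds, constraints, binary_cols = _build_milp(
        network, states, epsilon
    )
    n = len(network)
    if not binary_cols:
        # no flags: objective 0; canonical flux is the minimum-|v| vector
        v = _min_abs_flux_lp(network, {})
        if v is None:
            return ImatSolution({}, 0, set(), set(), "infeasible", epsilon)
        fluxes = _round_fluxes(network, v)
        return ImatSolution(fluxes, 0, set(), set(), "optimal", epsilon)

    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=var_bounds,
        options={"time_limit": float(time_limit)},
    )
    if res.status == 2:
        return ImatSolution({}, 0, set(), set(), "infeasible", epsilon)
    if res.x is None:
        if res.status == 1:
            return ImatSolution({}, 0, set(), set(), "time-limit", epsilon)
        raise ImatError(f"MILP solver failure: {res.message}")
    status = "optimal" if res.status == 0 else "time-limit"

    binaries = np.round(res.x[n:]).astype(int)
    satisfied_high: set[str] = set()
    satisfied_low: set[str] = set()
    overrides: dict[str, tuple[float, float]] = {}
    for (kind, j), y in zip(binary_cols, binaries):
        if y != 1:
            continue
        rxn = network.reactions[j]
        if kind == "high_fwd":
            satisfied_high.add(rxn.id)
            overrides[rxn.id] = (max(rxn.lower_bound, epsilon), rxn.upper_bound)
        elif kind == "high_rev":
            satisfied_high.add(rxn.id)
            overrides[rxn.id] = (rxn.lower_bound, min(rxn.upper_bound, -epsilon))
        else:
            satisfied_low.add(rxn.id)
            overrides[rxn.id] = (0.0, 0.0)
    objective = len(satisfied_high) + len(satisfied_low)

    v = _min_abs_flux_lp(network, overrides)
    if v is None:  # canonicalization LP should inherit MILP feasibility
        v = res.x[:n]
    fluxes = _round_fluxes(network, v)
    return ImatSolution(fluxes, objective, satisfied_high, satisfied_low, status, epsilon)


def _round_fluxes(network: MetabolicNetwork, v: np.ndarray) -> dict[str, float]:
    return {
        rxn.id: float(round(val, _ROUND_DECIMALS) + 0.0)
        for rxn, val in zip(network.reactions, v)
    }


def extract_tissue_model(
    network: MetabolicNetwork,
    solution: ImatSolution,
    tissue: str,
    activity_tol: float = 1e-6,
    source_states: Mapping[str, int] | None = None,
) -> TissueModel:
    """Keep only reactions carrying flux above ``activity_tol`` (numerical zero)."""
    if solution.status != "optimal":
        raise ImatError(
            f"cannot extract a tissue model from a {solution.status} solution"
        )
    active = {r for r, v in solution.fluxes.items() if abs(v) > activity_tol}
    if not active:
        warnings.warn(f"tissue {tissue}: all-zero flux vector, empty model", stacklevel=2)
    return TissueModel(
        tissue=tissue,
        active_reactions=active,
        fluxes=dict(solution.fluxes),
        epsilon=solution.epsilon,
        source_states=dict(source_states or {}),
    )


def active_set_overlap(models: list[TissueModel]) -> dict[str, int]:
    """Counts of every intersection region of the models' active sets.

    For k models there are 2^k - 1 non-empty membership patterns; each is
    labeled by the ``&``-joined tissue names whose models contain exactly
    that region's reactions.  The full intersection is additionally
    reported under ``"shared"`` (the count of reactions active in every
    model).
    """
    if len(models) < 2:
        raise ValueError("need at least two tissue models")
    key_sets = [frozenset(m.fluxes) for m in models]
    if len(set(key_sets)) != 1:
        raise ValueError("tissue models come from different networks")
    names = [m.tissue for m in models]
    actives = [m.active_reactions for m in models]
    union = set().union(*actives)
    counts: dict[str, int] = {}
    k = len(models)
    for pattern in range(1, 2**k):
        members = [i for i in range(k) if pattern >> i & 1]
        region = set(union)
        for i in range(k):
            if i in members:
                region &= actives[i]
            else:
                region -= actives[i]
        counts["&".join(names[i] for i in members)] = len(region)
    counts["shared"] = len(set.intersection(*actives)) if actives else 0
    return counts
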