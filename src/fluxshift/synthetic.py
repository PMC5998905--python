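"""Synthetic networks and expression tables with planted ground truth.

The generator emulates, at toy scale, a multi-tissue expression-to-flux
study: a stoichiometric network of parallel pathways (linear chains fed
and drained by exchange reactions, cross-linked at branch points), GPR
rules of mixed forms, and per-sample expression tables in which the genes
of designated pathways are driven into the top or bottom expression
stratum.  The planted truth (which reactions each sample should activate
or silence, and which pathways differ between designated sample pairs)
ships with the scenario so every pipeline stage can be checked exactly.

Stratum construction guarantees that at zero noise the per-sample
15%/15% quantile discretization recovers the planted gene states exactly:
filler (non-model) genes pad each stratum so the high and low classes have
exactly the nominal count, and the strata are separated by wide value gaps
so the cutoffs fall between them.

Exchange reactions carry a small capacity (default 1.5 flux units, versus
the +-1000 internal bounds) so that an activated pathway's flux — pinned
near the activation threshold epsilon by the canonical minimum-|v|
optimum — is a large fraction of each reaction's flux-variability range.
That reproduces the regime of real tissue-model studies, where simulated
fluxes approach their variability bounds and the FVA-normalized change
ratio is informative.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .fba import is_feasible
from .network import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    write_tabular,
)
from .gpr import parse_gpr

__all__ = [
    "GenerationError",
    "SyntheticScenario",
    "make_network",
    "plant_expression",
    "make_scenario",
]

# expression strata (FPKM): separated by wide gaps so quantile cutoffs
# always fall between strata at zero noise
_LOW_STRATUM = (0.1, 1.0)
_MID_STRATUM = (10.0, 20.0)
_HIGH_STRATUM = (100.0, 200.0)


class GenerationError(RuntimeError):
    """A requested scenario is internally inconsistent or unrealizable."""


@dataclass
class SyntheticScenario:
    """A generated study: network + expression + manifest + planted truth."""

    network: MetabolicNetwork
    expression: ExpressionTable
    manifest: pd.DataFrame  # columns sample_id, stage, order
    truth: dict
    seed: int

    @property
    def samples(self) -> list[str]:
        return list(self.manifest["sample_id"])

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_tabular(self.network, os.path.join(outdir, "model.tsv"))
        self.expression.to_tsv(os.path.join(outdir, "expression.tsv"))
        self.manifest.to_csv(
            os.path.join(outdir, "manifest.tsv"), sep="\t", index=False,
            lineterminator="\n",
        )
        with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_network(
    n_linear_chains: int,
    n_branch_points: int,
    reversible_fraction: float,
    seed: int,
    chain_length_range: tuple[int, int] = (4, 6),
    exchange_capacity: float = 1.5,
    link_capacity: float = 0.2,
) -> MetabolicNetwork:
    """Generate a connected toy network of chains with cross-links.

    Each chain c is ``EX_c_in -> Mc_1 -> ... -> Mc_L -> EX_c_out`` with one
    subsystem label (``pathway_c``) on its internal reactions; the first
    ``n_linear_chains - 1`` branch reactions link consecutive chains (so the
    network is connected), the rest are random cross-links.  Internal
    reactions get bounds [-1000, 1000] when drawn reversible (probability
    ``reversible_fraction``), else [0, 1000]; exchanges are irreversible
    with capacity ``exchange_capacity``.  GPRs cycle through single-gene,
    AND-pair and OR-pair forms with private genes per reaction.
    """
    if n_linear_chains < 1:
        raise ValueError("need at least one chain")
    if not (0 <= reversible_fraction <= 1):
        raise ValueError("reversible_fraction must be in [0, 1]")
    if n_branch_points < n_linear_chains - 1:
        raise ValueError(
            "need at least n_linear_chains - 1 branch points to connect the chains"
        )
    rng = np.random.default_rng(seed)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    chain_mets: list[list[str]] = []
    gene_counter = 0

    def next_gpr() -> str:
        nonlocal gene_counter
        form = int(rng.integers(0, 3))
        if form == 0:
            gene_counter += 1
            return f"g{gene_counter:03d}"
        gene_counter += 2
        op = "and" if form == 1 else "or"
        return f"g{gene_counter - 1:03d} {op} g{gene_counter:03d}"

    def internal_bounds() -> tuple[float, float]:
        if rng.random() < reversible_fraction:
            return (-DEFAULT_BOUND, DEFAULT_BOUND)
        return (0.0, DEFAULT_BOUND)

    for c in range(1, n_linear_chains + 1):
        length = int(rng.integers(chain_length_range[0], chain_length_range[1] + 1))
        mets = [f"M{c}_{i}" for i in range(1, length + 1)]
        chain_mets.append(mets)
        metabolites.extend(Metabolite(id=m) for m in mets)
        reactions.append(
            Reaction(
                id=f"EX_{c}_in",
                stoichiometry={mets[0]: 1.0},
                lower_bound=0.0,
                upper_bound=exchange_capacity,
                subsystem="exchange",
                is_exchange=True,
            )
        )
        for i in range(length - 1):
            lb, ub = internal_bounds()
            reactions.append(
                Reaction(
                    id=f"R{c}_{i + 1}",
                    stoichiometry={mets[i]: -1.0, mets[i + 1]: 1.0},
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=parse_gpr(next_gpr()),
                    subsystem=f"pathway_{c}",
                )
            )
        reactions.append(
            Reaction(
                id=f"EX_{c}_out",
                stoichiometry={mets[-1]: -1.0},
                lower_bound=0.0,
                upper_bound=exchange_capacity,
                subsystem="exchange",
                is_exchange=True,
            )
        )

    for b in range(n_branch_points):
        if b < n_linear_chains - 1:
            src_chain, dst_chain = b, b + 1
        elif n_linear_chains >= 2:
            src_chain, dst_chain = (
                int(i) for i in rng.choice(n_linear_chains, size=2, replace=False)
            )
        else:
            src_chain = dst_chain = 0
        src = chain_mets[src_chain][int(rng.integers(0, len(chain_mets[src_chain])))]
        dst = chain_mets[dst_chain][int(rng.integers(0, len(chain_mets[dst_chain])))]
        if src == dst:  # within-chain shunt must connect distinct metabolites
            dst = chain_mets[dst_chain][
                (chain_mets[dst_chain].index(src) + 1) % len(chain_mets[dst_chain])
            ]
        # links are minor shunts: low capacity so they connect the chains
        # without dominating any pathway's flux-variability range
        reactions.append(
            Reaction(
                id=f"LNK_{b + 1}",
                stoichiometry={src: -1.0, dst: 1.0},
                lower_bound=0.0,
                upper_bound=link_capacity,
                gpr=parse_gpr(next_gpr()),
                subsystem="linker",
            )
        )
    return MetabolicNetwork(metabolites, reactions)


def _pathway_members(
    network: MetabolicNetwork,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Pathway -> reaction ids and pathway -> gene ids (plantable pathways)."""
    rxns: dict[str, list[str]] = {}
    genes: dict[str, list[str]] = {}
    for rxn in network.reactions:
        if not rxn.subsystem or rxn.gpr.is_empty:
            continue
        rxns.setdefault(rxn.subsystem, []).append(rxn.id)
        genes.setdefault(rxn.subsystem, []).extend(sorted(rxn.genes))
    return rxns, genes


def plant_expression(
    network: MetabolicNetwork,
    samples: Sequence[str],
    active_plan: Mapping[str, Mapping[str, str]],
    noise_sd: float = 0.0,
    seed: int = 0,
    low_q: float = 0.15,
    high_q: float = 0.15,
    epsilon: float = 1.0,
) -> tuple[ExpressionTable, dict]:
    """Generate an expression table realizing a per-sample pathway plan.

    ``active_plan`` maps sample id -> {pathway label -> "on" | "off"}.
    Genes of "on" pathways draw from the high stratum, "off" from the low
    stratum, everything else from the middle stratum; filler genes (ids
    ``bg###``, not in the model) pad the extreme classes to exactly the
    nominal quantile count.  Returns the table and the truth record
    (planted gene states and reaction sets per sample, stratum parameters).

    Every sample's planted reaction sets are checked for steady-state
    realizability (a flux with |v| >= epsilon on all planted-active
    reactions and v = 0 on all planted-inactive ones) at generation time.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    pathway_rxns, pathway_genes = _pathway_members(network)
    for sample, plan in active_plan.items():
        if sample not in samples:
            raise GenerationError(f"plan references unknown sample {sample!r}")
        for pathway, state in plan.items():
            if pathway not in pathway_rxns:
                raise GenerationError(
                    f"sample {sample}: unknown or unplantable pathway {pathway!r}"
                )
            if state not in ("on", "off"):
                raise GenerationError(
                    f"sample {sample}: plan state must be 'on'/'off', got {state!r}"
                )

    model_genes = sorted(network.genes)
    n_model = len(model_genes)
    high_sets: dict[str, set[str]] = {}
    low_sets: dict[str, set[str]] = {}
    for sample in samples:
        plan = active_plan.get(sample, {})
        high: set[str] = set()
        low: set[str] = set()
        for pathway, state in plan.items():
            target = high if state == "on" else low
            target.update(pathway_genes[pathway])
        clash = high & low
        if clash:
            raise GenerationError(
                f"sample {sample}: genes planted both high and low: {sorted(clash)[:5]}"
            )
        high_sets[sample], low_sets[sample] = high, low

    # pad with filler genes so each extreme class has exactly k members
    n_filler = 0
    while True:
        n_total = n_model + n_filler
        k_low = math.ceil(low_q * n_total)
        k_high = math.ceil(high_q * n_total)
        ok = all(
            len(high_sets[s]) <= k_high
            and len(low_sets[s]) <= k_low
            and (k_high - len(high_sets[s])) + (k_low - len(low_sets[s])) <= n_filler
            for s in samples
        )
        if ok:
            break
        n_filler += 1
    fillers = [f"bg{i:03d}" for i in range(1, n_filler + 1)]
    all_genes = model_genes + fillers

    rng = np.random.default_rng(seed)
    values = np.empty((len(all_genes), len(samples)))
    truth_samples: dict[str, dict] = {}
    for col, sample in enumerate(samples):
        high, low = high_sets[sample], low_sets[sample]
        filler_high = set(fillers[: k_high - len(high)])
        filler_low = set(
            fillers[k_high - len(high) : (k_high - len(high)) + (k_low - len(low))]
        )
        states: dict[str, int] = {}
        for row, gene in enumerate(all_genes):
            if gene in high or gene in filler_high:
                lo, hi = _HIGH_STRATUM
                state = 1
            elif gene in low or gene in filler_low:
                lo, hi = _LOW_STRATUM
                state = -1
            else:
                lo, hi = _MID_STRATUM
                state = 0
            value = rng.uniform(lo, hi)
            if noise_sd > 0:
                value = max(value + rng.normal(0.0, noise_sd), 0.0)
            values[row, col] = value
            states[gene] = state
        plan = active_plan.get(sample, {})
        r_high = sorted(
            rid for p, st in plan.items() if st == "on" for rid in pathway_rxns[p]
        )
        r_low = sorted(
            rid for p, st in plan.items() if st == "off" for rid in pathway_rxns[p]
        )
        overrides = {
            rid: (max(network.reaction(rid).lower_bound, epsilon),
                  network.reaction(rid).upper_bound)
            for rid in r_high
        }
        overrides.update({rid: (0.0, 0.0) for rid in r_low})
        if not is_feasible(network, overrides):
            raise GenerationError(
                f"sample {sample}: planted reaction states are not realizable "
                "as a steady-state flux"
            )
        truth_samples[sample] = {
            "gene_states": states,
            "R_high": r_high,
            "R_low": r_low,
        }

    table = ExpressionTable(
        pd.DataFrame(np.round(values, 6), index=all_genes, columns=list(samples))
    )
    truth = {
        "samples": truth_samples,
        "strata": {
            "low": _LOW_STRATUM,
            "mid": _MID_STRATUM,
            "high": _HIGH_STRATUM,
        },
        "noise_sd": noise_sd,
        "epsilon": epsilon,
        "quantiles": {"low_q": low_q, "high_q": high_q},
    }
    return table, truth


def make_scenario(
    seed: int,
    n_samples: int = 4,
    n_chains: int = 6,
    n_branch_points: int = 5,
    reversible_fraction: float = 0.25,
    noise_sd: float = 0.0,
    epsilon: float = 1.0,
) -> SyntheticScenario:
    """Standard study scenario: toggled, constitutive and silent pathways.

    Pathway 1 is on in every sample, pathway 2 off in every sample;
    pathway 3 is on in the first (booting-like) half of the samples and off
    in the second (mature-like) half, pathway 4 the reverse; remaining
    pathways are background.  The planned comparison pair is the last
    booting sample versus the first mature sample, for which pathway 4 is
    the planted up-regulated pathway and pathway 3 the planted
    down-regulated one.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if n_chains < 4:
        raise ValueError("need at least four chains for the standard plan")
    network = make_network(
        n_linear_chains=n_chains,
        n_branch_points=n_branch_points,
        reversible_fraction=reversible_fraction,
        seed=seed,
    )
    half = n_samples // 2
    samples = [
        f"tissue{i + 1}_{'B' if i < half else 'M'}" for i in range(n_samples)
    ]
    stages = ["booting" if i < half else "mature" for i in range(n_samples)]
    plan: dict[str, dict[str, str]] = {}
    for i, sample in enumerate(samples):
        booting = i < half
        plan[sample] = {
            "pathway_1": "on",
            "pathway_2": "off",
            "pathway_3": "on" if booting else "off",
            "pathway_4": "off" if booting else "on",
        }
    expression, truth = plant_expression(
        network,
        samples,
        plan,
        noise_sd=noise_sd,
        seed=seed + 1,
        epsilon=epsilon,
    )
    manifest = pd.DataFrame(
        {
            "sample_id": samples,
            "stage": stages,
            "order": np.arange(1, n_samples + 1),
        }
    )
    truth["planned_pair"] = [samples[half - 1], samples[half]]
    truth["up_pathways"] = ["pathway_4"]
    truth["down_pathways"] = ["pathway_3"]
    truth["toggled_pathways"] = ["pathway_3", "pathway_4"]
    truth["always_on_pathways"] = ["pathway_1"]
    truth["plan"] = plan
    return SyntheticScenario(
        network=network,
        expression=expression,
        manifest=manifest,
        truth=truth,
        seed=seed,
    )
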