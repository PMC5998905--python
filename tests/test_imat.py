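"""iMAT MILP: expression-consistency objective, fluxes and tissue models."""

import numpy as np
import pytest

from fluxshift.imat import (
    ImatError,
    ImatSolution,
    TissueModel,
    active_set_overlap,
    extract_tissue_model,
    reaction_states,
    solve_imat,
)
from fluxshift.network import MetabolicNetwork, Metabolite, Reaction
from fluxshift.reference import brute_force_imat_objective

from conftest import random_flagged_instance


class TestReactionStates:
    def make_net(self, gpr_text):
        from fluxshift.gpr import parse_gpr

        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": 1.0}, 0, 10),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 10, gpr=parse_gpr(gpr_text)),
            Reaction("EX_B", {"B": -1.0}, 0, 10),
        ]
        return MetabolicNetwork(mets, rxns)

    def states_for(self, gpr_text, gene_values):
        net = self.make_net(gpr_text)
        # build the state map directly to control the gene states exactly
        from fluxshift.expression import ExpressionStateMap, SampleStates

        state_map = ExpressionStateMap(
            {"s": SampleStates(states=dict(gene_values), low_cutoff=0, high_cutoff=0)}
        )
        return reaction_states(net, state_map, "s")

    def test_and_of_highs_is_high(self):
        assert self.states_for("g1 and g2", {"g1": 1, "g2": 1})["R1"] == 1

    def test_or_of_low_and_moderate_is_moderate(self):
        assert self.states_for("g1 or g2", {"g1": -1, "g2": 0})["R1"] == 0

    def test_exchange_empty_gpr_unconstrained(self):
        states = self.states_for("g1", {"g1": 1})
        assert states["EX_A"] == 0 and states["EX_B"] == 0


class TestSolveImat:
    def test_branch_network_prefers_consistent_route(self, branch_network):
        """Direct route flagged high, detour flagged low: both satisfiable."""
        solution = solve_imat(branch_network, {"R_AB": 1, "R_AC": -1}, epsilon=1.0)
        assert solution.status == "optimal"
        assert solution.objective == 2
        assert solution.fluxes["R_AB"] >= 1.0 - 1e-9
        assert solution.fluxes["R_AC"] == pytest.approx(0.0, abs=1e-9)
        assert solution.satisfied_high == {"R_AB"}
        assert solution.satisfied_low == {"R_AC"}

    def test_no_flags_zero_objective_zero_flux(self, branch_network):
        solution = solve_imat(branch_network, {})
        assert solution.objective == 0
        assert all(v == 0 for v in solution.fluxes.values())

    def test_mutually_exclusive_highs_one_satisfied(self):
        """Two branches flagged high but only one unit of boundary flux."""
        mets = [Metabolite(m) for m in ("A", "B", "C")]
        rxns = [
            Reaction("EX_A", {"A": 1.0}, 0, 1.0),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0, 1000),
            Reaction("R_AC", {"A": -1.0, "C": 1.0}, 0, 1000),
            Reaction("EX_B", {"B": -1.0}, 0, 1000),
            Reaction("EX_C", {"C": -1.0}, 0, 1000),
        ]
        net = MetabolicNetwork(mets, rxns)
        solution = solve_imat(net, {"R_AB": 1, "R_AC": 1}, epsilon=1.0)
        assert solution.objective == 1

    def test_reversible_high_satisfiable_backwards(self):
        """A reaction that can only carry reverse flux still satisfies R_H."""
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": 1.0}, 0, 10),
            Reaction("R_BA", {"B": -1.0, "A": 1.0}, -1000, 1000),  # must run B<-A
            Reaction("EX_B", {"B": -1.0}, 0, 10),
        ]
        net = MetabolicNetwork(mets, rxns)
        solution = solve_imat(net, {"R_BA": 1}, epsilon=1.0)
        assert solution.objective == 1
        assert solution.fluxes["R_BA"] <= -1.0 + 1e-9

    def test_objective_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            net, states = random_flagged_instance(rng)
            solution = solve_imat(net, states)
            assert solution.objective == brute_force_imat_objective(net, states)

    def test_adding_high_flag_never_decreases_objective(self):
        rng = np.random.default_rng(88)
        for _ in range(30):
            net, states = random_flagged_instance(rng, max_flags=4)
            base = solve_imat(net, states).objective
            unflagged = [r.id for r in net.reactions if r.id not in states]
            if not unflagged:
                continue
            extra = dict(states)
            extra[unflagged[0]] = 1
            grown = solve_imat(net, extra).objective
            assert base <= grown <= base + 1

    def test_epsilon_must_be_positive(self, branch_network):
        with pytest.raises(ValueError):
            solve_imat(branch_network, {"R_AB": 1}, epsilon=0.0)

    def test_unknown_reaction_in_states_rejected(self, branch_network):
        with pytest.raises(KeyError):
            solve_imat(branch_network, {"nope": 1})

    def test_infeasible_bounds_reported(self):
        # forced uptake with no outlet
        mets = [Metabolite("A")]
        rxns = [Reaction("EX_A", {"A": 1.0}, 5.0, 10.0)]
        net = MetabolicNetwork(mets, rxns)
        assert solve_imat(net, {}).status == "infeasible"


class TestExtractTissueModel:
    def make_solution(self, fluxes):
        return ImatSolution(
            fluxes=fluxes, objective=0, satisfied_high=set(), satisfied_low=set(),
            status="optimal",
        )

    def test_thresholding(self, branch_network):
        sol = self.make_solution(
            {"EX_A": 10.0, "R_AB": 10.0, "R_AC": 0.0, "R_CB": 0.0, "EX_B": 10.0}
        )
        model = extract_tissue_model(branch_network, sol, "leaf")
        assert model.active_reactions == {"EX_A", "R_AB", "EX_B"}

    def test_below_tolerance_excluded(self, branch_network):
        sol = self.make_solution({r.id: 0.0 for r in branch_network.reactions})
        sol.fluxes["R_AB"] = 1e-9
        with pytest.warns(UserWarning, match="all-zero"):
            model = extract_tissue_model(branch_network, sol, "leaf")
        assert model.active_reactions == set()

    def test_non_optimal_rejected(self, branch_network):
        sol = self.make_solution({})
        sol.status = "time-limit"
        with pytest.raises(ImatError):
            extract_tissue_model(branch_network, sol, "leaf")


class TestActiveSetOverlap:
    def model(self, tissue, active, universe=("a", "b", "c", "d")):
        return TissueModel(
            tissue=tissue,
            active_reactions=set(active),
            fluxes={r: (1.0 if r in active else 0.0) for r in universe},
            epsilon=1.0,
        )

    def test_two_models_regions(self):
        counts = active_set_overlap(
            [self.model("t1", {"a", "b", "c"}), self.model("t2", {"b", "c", "d"})]
        )
        assert counts["shared"] == 2
        assert counts["t1"] == 1  # only-first
        assert counts["t2"] == 1  # only-second
        assert counts["t1&t2"] == 2

    def test_identical_models(self):
        counts = active_set_overlap(
            [self.model("t1", {"a", "b"}), self.model("t2", {"a", "b"})]
        )
        assert counts["shared"] == 2 and counts["t1"] == 0 and counts["t2"] == 0

    def test_three_disjoint_models(self):
        counts = active_set_overlap(
            [self.model("t1", {"a"}), self.model("t2", {"b"}), self.model("t3", {"c"})]
        )
        assert counts["shared"] == 0
        assert counts["t1"] == counts["t2"] == counts["t3"] == 1

    def test_mismatched_networks_rejected(self):
        with pytest.raises(ValueError, match="different networks"):
            active_set_overlap(
                [self.model("t1", {"a"}), self.model("t2", {"a"}, universe=("a", "z"))]
            )
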