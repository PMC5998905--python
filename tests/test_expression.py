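"""FPKM computation, quantile discretization and fold-change calls."""

import math

import numpy as np
import pandas as pd
import pytest

from fluxshift.expression import (
    ExpressionTable,
    compute_fpkm,
    discretize,
    discretize_values,
    gene_fold_changes,
)


def make_table(values: dict[str, list[float]], genes: list[str]) -> ExpressionTable:
    return ExpressionTable(pd.DataFrame(values, index=genes))


class TestFpkm:
    def test_unit_substitution(self):
        fpkm = compute_fpkm({"g": 10}, {"g": 1000}, 1_000_000)
        assert fpkm["g"] == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        # 100 fragments / (10 million reads x 2 kb) = 5
        fpkm = compute_fpkm({"g": 100}, {"g": 2000}, 10_000_000)
        assert fpkm["g"] == pytest.approx(5.0)

    def test_zero_fragments_zero_fpkm(self):
        assert compute_fpkm({"g": 0}, {"g": 500}, 10**6)["g"] == 0.0

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_fpkm({"g": 1}, {"g": 1000}, 0)
        with pytest.raises(ValueError):
            compute_fpkm({"g": 1}, {"g": 0}, 10**6)


class TestDiscretize:
    def test_values_1_to_20_extremes(self):
        genes = [f"g{i}" for i in range(1, 21)]
        table = make_table({"s": list(range(1, 21))}, genes)
        states = discretize(table).states("s")
        assert {g for g, s in states.items() if s == 1} == {"g18", "g19", "g20"}
        assert {g for g, s in states.items() if s == -1} == {"g1", "g2", "g3"}

    def test_all_equal_all_moderate(self):
        states, _, _ = discretize_values(np.full(40, 7.0))
        assert (states == 0).all()

    def test_fraction_preconditions(self):
        table = make_table({"s": [1.0, 2.0]}, ["a", "b"])
        with pytest.raises(ValueError):
            discretize(table, low_q=0.5, high_q=0.5)

    @pytest.mark.parametrize("n", [7, 20, 100, 1001])
    def test_distinct_values_match_sort_oracle(self, n):
        """Extreme classes are exactly the ceil(0.15 n) top/bottom values."""
        rng = np.random.default_rng(n)
        values = rng.permutation(np.arange(n, dtype=float) + 1)
        states, _, _ = discretize_values(values)
        k = math.ceil(0.15 * n)
        order = np.argsort(values)
        expected = np.zeros(n, dtype=int)
        expected[order[:k]] = -1
        expected[order[-k:]] = 1
        np.testing.assert_array_equal(states, expected)

    def test_large_zero_block_stays_moderate(self):
        """A value shared by more than 15% of genes is excluded from the extreme class."""
        values = np.concatenate([np.zeros(50), np.arange(1, 51, dtype=float)])
        states, _, _ = discretize_values(values)
        assert (states[:50] == 0).all()  # zeros are >15% of the sample
        assert states.tolist().count(1) == 15

    def test_small_zero_block_goes_low(self):
        values = np.concatenate([np.zeros(10), np.arange(1, 91, dtype=float)])
        states, _, _ = discretize_values(values)
        assert (states[:10] == -1).all()

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 100, size=200)
        base, _, _ = discretize_values(values)
        transformed, _, _ = discretize_values(np.exp(values / 50.0))
        np.testing.assert_array_equal(base, transformed)

    def test_states_consistent_with_stored_cutoffs(self):
        genes = [f"g{i}" for i in range(40)]
        table = make_table({"s": list(np.linspace(1, 40, 40))}, genes)
        state_map = discretize(table)
        lc, hc = state_map.cutoffs("s")
        for gene, state in state_map.states("s").items():
            value = table.values.at[gene, "s"]
            if state == 1:
                assert value >= hc
            elif state == -1:
                assert value <= lc
            else:
                assert lc < value < hc


class TestFoldChange:
    TABLE = make_table(
        {"t1": [2.0, 4.0, 3.0], "t2": [5.0, 1.0, 3.0]}, ["up", "down", "flat"]
    )

    def test_literal_rule_with_zero_pseudocount(self):
        changes = {
            c.gene: c for c in gene_fold_changes(self.TABLE, "t1", "t2", pseudocount=0)
        }
        assert changes["up"].fc == pytest.approx(2.5)
        assert changes["up"].call == "up"
        assert changes["down"].fc == pytest.approx(0.25)
        assert changes["down"].call == "down"
        assert changes["flat"].fc == pytest.approx(1.0)
        assert changes["flat"].call == "unchanged"

    def test_mirrored_calls_on_swap(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        table = make_table(
            {"a": rng.uniform(0.5, 50, 50), "b": rng.uniform(0.5, 50, 50)}, genes
        )
        fwd = {c.gene: c for c in gene_fold_changes(table, "a", "b", pseudocount=0)}
        rev = {c.gene: c for c in gene_fold_changes(table, "b", "a", pseudocount=0)}
        mirror = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for gene in genes:
            assert rev[gene].fc == pytest.approx(1.0 / fwd[gene].fc)
            assert rev[gene].call == mirror[fwd[gene].call]

    def test_unknown_sample_raises(self):
        with pytest.raises(KeyError):
            gene_fold_changes(self.TABLE, "t1", "nope")


def test_table_rejects_negative_values_and_duplicates():
    with pytest.raises(ValueError):
        make_table({"s": [-1.0]}, ["g"])
    with pytest.raises(ValueError):
        ExpressionTable(pd.DataFrame({"s": [1.0, 2.0]}, index=["g", "g"]))
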