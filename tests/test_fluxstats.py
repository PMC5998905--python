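"""Total variation, flux-change ratio and pattern clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxshift.fluxstats import (
    cluster_patterns,
    compare_fluxes,
    flux_change,
    rank_fluctuating_reactions,
    significantly_active,
    total_variation,
)

series_strategy = st.lists(
    st.floats(min_value=-1000, max_value=1000, allow_nan=False), min_size=2, max_size=12
)


def tv_loop_oracle(values):
    total = 0.0
    for prev, cur in zip(values, values[1:]):
        total += abs(cur - prev)
    return total


class TestTotalVariation:
    def test_worked_example(self):
        assert total_variation([5, 3, 8]) == pytest.approx(7.0)

    def test_constant_series_zero(self):
        assert total_variation([4.2] * 5) == 0.0

    def test_bound_to_bound_swing(self):
        assert total_variation([0, 1000, -1000]) == pytest.approx(3000.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            total_variation([1.0])

    @settings(max_examples=200, derandomize=True)
    @given(series_strategy)
    def test_matches_loop_oracle_and_reversal_invariant(self, series):
        tv = total_variation(series)
        assert tv == pytest.approx(tv_loop_oracle(series))
        assert tv >= 0
        assert total_variation(series[::-1]) == pytest.approx(tv)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=10), st.data())
    def test_removing_a_point_never_increases_tv(self, series, data):
        j = data.draw(st.integers(0, len(series) - 1))
        shorter = series[:j] + series[j + 1 :]
        assert total_variation(shorter) <= total_variation(series) + 1e-9

    def test_zero_iff_constant(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            series = rng.uniform(-10, 10, size=rng.integers(2, 8))
            if total_variation(series) == 0:
                assert len(set(series)) == 1


class TestRanking:
    def test_oscillating_beats_constant(self):
        matrix = pd.DataFrame(
            {"t1": [1.0, 5.0], "t2": [1.0, -5.0], "t3": [1.0, 5.0]},
            index=["flat", "osc"],
        )
        ranked = rank_fluctuating_reactions(matrix)
        assert list(ranked["reaction_id"]) == ["osc", "flat"]
        assert list(ranked["rank"]) == [1, 2]

    def test_ties_break_lexicographically(self):
        matrix = pd.DataFrame(
            {"t1": [0.0, 0.0], "t2": [1.0, 1.0]}, index=["rB", "rA"]
        )
        ranked = rank_fluctuating_reactions(matrix)
        assert list(ranked["reaction_id"]) == ["rA", "rB"]

    def test_single_column_rejected(self):
        matrix = pd.DataFrame({"t1": [1.0]}, index=["r"])
        with pytest.raises(ValueError):
            rank_fluctuating_reactions(matrix)


class TestFluxChange:
    def test_worked_example_up(self):
        change = flux_change(2.0, 8.0, (0.0, 10.0))
        assert change.ratio == pytest.approx(0.6)
        assert change.call == "up"

    def test_absolute_value_semantics(self):
        change = flux_change(-8.0, 2.0, (-10.0, 10.0))
        assert change.ratio == pytest.approx(-0.3)
        assert change.call == "unchanged"

    def test_degenerate_range_undefined_not_error(self):
        change = flux_change(4.0, 4.0, (4.0, 4.0))
        assert math.isnan(change.ratio)
        assert change.call == "undefined"

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False),
        st.floats(-10, 10), st.floats(0.1, 20),
    )
    def test_antisymmetry(self, f1, f2, vmin, width):
        fwd = flux_change(f1, f2, (vmin, vmin + width))
        rev = flux_change(f2, f1, (vmin, vmin + width))
        assert rev.ratio == pytest.approx(-fwd.ratio)

    def test_irreversible_in_range_ratio_bounded(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            vmin = rng.uniform(0, 5)
            vmax = vmin + rng.uniform(0.01, 10)
            f1, f2 = rng.uniform(vmin, vmax, size=2)
            change = flux_change(f1, f2, (vmin, vmax))
            assert -1.0 <= change.ratio <= 1.0

    def test_equal_fluxes_never_called(self):
        for rng_pair in [(0.0, 10.0), (3.0, 3.0), (-5.0, 5.0)]:
            assert flux_change(4.0, 4.0, rng_pair).call in ("unchanged", "undefined")

    def test_compare_fluxes_frame(self):
        matrix = pd.DataFrame({"a": [2.0, 1.0], "b": [8.0, 1.0]}, index=["r1", "r2"])
        frame = compare_fluxes(matrix, "a", "b", {"r1": (0.0, 10.0), "r2": (0.0, 10.0)})
        assert list(frame["call"]) == ["up", "unchanged"]
        with pytest.raises(KeyError):
            compare_fluxes(matrix, "a", "nope", {})


class TestSignificantlyActive:
    def test_top_quartile_of_nonzero_magnitudes(self):
        fluxes = {f"r{i}": float(i) for i in range(1, 9)}  # 1..8
        top = significantly_active(fluxes)  # 75% quantile of 1..8 is 6.25
        assert top == {"r7", "r8"}

    def test_sign_ignored_and_zeros_excluded(self):
        fluxes = {"fwd": 5.0, "rev": -10.0, "off": 0.0}
        assert significantly_active(fluxes, 0.5) == {"rev"}

    def test_empty_model_empty_set(self):
        assert significantly_active({"r": 0.0}) == set()

    def test_quantile_validated(self):
        with pytest.raises(ValueError):
            significantly_active({"r": 1.0}, 1.5)


class TestClustering:
    def test_identical_pair_merges_first_at_zero_height(self):
        matrix = pd.DataFrame(
            {"t1": [1.0, 0.0], "t2": [1.0, 0.0], "t3": [0.0, 5.0]},
            index=["r1", "r2"],
        )
        result = cluster_patterns(matrix, axis="columns")
        first_merge = result.linkage_matrix[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}  # t1, t2
        assert first_merge[2] == 0.0

    def test_two_columns_single_merge(self):
        matrix = pd.DataFrame({"t1": [1.0, 2.0], "t2": [3.0, 4.0]}, index=["r1", "r2"])
        result = cluster_patterns(matrix, axis="columns")
        assert result.linkage_matrix.shape == (1, 4)

    def test_heights_non_decreasing(self, scenario):
        matrix = scenario.expression.values.iloc[:20]
        result = cluster_patterns(matrix, axis="rows")
        heights = result.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert sorted(result.leaves) == sorted(result.labels)

    def test_newick_contains_all_labels(self):
        matrix = pd.DataFrame(
            {"t1": [1.0, 0.0], "t2": [0.0, 1.0], "t3": [1.0, 1.0]}, index=["r1", "r2"]
        )
        newick = cluster_patterns(matrix, axis="columns").to_newick()
        for label in ("t1", "t2", "t3"):
            assert label in newick
        assert newick.endswith(";")

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            cluster_patterns(pd.DataFrame({"t1": [1.0]}, index=["r"]), axis="columns")
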