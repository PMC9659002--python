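"""Fuzzy composition, lattice degree of nearness and weight-group selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fim_riskweight import (
    compose,
    inner_composition,
    lattice_nearness,
    membership_from_composition_rows,
    membership_matrix,
    nearness_analysis,
    outer_composition,
    reference_membership,
    select_optimal,
)
from fim_riskweight.datasets import load_nearness_example

membership_vectors = st.lists(
    st.floats(0.001, 1.0), min_size=5, max_size=5
).map(lambda v: np.array(v) / np.sum(v))


class TestMembershipMatrix:
    def test_variable_identical_to_outcome_is_uniform(self):
        lcm = np.repeat([1, 2, 3, 4, 5], 4)
        levels = pd.DataFrame({"v": lcm, "LCM": lcm})
        R = membership_matrix(levels)
        np.testing.assert_allclose(R.loc["v"], 0.2)

    def test_single_observation_point_mass(self):
        levels = pd.DataFrame({"v": [3], "LCM": [3]})
        R = membership_matrix(levels)
        np.testing.assert_allclose(R.loc["v"], [0, 0, 1, 0, 0])

    def test_independent_variable_near_uniform(self):
        rng = np.random.default_rng(13)
        n = 20000
        levels = pd.DataFrame({"v": rng.integers(1, 6, n),
                               "LCM": rng.integers(1, 6, n)})
        R = membership_matrix(levels)
        np.testing.assert_allclose(R.loc["v"], 0.2, atol=0.03)

    def test_rows_sum_to_one(self, toy_levels):
        R = membership_matrix(toy_levels)
        np.testing.assert_allclose(R.sum(axis=1), 1.0)
        assert ((R >= 0) & (R <= 1)).all().all()

    def test_never_agreeing_variable_warned_uniform(self, caplog):
        levels = pd.DataFrame({"v": [1, 1, 2, 2], "LCM": [3, 3, 4, 4]})
        with caplog.at_level("WARNING"):
            R = membership_matrix(levels)
        np.testing.assert_allclose(R.loc["v"], 0.2)
        assert "uniform" in caplog.text


class TestCompose:
    def test_point_mass_weight_selects_row(self, toy_levels):
        R = membership_matrix(toy_levels)
        A = pd.Series({"X1": 1.0, "X2": 0.0})
        np.testing.assert_allclose(compose(A, R), R.loc["X1"])

    def test_uniform_weights_equal_rows(self):
        R = pd.DataFrame([[0.1, 0.2, 0.4, 0.2, 0.1]] * 3,
                         index=["a", "b", "c"], columns=range(1, 6))
        A = pd.Series(1 / 3, index=["a", "b", "c"])
        np.testing.assert_allclose(compose(A, R), [0.1, 0.2, 0.4, 0.2, 0.1])

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(17)
        R = rng.random((4, 5))
        R = R / R.sum(axis=1, keepdims=True)
        Rdf = pd.DataFrame(R, index=list("abcd"), columns=range(1, 6))
        A = pd.Series(rng.random(4), index=list("abcd"))
        A = A / A.sum()
        manual = np.array([sum(A[v] * Rdf.loc[v, ell] for v in "abcd")
                           for ell in range(1, 6)])
        np.testing.assert_allclose(compose(A, Rdf), manual / manual.sum())

    def test_dimension_mismatch(self, toy_levels):
        R = membership_matrix(toy_levels)
        with pytest.raises(ValueError):
            compose(pd.Series({"X1": 1.0}), R)


class TestCompositionsOnPublishedTable:
    def test_inner_composition(self):
        near = load_nearness_example()
        b1 = near["methods"]["chisq"]["B"]
        assert inner_composition(b1, near["C"]) * 100 == pytest.approx(43.83, abs=0.005)

    def test_outer_composition(self):
        near = load_nearness_example()
        b1 = near["methods"]["chisq"]["B"]
        assert outer_composition(b1, near["C"]) * 100 == pytest.approx(5.11, abs=0.005)

    def test_nearness_all_methods(self):
        near = load_nearness_example()
        for method, d in near["methods"].items():
            sigma = lattice_nearness(d["B"], near["C"])
            assert sigma == pytest.approx(d["sigma"], abs=1e-4)

    def test_argmax_selects_chi_square(self):
        near = load_nearness_example()
        sigmas = {m: lattice_nearness(d["B"], near["C"])
                  for m, d in near["methods"].items()}
        assert select_optimal(sigmas) == "chisq"

    def test_self_composition_idempotence(self):
        c = load_nearness_example()["C"]
        assert inner_composition(c, c) == pytest.approx(c.max())
        assert outer_composition(c, c) == pytest.approx(c.min())
        assert lattice_nearness(c, c) == pytest.approx(
            0.5 * (0.4383 + 1 - 0.0292), abs=1e-4)


class TestLatticeOperations:
    def test_disjoint_supports(self):
        b = np.array([1.0, 0, 0, 0, 0])
        c = np.array([0, 0, 0, 0, 1.0])
        assert inner_composition(b, c) == 0.0

    def test_uniform_vectors(self):
        u = np.full(5, 0.2)
        assert outer_composition(u, u) == pytest.approx(0.2)
        assert lattice_nearness(u, u) == pytest.approx(0.5)

    @given(membership_vectors, membership_vectors)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_symmetry(self, b, c):
        assert lattice_nearness(b, c) == pytest.approx(lattice_nearness(c, b))

    @given(membership_vectors, membership_vectors)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_bounds(self, b, c):
        sigma = lattice_nearness(b, c)
        low = 0.5 * (1 - np.maximum(b, c).min())
        high = 0.5 * (1 + np.minimum(b, c).max())
        assert low - 1e-12 <= sigma <= high + 1e-12
        assert 0.0 <= sigma <= 1.0

    @given(membership_vectors, membership_vectors)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_reconstruction_round_trip(self, b, c):
        inner_row = np.minimum(b, c)
        outer_row = np.maximum(b, c)
        np.testing.assert_allclose(
            membership_from_composition_rows(inner_row, outer_row, c), b)


class TestSelectOptimal:
    def test_single_method(self):
        assert select_optimal({"ridit": 0.4}) == "ridit"

    def test_exact_tie_fixed_order(self, caplog):
        with caplog.at_level("INFO"):
            assert select_optimal({"ahp": 0.6, "ridit": 0.6}) == "ridit"

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_optimal({})


class TestReferenceMembership:
    def test_single_level_point_mass(self):
        rates = pd.Series([1.0, 2.0, 3.0])
        levels = pd.Series([4, 4, 4])
        np.testing.assert_allclose(reference_membership(rates, levels),
                                   [0, 0, 0, 1, 0])

    def test_equal_rates_balanced_levels(self):
        rates = pd.Series(np.ones(10))
        levels = pd.Series(np.repeat([1, 2, 3, 4, 5], 2))
        np.testing.assert_allclose(reference_membership(rates, levels), 0.2)

    def test_monotone_under_sorted_assignment(self):
        # equal group sizes, levels assigned by increasing rate => C increases
        rng = np.random.default_rng(19)
        for _ in range(10):
            rates = pd.Series(np.sort(rng.random(25)) + 0.01)
            levels = pd.Series(np.repeat([1, 2, 3, 4, 5], 5))
            c = reference_membership(rates, levels).to_numpy()
            assert (np.diff(c) > 0).all()

    def test_zero_total_rate_is_error(self):
        with pytest.raises(ValueError):
            reference_membership(pd.Series([0.0, 0.0]), pd.Series([1, 2]))


def test_nearness_analysis_end_to_end(toy_levels):
    R = membership_matrix(toy_levels)
    groups = {
        "chisq": pd.Series({"X1": 0.8, "X2": 0.2}),
        "ridit": pd.Series({"X1": 0.5, "X2": 0.5}),
    }
    C = pd.Series([0.1, 0.15, 0.2, 0.25, 0.3], index=range(1, 6))
    result = nearness_analysis(groups, R, C)
    assert set(result.sigma) == {"chisq", "ridit"}
    assert result.selected in result.sigma
    for b in result.composed.values():
        assert b.sum() == pytest.approx(1.0)
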