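"""Selection theory: intensities, gain, Smith-Hazel index, overlap."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cloverqg as cq
from cloverqg.selection import (
    GainEstimate,
    SelectionPlan,
    correlated_response,
    family_phenotypic_sd,
    index_scores,
    predicted_gain,
    select_top,
    selection_intensity,
    selection_overlap,
    smith_hazel_coefficients,
)


class TestSelectionIntensity:
    def test_median_truncation(self):
        assert round(selection_intensity(0.5), 3) == 0.798

    @given(st.floats(0.001, 0.998), st.floats(0.001, 0.998))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_decreasing_in_pressure(self, p1, p2):
        if p1 == p2:
            return
        lo, hi = sorted([p1, p2])
        assert selection_intensity(lo) > selection_intensity(hi)

    def test_vanishes_as_everything_is_kept(self):
        assert selection_intensity(0.9999) < 0.001

    def test_domain_errors(self):
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                selection_intensity(p)

    def test_finite_population_correction_reduces_intensity(self):
        k_inf = selection_intensity(0.05)
        k_120 = selection_intensity(0.05, population_size=120)
        assert k_120 < k_inf
        assert k_120 > 0.9 * k_inf


class TestFamilyPhenotypicSd:
    def test_reported_shoot_dm_components(self):
        assert family_phenotypic_sd(13.5, 4.7, 49.6, 2) == pytest.approx(
            math.sqrt(40.65), rel=1e-12
        )

    def test_reductions(self):
        assert family_phenotypic_sd(9.0, 0, 0, 3) == 3.0
        assert family_phenotypic_sd(0, 0, 0, 2) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            family_phenotypic_sd(-1, 0, 1, 2)


class TestPredictedGain:
    def test_reported_shoot_dm_gains(self):
        sigma_pf = family_phenotypic_sd(13.5, 4.7, 49.6, 2)
        g5 = predicted_gain(SelectionPlan(0.05), 13.5, sigma_pf, 11.4, "shoot_dm")
        g20 = predicted_gain(SelectionPlan(0.20), 13.5, sigma_pf, 11.4, "shoot_dm")
        assert g5.gain == pytest.approx(2.18, abs=0.01)
        assert round(g5.gain_percent) == 19
        assert round(g20.gain_percent) == 13

    def test_linearity_in_intensity_and_family_variance(self):
        plan1 = SelectionPlan(0.2, intensity=1.0)
        plan2 = SelectionPlan(0.2, intensity=2.0)
        g1 = predicted_gain(plan1, 10.0, 5.0, 20.0)
        g2 = predicted_gain(plan2, 10.0, 5.0, 20.0)
        g3 = predicted_gain(plan1, 20.0, 5.0, 20.0)
        assert g2.gain == pytest.approx(2 * g1.gain)
        assert g3.gain == pytest.approx(2 * g1.gain)

    def test_gain_nonnegative_and_percent_of_absolute_mean(self):
        g = predicted_gain(SelectionPlan(0.1), 4.0, 3.0, -8.0)
        assert g.gain >= 0
        assert g.gain_percent == pytest.approx(100 * g.gain / 8.0)

    def test_degenerate_population_rejected(self):
        with pytest.raises(ValueError):
            predicted_gain(SelectionPlan(0.1), 1.0, 0.0, 5.0)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            SelectionPlan(0.0)
        with pytest.raises(ValueError):
            SelectionPlan(0.5, parental_control=0.0)
        with pytest.raises(ValueError):
            SelectionPlan(0.5, intensity=-1.0)


class TestSmithHazel:
    def test_identity_when_phenotype_equals_genotype(self):
        P = np.array([[4.0, 1.0], [1.0, 2.0]])
        w = np.array([1.0, 2.0])
        b = smith_hazel_coefficients(P, P, w)
        assert b == pytest.approx(w, rel=1e-10)

    def test_scalar_reduction_to_heritability(self):
        b = smith_hazel_coefficients(
            np.array([[40.65]]), np.array([[13.5]]), np.array([1.0])
        )
        assert b[0] == pytest.approx(13.5 / 40.65, rel=1e-10)

    def test_hand_worked_two_trait_system(self):
        P = np.array([[4.0, 1.0], [1.0, 2.0]])
        A = np.array([[2.0, 0.5], [0.5, 1.0]])
        b = smith_hazel_coefficients(P, A, np.array([1.0, 1.0]))
        assert b == pytest.approx([0.5, 0.5], abs=1e-10)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=50)
    def test_solution_residual_below_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((3, 3))
        P = m @ m.T + np.eye(3)
        a = rng.standard_normal((3, 3))
        A = (a + a.T) / 2
        w = rng.standard_normal(3)
        b = smith_hazel_coefficients(P, A, w)
        rhs = A @ w
        assert np.linalg.norm(P @ b - rhs) <= 1e-8 * max(np.linalg.norm(rhs), 1e-12)

    def test_indefinite_phenotypic_matrix_rejected(self):
        P = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(np.linalg.LinAlgError):
            smith_hazel_coefficients(P, np.eye(2), np.ones(2))


class TestIndexScores:
    def test_single_trait_coefficient_reduces_to_trait_ranking(self):
        m = pd.DataFrame({"x": [3.0, 1.0, 2.0], "y": [9.0, 9.0, 9.0]},
                         index=[1, 2, 3])
        res = index_scores(np.array([1.0, 0.0]), m)
        assert res.ranking == [1, 3, 2]

    def test_equal_coefficients_average_traits(self):
        m = pd.DataFrame({"x": [2.0, 4.0], "y": [6.0, 0.0]}, index=[1, 2])
        res = index_scores(np.array([0.5, 0.5]), m)
        assert res.scores[1] == pytest.approx(4.0)
        assert res.scores[2] == pytest.approx(2.0)

    def test_ranking_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.standard_normal((40, 3)), index=range(1, 41))
        b = np.array([0.7, -0.2, 1.3])
        res = index_scores(b, m)
        brute = sorted(range(1, 41), key=lambda f: (-(m.loc[f] @ b), f))
        assert res.ranking == brute

    def test_missing_values_exclude_family_with_warning(self):
        m = pd.DataFrame({"x": [1.0, np.nan], "y": [1.0, 1.0]}, index=[1, 2])
        with pytest.warns(UserWarning, match="excluded"):
            res = index_scores(np.array([1.0, 1.0]), m)
        assert list(res.scores.index) == [1]

    @given(st.integers(0, 500))
    @settings(derandomize=True, max_examples=25)
    def test_monotone_in_trait_values_for_nonnegative_coefficients(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.standard_normal((10, 2)), index=range(10))
        b = np.abs(rng.standard_normal(2))
        before = index_scores(b, m).scores[3]
        m.loc[3] += np.abs(rng.standard_normal(2))
        after = index_scores(b, m).scores[3]
        assert after >= before


class TestCorrelatedResponse:
    def test_zero_genetic_correlation_gives_zero(self):
        assert correlated_response(SelectionPlan(0.05), 0.6, 0.5, 0.0, 2.0) == 0.0

    def test_perfect_correlation_reduces_to_direct_response(self):
        plan = SelectionPlan(0.05)
        h = 0.55
        cr = correlated_response(plan, h, h, 1.0, 3.0)
        assert cr == pytest.approx(plan.intensity * 0.5 * h * h * 3.0, rel=1e-12)

    def test_reported_component_arithmetic(self):
        plan = SelectionPlan(0.05, intensity=2.06)
        cr = correlated_response(
            plan, math.sqrt(0.33), math.sqrt(0.24), 0.62, math.sqrt(0.06)
        )
        assert round(cr, 4) == 0.0440

    def test_signed_response_and_domain_checks(self):
        plan = SelectionPlan(0.1)
        assert correlated_response(plan, 0.5, 0.5, -0.4, 1.0) < 0
        with pytest.raises(ValueError):
            correlated_response(plan, 1.2, 0.5, 0.1, 1.0)
        with pytest.raises(ValueError):
            correlated_response(plan, 0.5, 0.5, 1.1, 1.0)


class TestSelectTop:
    @pytest.mark.parametrize("p,expected", [(0.05, 6), (0.10, 12), (0.20, 24)])
    def test_counts_at_study_pressures(self, p, expected):
        values = pd.Series(np.arange(120, dtype=float), index=range(1, 121))
        assert len(select_top(values, p)) == expected

    def test_top_values_selected_with_id_tie_break(self):
        values = pd.Series({1: 5.0, 2: 7.0, 3: 7.0, 4: 1.0})
        assert select_top(values, 0.5) == [2, 3]

    def test_all_equal_values_warn_and_take_lowest_ids(self):
        values = pd.Series({f: 1.0 for f in range(1, 11)})
        with pytest.warns(UserWarning, match="tie"):
            chosen = select_top(values, 0.2)
        assert chosen == [1, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_top(pd.Series(dtype=float), 0.1)


class TestSelectionOverlap:
    def test_identical_and_disjoint_sets(self):
        same = selection_overlap({"a": {1, 2, 3}, "b": {1, 2, 3}})
        assert same["pairwise"]["a&b"]["count"] == 3
        assert same["common"]["count"] == 3
        disjoint = selection_overlap({"a": {1, 2}, "b": {3, 4}})
        assert disjoint["pairwise"]["a&b"]["count"] == 0

    def test_needs_at_least_two_sets(self):
        with pytest.raises(ValueError):
            selection_overlap({"a": {1}})

    def test_correlated_rankings_overlap_above_hypergeometric_null(self):
        # two traits with moderate genetic correlation share top families more
        # often than the 6*6/120 = 0.3 null expectation
        rho, n, n_seeds = 0.62, 120, 200
        rng = np.random.default_rng(7)
        overlaps = []
        for _ in range(n_seeds):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            sx = select_top(pd.Series(x, index=range(n)), 0.05)
            sy = select_top(pd.Series(y, index=range(n)), 0.05)
            overlaps.append(len(set(sx) & set(sy)))
        null_expectation = 6 * 6 / 120
        assert np.mean(overlaps) > null_expectation


def test_gain_estimate_is_a_plain_record():
    g = GainEstimate("shoot_dm", 0.05, 2.06, 2.18, 19.1, 6.38)
    assert g.trait == "shoot_dm"
    assert g.gain_percent == pytest.approx(19.1)
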