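"""Heritability and correlation estimators."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cloverqg as cq
from cloverqg.errors import PairingError
from cloverqg.genetics import (
    genetic_correlation,
    genetic_correlation_matrix,
    genetic_covariance,
    heritability_from_fit,
    narrow_sense_heritability,
    phenotypic_correlations,
)
from cloverqg.reml import ModelSpec, fit_reml


class TestNarrowSenseHeritability:
    def test_reported_component_arithmetic(self):
        assert round(narrow_sense_heritability(13.5, 4.7, 49.6, 2), 2) == 0.33
        assert round(narrow_sense_heritability(2.2, 0.9, 10.2, 2), 2) == 0.28

    def test_pure_genetic_variance_gives_unity(self):
        for v in (0.5, 13.5):
            for n in (1, 2, 5):
                assert narrow_sense_heritability(v, 0, 0, n) == 1.0

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            narrow_sense_heritability(0, 0, 0, 2)
        with pytest.raises(ValueError):
            narrow_sense_heritability(-1, 0, 1, 2)
        with pytest.raises(ValueError):
            narrow_sense_heritability(1, 0, 1, 0)

    @given(
        st.floats(0.01, 100),
        st.floats(0, 100),
        st.floats(0.01, 100),
        st.integers(1, 6),
        st.floats(0.01, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, vf, vfr, ve, n, c):
        base = narrow_sense_heritability(vf, vfr, ve, n)
        scaled = narrow_sense_heritability(c * vf, c * vfr, c * ve, n)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_from_fit_equals_formula_on_reported_components(self, wide_ta1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_reml(wide_ta1, ModelSpec("shoot_dm"))
        h = heritability_from_fit(fit, 2, cq.TA1)
        expected = narrow_sense_heritability(
            fit.estimates["family"], 0.0, fit.estimates["residual"], 2
        )
        assert h.h2 == pytest.approx(expected, rel=1e-12)
        assert 0 <= h.h2 <= 1
        assert h.se is not None and h.se > 0


class TestGeneticCovariance:
    def test_self_covariance_equals_family_variance(self, wide_ta1):
        dup = wide_ta1.assign(shoot_copy=wide_ta1["shoot_dm"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov, vx, vy = genetic_covariance(dup, "shoot_dm", "shoot_copy")
        assert cov == pytest.approx(vx, rel=1e-6)
        assert vx == pytest.approx(vy, rel=1e-6)

    def test_polarization_equals_direct_cross_product_on_balanced_oneway(self):
        rng = np.random.default_rng(21)
        a, n = 6, 4
        fam = np.repeat(np.arange(a), n)
        gx = 2.0 * rng.standard_normal(a)
        gy = 1.5 * gx / 2.0 + 0.8 * rng.standard_normal(a)
        x = gx[fam] + rng.standard_normal(a * n)
        y = gy[fam] + rng.standard_normal(a * n)
        data = pd.DataFrame({"family": fam + 1, "x": x, "y": y})

        # direct ANOVA cross-product estimator: (MCP_between - MCP_within)/n
        xm = data.groupby("family")["x"].transform("mean").to_numpy()
        ym = data.groupby("family")["y"].transform("mean").to_numpy()
        mcp_b = n * ((xm - x.mean()) * (ym - y.mean())).sum() / n / (a - 1)
        mcp_w = ((x - xm) * (y - ym)).sum() / (a * (n - 1))
        direct = (mcp_b - mcp_w) / n

        # interior check so ANOVA = REML for the traits, their sum and difference
        for v in (x, y, x + y, x - y):
            vm = pd.Series(v).groupby(fam).transform("mean").to_numpy()
            msb = n * ((np.unique(vm) - v.mean()) ** 2).sum() / (a - 1)
            msw = ((v - vm) ** 2).sum() / (a * (n - 1))
            assert msb > msw

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov, _, _ = genetic_covariance(data, "x", "y", terms=("family",))
        assert cov == pytest.approx(direct, rel=1e-5)

    def test_disjoint_plots_raise_pairing_error(self, wide_ta1):
        broken = wide_ta1.copy()
        broken.loc[:, "root_dm"] = np.nan
        with pytest.raises(PairingError):
            genetic_covariance(broken, "shoot_dm", "root_dm")


class TestGeneticCorrelation:
    def test_duplicated_trait_gives_unity(self, wide_ta1):
        dup = wide_ta1.assign(shoot_copy=wide_ta1["shoot_dm"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = genetic_correlation(dup, "shoot_dm", "shoot_copy")
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_antisymmetry_under_reflection(self, wide_ta1):
        flipped = wide_ta1.assign(neg_root=-wide_ta1["root_dm"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = genetic_correlation(wide_ta1, "shoot_dm", "root_dm")
            r_flip = genetic_correlation(flipped, "shoot_dm", "neg_root")
        assert r_flip == pytest.approx(-r, rel=1e-6)

    def test_matrix_is_symmetric_with_unit_diagonal(self, wide_ta1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmat = genetic_correlation_matrix(
                wide_ta1, ["shoot_dm", "root_dm", "rsr"]
            )
        m = gmat.r.to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12

    def test_overshooting_estimates_are_clamped_and_flagged(self, wide_ta1):
        # a noisy duplicate of a trait routinely estimates rA slightly above 1
        rng = np.random.default_rng(3)
        noisy = wide_ta1.assign(
            shoot_noisy=wide_ta1["shoot_dm"] + 0.05 * rng.standard_normal(len(wide_ta1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = genetic_correlation(noisy, "shoot_dm", "shoot_noisy")
        if raw > 1.0:  # clamping branch must engage and flag
            with pytest.warns(UserWarning, match="clamped"):
                gmat = genetic_correlation_matrix(noisy, ["shoot_dm", "shoot_noisy"])
            assert gmat.r.loc["shoot_dm", "shoot_noisy"] == 1.0
            assert gmat.clamped.loc["shoot_dm", "shoot_noisy"]
        else:
            gmat = genetic_correlation_matrix(noisy, ["shoot_dm", "shoot_noisy"])
            assert gmat.r.loc["shoot_dm", "shoot_noisy"] == pytest.approx(raw)


class TestPhenotypicCorrelations:
    def test_identical_columns(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        r, p = phenotypic_correlations(m)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 1e-6

    def test_orthogonal_sign_patterns(self):
        m = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        r, _ = phenotypic_correlations(m)
        assert r.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_flagged(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            r, p = phenotypic_correlations(m)
        assert np.isnan(r.loc["a", "b"])

    def test_recovery_of_a_moderate_association(self):
        # the cross-treatment shoot association strength seen in the study
        rho, n, n_seeds = 0.47, 120, 200
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(n_seeds):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            m = pd.DataFrame({"x": x, "y": y})
            r, _ = phenotypic_correlations(m)
            estimates.append(r.loc["x", "y"])
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(estimates.mean() - rho) < 2 * mc_se

    def test_p_values_match_t_distribution(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.standard_normal((30, 2)), columns=["x", "y"])
        r, p = phenotypic_correlations(m)
        rv = r.loc["x", "y"]
        t = rv * np.sqrt(28 / (1 - rv**2))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-9)
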