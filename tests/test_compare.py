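"""Sequential landscape comparison and the angle between gradient vectors."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paceshape import (
    SurfaceData,
    angle_credible_interval,
    build_default_grid,
    fit_linear,
    sequential_compare,
    vector_angle,
    z_transform,
)

vectors = st.tuples(
    st.floats(min_value=-10, max_value=10),
    st.floats(min_value=-10, max_value=10),
).filter(lambda v: abs(v[0]) + abs(v[1]) > 1e-3)


def grid_intakes():
    cells = build_default_grid().cells()
    return (
        np.array([c.mean_protein for c in cells]),
        np.array([c.mean_carb for c in cells]),
    )


def make_pair(rng, beta_a=(0.5, 0.5), beta_b=(0.5, 0.5), sigma=0.3):
    P, C = grid_intakes()
    zP, zC = z_transform(P), z_transform(C)
    ra = beta_a[0] * zP + beta_a[1] * zC + rng.normal(0, sigma, size=P.size)
    rb = beta_b[0] * zP + beta_b[1] * zC + rng.normal(0, sigma, size=P.size)
    return SurfaceData(P, C, ra, "trait_A"), SurfaceData(P, C, rb, "trait_B")


def explicit_partial_f(level, data_a, data_b):
    """Oracle: the same partial F from two explicit statsmodels OLS fits."""
    P = np.concatenate([data_a.P, data_b.P])
    C = np.concatenate([data_a.C, data_b.C])
    T = np.concatenate([np.zeros(data_a.n), np.ones(data_b.n)])
    y = np.concatenate([z_transform(data_a.response), z_transform(data_b.response)])
    blocks = {
        "1": np.ones_like(P), "trait": T, "P": P, "C": C,
        "trait:P": T * P, "trait:C": T * C, "P2": P**2, "C2": C**2,
        "trait:P2": T * P**2, "trait:C2": T * C**2, "PC": P * C, "trait:PC": T * P * C,
    }
    reduced = {
        "linear": ["1", "trait", "P", "C"],
        "quadratic": ["1", "trait", "P", "C", "trait:P", "trait:C", "P2", "C2"],
        "correlational": ["1", "trait", "P", "C", "trait:P", "trait:C",
                          "P2", "C2", "trait:P2", "trait:C2", "PC"],
    }[level]
    added = {
        "linear": ["trait:P", "trait:C"],
        "quadratic": ["trait:P2", "trait:C2"],
        "correlational": ["trait:PC"],
    }[level]
    Xr = np.column_stack([blocks[t] for t in reduced])
    Xc = np.column_stack([blocks[t] for t in reduced + added])
    fit_r = sm.OLS(y, Xr).fit()
    fit_c = sm.OLS(y, Xc).fit()
    df1 = len(added)
    df2 = int(fit_c.df_resid)
    f = ((fit_r.ssr - fit_c.ssr) / df1) / (fit_c.ssr / df2)
    return fit_r.ssr, fit_c.ssr, df1, df2, f


class TestSequentialCompare:
    def test_identical_traits_give_zero_f_everywhere(self, rng):
        data_a, _ = make_pair(rng)
        result = sequential_compare(data_a, data_a)
        for level in ["linear", "quadratic", "correlational"]:
            lt = result.levels[level]
            assert lt.f_statistic == pytest.approx(0.0, abs=1e-8)
            assert lt.p_value > 0.999
            assert lt.ss_reduced == pytest.approx(lt.ss_complete, abs=1e-8)

    def test_degrees_of_freedom_bookkeeping_28_diets(self, rng):
        result = sequential_compare(*make_pair(rng))
        assert (result.levels["linear"].df1, result.levels["linear"].df2) == (2, 50)
        assert (result.levels["quadratic"].df1, result.levels["quadratic"].df2) == (2, 46)
        assert (
            result.levels["correlational"].df1,
            result.levels["correlational"].df2,
        ) == (1, 44)

    def test_matches_two_explicit_fit_oracle(self, rng):
        data_a, data_b = make_pair(rng, beta_a=(0.6, 0.2), beta_b=(-0.3, 0.8))
        result = sequential_compare(data_a, data_b)
        for level in ["linear", "quadratic", "correlational"]:
            ssr, ssc, df1, df2, f = explicit_partial_f(level, data_a, data_b)
            lt = result.levels[level]
            assert lt.ss_reduced == pytest.approx(ssr, abs=1e-9)
            assert lt.ss_complete == pytest.approx(ssc, abs=1e-9)
            assert (lt.df1, lt.df2) == (df1, df2)
            assert lt.f_statistic == pytest.approx(f, abs=1e-9)

    def test_nesting_complete_ss_never_increases(self, rng):
        result = sequential_compare(*make_pair(rng, beta_b=(-0.2, 0.9)))
        ss = [result.levels[l].ss_complete for l in ["linear", "quadratic", "correlational"]]
        assert ss[0] >= ss[1] - 1e-10 >= ss[2] - 2e-10
        # each level's reduced model nests inside its complete model
        for l in ["linear", "quadratic", "correlational"]:
            assert result.levels[l].ss_reduced >= result.levels[l].ss_complete - 1e-10

    def test_mismatched_grids_rejected(self, rng):
        data_a, data_b = make_pair(rng)
        shifted = SurfaceData(data_b.P + 1.0, data_b.C, data_b.response)
        with pytest.raises(ValueError, match="same diet grid"):
            sequential_compare(data_a, shifted)

    def test_follow_ups_attribute_linear_difference_to_nutrients(self, rng):
        # strong protein-slope difference: linear level significant, P follow-up too
        data_a, data_b = make_pair(rng, beta_a=(0.8, 0.5), beta_b=(-0.8, 0.5), sigma=0.2)
        result = sequential_compare(data_a, data_b)
        assert result.levels["linear"].p_value < 0.05
        fus = {f.nutrient: f for f in result.follow_ups if f.level == "linear"}
        assert set(fus) == {"P", "C"}
        assert fus["P"].df2 == 50 and fus["P"].df1 == 1
        assert fus["P"].p_value < 0.05

    def test_null_p_values_approximately_uniform(self, rng):
        # responses generated on a common scale so the F-test's own null
        # distribution is probed (within-sample standardisation is a
        # separately documented conservative preprocessing step)
        pvals = []
        for _ in range(500):
            data_a, data_b = make_pair(rng)  # same generating surface
            pvals.append(
                sequential_compare(data_a, data_b, standardize=False)
                .levels["linear"]
                .p_value
            )
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestVectorAngle:
    def test_aligned_vectors(self):
        assert vector_angle((0.3, 0.7), (0.3, 0.7)) == pytest.approx(0.0, abs=1e-9)

    def test_opposed_vectors(self):
        assert vector_angle((1, 0), (-1, 0)) == pytest.approx(180.0, abs=1e-9)

    def test_orthogonal_vectors(self):
        assert vector_angle((1, 0), (0, 1)) == pytest.approx(90.0, abs=1e-9)

    def test_zero_vector_rejected_with_name(self):
        with pytest.raises(ValueError, match="second"):
            vector_angle((1, 0), (0, 0))

    @settings(max_examples=80, derandomize=True)
    @given(vectors, vectors)
    def test_symmetry(self, a, b):
        assert vector_angle(a, b) == pytest.approx(vector_angle(b, a), abs=1e-9)

    @settings(max_examples=80, derandomize=True)
    @given(vectors, vectors, st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, a, b, c):
        scaled = (a[0] * c, a[1] * c)
        assert vector_angle(scaled, b) == pytest.approx(vector_angle(a, b), abs=1e-6)


class TestAngleInterval:
    def _fits(self, rng, **kwargs):
        data_a, data_b = make_pair(rng, **kwargs)
        return fit_linear(data_a), fit_linear(data_b)

    def test_zero_covariance_collapses_to_point(self, rng):
        fit_a, fit_b = self._fits(rng, beta_a=(0.6, 0.1), beta_b=(0.1, 0.6))
        degenerate_a = _with_cov(fit_a, np.zeros((2, 2)))
        degenerate_b = _with_cov(fit_b, np.zeros((2, 2)))
        res = angle_credible_interval(degenerate_a, degenerate_b, n_draws=2000, seed=1)
        assert res.ci_lower == pytest.approx(res.theta, abs=1e-9)
        assert res.ci_upper == pytest.approx(res.theta, abs=1e-9)

    def test_identical_generating_vectors_interval_near_zero(self, rng):
        fit_a, fit_b = self._fits(rng)  # same truth, sigma = 0.3
        res = angle_credible_interval(fit_a, fit_b, n_draws=5000, seed=2)
        assert res.ci_lower < 5.0
        assert res.theta < 45.0
        assert 0 <= res.ci_lower <= res.theta <= res.ci_upper <= 180

    def test_deterministic_given_seed(self, rng):
        fit_a, fit_b = self._fits(rng, beta_b=(-0.5, 0.5))
        r1 = angle_credible_interval(fit_a, fit_b, n_draws=3000, seed=42)
        r2 = angle_credible_interval(fit_a, fit_b, n_draws=3000, seed=42)
        assert (r1.theta, r1.ci_lower, r1.ci_upper) == (r2.theta, r2.ci_lower, r2.ci_upper)

    def test_bootstrap_method_runs_and_brackets_point(self, rng):
        data_a, data_b = make_pair(rng, beta_b=(-0.5, 0.5), sigma=0.2)
        res = angle_credible_interval(
            fit_linear(data_a),
            fit_linear(data_b),
            n_draws=1000,
            seed=3,
            method="bootstrap",
            data_A=data_a,
            data_B=data_b,
        )
        assert res.ci_lower <= res.theta <= res.ci_upper

    def test_non_psd_covariance_rejected(self, rng):
        fit_a, fit_b = self._fits(rng)
        bad = _with_cov(fit_a, np.array([[1.0, 2.0], [2.0, 1.0]]))  # eigenvalue -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            angle_credible_interval(bad, fit_b, n_draws=1000, seed=0)

    def test_too_few_draws_rejected(self, rng):
        fit_a, fit_b = self._fits(rng)
        with pytest.raises(ValueError, match="1000"):
            angle_credible_interval(fit_a, fit_b, n_draws=10, seed=0)


def _with_cov(fit, cov2x2):
    """Copy a GradientFit, replacing the (P, C) coefficient covariance."""
    import dataclasses

    cov = fit.cov.copy()
    cov.loc[["P", "C"], ["P", "C"]] = cov2x2
    return dataclasses.replace(fit, cov=cov)
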