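import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mkdfe.comparative import (ancova, ols_regression, regression_suite,
                               slopes_vs_group_pi, spearman_test)
from mkdfe.synthetic import generate_species_table


def normal_equations_ols(x, y):
    """Independent oracle: OLS via explicit normal equations + t-test."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    pval = 2 * stats.t.sf(abs(t), n - p)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / ss_tot
    return beta[1], beta[0], r2, pval


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = ols_regression(x, y)
        slope, intercept, r2, p = normal_equations_ols(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_null_r2_small_p_uniformish(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = ols_regression(x, y)
        assert res.r2 < 0.01
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ps.append(ols_regression(r.normal(size=20), r.normal(size=20)).p_value)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_log10_transform(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        res = ols_regression(x, y, log10_x=True)
        assert res.slope == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(8.0)
        y = x**3 + 1
        assert spearman_test(x, y)[0] == pytest.approx(1.0)
        assert spearman_test(x[::-1], y)[0] == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho, p = spearman_test(x, y)
        # independent enumeration over all 7! orderings of y
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        rhos = []
        for perm in itertools.permutations(range(7)):
            rhos.append(stats.pearsonr(xr, yr[list(perm)]).statistic)
        rhos = np.asarray(rhos)
        p_oracle = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman_test(x, y)
        rho_sc, p_sc = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_sc)
        assert p == pytest.approx(p_sc)

    def test_constant_vector_nan(self):
        rho, p = spearman_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


def parallel_lines_table(slope=5.0, noise=0.1, seed=0, n_groups=4, per_group=6,
                         intercepts=None):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        icpt = (intercepts[g] if intercepts is not None else g * 2.0)
        x = rng.uniform(0, 1, per_group)
        y = icpt + slope * x + rng.normal(0, noise, per_group)
        for xi, yi in zip(x, y):
            rows.append({"y": yi, "x": xi, "group": f"g{g}"})
    return pd.DataFrame(rows)


class TestAncova:
    def test_parallel_lines_recovery(self):
        ok_slope = ok_inter = 0
        reps = 60
        for seed in range(reps):
            df = parallel_lines_table(seed=seed)
            res = ancova(df, "y", "x")
            if 4.8 <= res.common_slope <= 5.2 and res.p_slope < 1e-6:
                ok_slope += 1
            if res.p_interaction > 0.05:
                ok_inter += 1
        assert ok_slope >= 0.9 * reps
        assert ok_inter >= 0.9 * reps

    def test_distinct_intercepts_detected(self):
        df = parallel_lines_table(seed=1)
        assert ancova(df, "y", "x").p_intercepts < 1e-6

    def test_null_pvalues_near_nominal(self):
        # identical intercepts and zero slope: both tests behave as nulls
        frac_i = frac_s = 0
        reps = 100
        for seed in range(reps):
            df = parallel_lines_table(slope=0.0, noise=1.0, seed=seed,
                                      intercepts=[0.0] * 4)
            res = ancova(df, "y", "x")
            frac_i += res.p_intercepts < 0.05
            frac_s += res.p_slope < 0.05
        assert frac_i <= 0.12 * reps
        assert frac_s <= 0.12 * reps

    def test_single_group_degenerates_to_ols(self):
        df = parallel_lines_table(n_groups=1, seed=2)
        res = ancova(df, "y", "x")
        ols = ols_regression(df["x"], df["y"])
        assert res.common_slope == pytest.approx(ols.slope)
        assert res.p_slope == pytest.approx(ols.p_value)

    def test_covariate_rescaling_invariance_of_pvalues(self):
        df = parallel_lines_table(seed=3)
        res1 = ancova(df, "y", "x")
        df2 = df.assign(x=df["x"] * 1000.0)
        res2 = ancova(df2, "y", "x")
        assert res2.p_slope == pytest.approx(res1.p_slope, rel=1e-9)
        assert res2.common_slope == pytest.approx(res1.common_slope / 1000.0)

    def test_matches_normal_equations_common_slope(self):
        # oracle: solve the additive design matrix by normal equations
        df = parallel_lines_table(seed=4)
        res = ancova(df, "y", "x")
        groups = sorted(df["group"].unique())
        X = np.column_stack(
            [np.ones(len(df)), df["x"].to_numpy()]
            + [(df["group"] == g).to_numpy(float) for g in groups[1:]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res.common_slope == pytest.approx(beta[1], abs=1e-10)

    def test_undersized_group_rejected(self):
        df = parallel_lines_table(seed=5)
        df = pd.concat([df, pd.DataFrame([{"y": 1.0, "x": 0.5, "group": "tiny"}])])
        with pytest.raises(ValueError, match="tiny"):
            ancova(df, "y", "x")


class TestSlopesVsGroupPi:
    def test_constructed_monotone_rho_minus_one(self):
        df = generate_species_table(
            groups=4, species_per_group=6,
            group_pi_means=[0.001, 0.004, 0.01, 0.03],
            slopes=[10.0, 5.0, 2.0, 1.0], noise_sd=0.0, seed=0,
        )
        frame, rho, p = slopes_vs_group_pi(df)
        assert rho == pytest.approx(-1.0)

    def test_two_species_group_flagged_and_excluded(self):
        df = generate_species_table(
            groups=5, species_per_group=5,
            group_pi_means=[0.001, 0.002, 0.004, 0.01, 0.03],
            slopes=[10.0, 7.0, 5.0, 2.0, 1.0], noise_sd=0.0, seed=1,
        )
        small = df[df["group"] == "group_A"].index[2:]
        df = df.drop(small)  # group_A left with 2 species
        frame, rho, p = slopes_vs_group_pi(df)
        assert not frame.loc[frame["group"] == "group_A", "used"].item()
        assert frame["used"].sum() == 4

    def test_equal_slopes_null(self):
        sig = 0
        reps = 60
        for seed in range(reps):
            df = generate_species_table(
                groups=5, species_per_group=6,
                group_pi_means=[0.001, 0.003, 0.006, 0.012, 0.03],
                slopes=[3.0] * 5, noise_sd=0.02, seed=seed,
            )
            _, rho, p = slopes_vs_group_pi(df)
            sig += p < 0.05
        assert sig <= 0.1 * reps


class TestRegressionSuite:
    def test_traits_recovered_from_synthetic_table(self):
        df = generate_species_table(
            groups=6, species_per_group=6,
            group_pi_means=[0.001, 0.002, 0.005, 0.01, 0.02, 0.04],
            slopes=[8, 6, 4, 3, 2, 1], noise_sd=0.01, seed=7,
        )
        res = regression_suite(df, response="omega_na").set_index("covariate")
        # omega_na decreases with pi_s; traits are log-linear in pi_s
        assert res.loc["pi_s", "slope"] < 0
        assert res.loc["fecundity", "slope"] < 0
        assert res.loc["propagule_size", "slope"] > 0
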