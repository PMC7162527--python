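import numpy as np
import pytest

from mkdfe.dfe import DiscreteDFE, GammaZero
from mkdfe.fit import FitOptions, FitResult
from mkdfe.mk import (DEFAULT_FAMILIES, DivergenceCounts, MKEstimate,
                      PerModelEstimate, aic_weights, bootstrap_ci, estimate_mk,
                      group_averaged_estimate, group_pooled_estimate,
                      mk_analysis, model_average)
from mkdfe.sfs import FoldedSFS, PairedSFS

FAST = FitOptions(n_starts=3, seed=0)


def fake_fit(omega_na_pred, aic=100.0, logL=-50.0, family="GammaZero"):
    """A FitResult with a point-mass DFE chosen to give the desired omega_na."""
    # omega_na(point mass at S) = S/(1-e^-S); invert numerically
    from scipy.optimize import brentq

    if omega_na_pred >= 1.0:
        s = 0.0
    else:
        s = brentq(lambda S: S / (1 - np.exp(-S)) - omega_na_pred, -500, -1e-12)
    model = DiscreteDFE((s,), (1.0,))
    return FitResult(model=model, theta_site=0.01, r=np.ones(3), logL=logL, k=5,
                     AIC=aic, family=family)


DIV = DivergenceCounts(dN=2000.0, dS=10000.0, L_nonsyn_div=1e5, L_syn_div=1e5)
# omega_obs = 0.2


class TestEstimateMk:
    def test_printed_formula_arithmetic(self):
        est = estimate_mk(fake_fit(0.15), DIV)
        assert est.omega_obs == pytest.approx(0.2)
        assert est.alpha == pytest.approx(0.25, rel=1e-6)
        assert est.omega_a == pytest.approx(0.05, rel=1e-6)
        assert est.omega_na == pytest.approx(0.15, rel=1e-6)

    def test_boundary_alpha_zero(self):
        est = estimate_mk(fake_fit(0.2), DIV)
        assert est.alpha == pytest.approx(0.0, abs=1e-6)
        assert est.omega_a == pytest.approx(0.0, abs=1e-6)

    def test_negative_alpha_allowed(self):
        est = estimate_mk(fake_fit(0.25), DIV)
        assert est.alpha == pytest.approx(-0.25, rel=1e-6)

    def test_identity_omega_a_plus_omega_na(self):
        for pred in (0.05, 0.2, 0.35):
            est = estimate_mk(fake_fit(pred), DIV)
            assert est.omega_a + est.omega_na == pytest.approx(est.omega_obs,
                                                               abs=1e-9)

    def test_zero_ds_rejected(self):
        with pytest.raises(ZeroDivisionError):
            estimate_mk(fake_fit(0.1),
                        DivergenceCounts(10, 0.0, 1e5, 1e5))


class TestModelAverage:
    def test_equal_aics_equal_weights(self):
        np.testing.assert_allclose(aic_weights([10.0, 10.0, 10.0]), np.ones(3) / 3)

    def test_printed_delta_aic_weights(self):
        # exp(0), exp(-1), exp(-2) normalized to sum 1
        w = aic_weights([0.0, 2.0, 4.0])
        expected = np.exp([0.0, -1.0, -2.0])
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)
        np.testing.assert_allclose(w, [0.66524, 0.24473, 0.09003], atol=5e-5)
        # the weight ratios are exp(-dAIC/2)
        assert w[1] / w[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_single_model_identity(self):
        f = fake_fit(0.15)
        est = estimate_mk(f, DIV)
        avg = model_average([(f, est)])
        assert avg.alpha == est.alpha
        assert avg.omega_a == est.omega_a

    def test_average_is_convex_and_identity_holds(self):
        pairs = []
        for fam, (pred, aic) in zip(("GammaZero", "GammaExpo", "ScaledBeta"),
                                    [(0.10, 100.0), (0.15, 101.0), (0.22, 103.0)]):
            f = fake_fit(pred, aic=aic, family=fam)
            pairs.append((f, estimate_mk(f, DIV)))
        avg = model_average(pairs)
        alphas = [e.alpha for _, e in pairs]
        assert min(alphas) <= avg.alpha <= max(alphas)
        assert avg.omega_a + avg.omega_na == pytest.approx(avg.omega_obs, abs=1e-9)
        assert sum(pm.aic_weight for pm in avg.per_model.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            model_average([])


class TestBootstrap:
    def test_same_seed_identical_bounds(self, small_dataset):
        pair, div, _ = small_dataset
        e1, _ = bootstrap_ci(pair, div, ("GammaZero",), B=10, seed=4, opts=FAST)
        e2, _ = bootstrap_ci(pair, div, ("GammaZero",), B=10, seed=4, opts=FAST)
        assert e1.ci == e2.ci

    def test_ci_brackets_point_estimate(self, small_dataset):
        pair, div, _ = small_dataset
        est, draws = bootstrap_ci(pair, div, ("GammaZero",), B=30, seed=1, opts=FAST)
        lo, hi = est.ci["omega_a"]
        assert lo < hi
        assert lo - 0.02 <= est.omega_a <= hi + 0.02
        assert len(draws["omega_a"]) == 30

    def test_degenerate_spectrum_zero_width_sfs_resampling(self):
        # all SNP mass in one class: multinomial resampling returns it intact
        n = 6
        syn = FoldedSFS(n, [200.0, 0.0, 0.0], 1e5, "synonymous")
        non = FoldedSFS(n, [80.0, 0.0, 0.0], 1e5, "nonsynonymous")
        pair = PairedSFS(syn, non, "deg")
        est, draws = bootstrap_ci(pair, DIV, ("GammaZero",), B=10, seed=0,
                                  opts=FAST, resample_divergence=False,
                                  resample_scheme="per_spectrum")
        assert np.ptp(draws["omega_na"]) == pytest.approx(0.0, abs=1e-6)


class TestGroupEstimators:
    def test_averaged_arithmetic(self):
        ests = [MKEstimate(0, 0, na, 0.2) for na in (0.12, 0.14, 0.16)]
        g = DivergenceCounts(2000, 10000, 1e5, 1e5, scope="group_tree")
        assert group_averaged_estimate(ests, g) == pytest.approx(0.06, rel=1e-9)

    def test_averaged_boundary_zero(self):
        g = DivergenceCounts(2000, 10000, 1e5, 1e5, scope="group_tree")
        ests = [MKEstimate(0, 0, 0.2, 0.2)] * 3
        assert group_averaged_estimate(ests, g) == pytest.approx(0.0, abs=1e-12)

    def test_averaged_empty_rejected(self):
        with pytest.raises(ValueError):
            group_averaged_estimate([], DIV)

    def test_pooled_identical_species_equals_single(self, small_dataset):
        pair, div, _ = small_dataset
        gdiv = DivergenceCounts(div.dN, div.dS, div.L_nonsyn_div, div.L_syn_div,
                                scope="group_tree")
        single, _ = mk_analysis(pair, gdiv, ("GammaZero",), FAST)
        pooled, _ = group_pooled_estimate([pair] * 4, gdiv, ("GammaZero",), FAST)
        assert pooled.omega_na == pytest.approx(single.omega_na, rel=1e-2)
        assert pooled.omega_a == pytest.approx(single.omega_a, abs=5e-3)

    def test_pooled_requires_group_tree_scope(self, small_dataset):
        pair, div, _ = small_dataset
        with pytest.raises(ValueError):
            group_pooled_estimate([pair], div, ("GammaZero",), FAST)

    def test_zero_snp_species_excluded_from_pool(self, small_dataset):
        pair, div, _ = small_dataset
        n = pair.sample_size
        empty = PairedSFS(
            FoldedSFS(n, np.zeros(n // 2), 1e5, "synonymous"),
            FoldedSFS(n, np.zeros(n // 2), 1e5, "nonsynonymous"),
            "empty",
        )
        gdiv = DivergenceCounts(div.dN, div.dS, div.L_nonsyn_div, div.L_syn_div,
                                scope="group_tree")
        with pytest.warns(UserWarning, match="zero SNPs"):
            with_empty, _ = group_pooled_estimate([pair, pair, empty], gdiv,
                                                  ("GammaZero",), FAST)
        without, _ = group_pooled_estimate([pair, pair], gdiv, ("GammaZero",), FAST)
        assert with_empty.omega_a == pytest.approx(without.omega_a, rel=1e-6)
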