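import numpy as np
import pytest
from scipy import stats as sps

from mrtool.errors import DegenerateInstrumentError, InsufficientInstrumentsError
from mrtool.estimators import (
    egger,
    ivw,
    run_all_methods,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized, random_harmonized


# ---------------------------------------------------------------------------
# independent oracles (least-squares route, distinct from the closed-form
# sums used by the implementation)

def ivw_oracle(bx, by, se_y):
    """WLS through the origin via lstsq on the weighted design."""
    w = 1.0 / np.asarray(se_y) ** 2
    x = (np.sqrt(w) * bx)[:, None]
    y = np.sqrt(w) * by
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    se = np.sqrt(1.0 / (x[:, 0] @ x[:, 0]))
    return float(beta[0]), float(se)


def egger_oracle(bx, by, se_y):
    """Weighted normal equations solved with a matrix inverse."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / np.asarray(se_y) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    k = len(bx)
    sigma2 = max(1.0, float(resid @ (w * resid)) / (k - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    return (float(coef[1]), float(np.sqrt(cov[1, 1])),
            float(coef[0]), float(np.sqrt(cov[0, 0])))


def weighted_median_oracle(ratios, weights):
    """Brute-force interpolation of the weighted-quantile polyline at 0.5."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    for j in range(len(r) - 1):
        if s[j] <= 0.5 <= s[j + 1]:
            frac = (0.5 - s[j]) / (s[j + 1] - s[j])
            return float(r[j] + frac * (r[j + 1] - r[j]))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------


class TestWaldRatio:
    def test_closed_form(self):
        h = make_harmonized([0.1], [0.05], se_y=[0.02])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.method == "wald"

    def test_zero_outcome_effect(self):
        h = make_harmonized([0.1], [0.0], se_y=[0.02])
        est = wald_ratio(h)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_second_order_se_matches_delta_oracle(self):
        h = make_harmonized([0.1], [0.05], se_x=[0.01], se_y=[0.02])
        est = wald_ratio(h, second_order_se=True)
        expected = np.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.01**2 / 0.1**4)
        assert est.se == pytest.approx(expected, rel=1e-12)

    def test_zero_exposure_effect_raises(self):
        h = make_harmonized([0.0], [0.05])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(h)

    def test_requires_single_snp(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientInstrumentsError):
            wald_ratio(h)


class TestIvw:
    def test_identical_ratios_degenerate_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.25 * bx, se_y=[0.01, 0.02, 0.03])
        est = ivw(h, mode="mre")
        fixed = ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.25, rel=1e-12)
        assert est.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(fixed.se, rel=1e-12)

    def test_two_snp_symmetric_mean(self):
        h = make_harmonized([1.0, 1.0], [0.2, 0.4], se_y=[0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.3, rel=1e-12)

    def test_three_snp_wls_oracle(self):
        bx = [0.10, 0.20, 0.30]
        by = [0.05, 0.08, 0.16]
        se_y = [0.01, 0.02, 0.02]
        beta_o, se_o = ivw_oracle(bx, by, se_y)
        # frozen from the oracle: beta = 210/425
        assert beta_o == pytest.approx(210.0 / 425.0, rel=1e-12)
        est = ivw(make_harmonized(bx, by, se_y=se_y), mode="fixed")
        assert est.beta == pytest.approx(beta_o, abs=1e-10)
        assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_k1_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], [0.05]))

    def test_mre_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, k=6)
            assert ivw(h, "mre").se >= ivw(h, "fixed").se - 1e-15


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.3 * bx, se_y=[0.01] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.02 + 0.3 * bx, se_y=[0.01] * 4)
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extras["egger_intercept"] == pytest.approx(0.02, abs=1e-12)

    def test_noisy_fixture_matches_normal_equations_oracle(self, rng):
        h = random_harmonized(rng, k=5)
        slope_o, se_slope_o, int_o, se_int_o = egger_oracle(h.bx, h.by, h.se_y)
        est = egger(h)
        assert est.beta == pytest.approx(slope_o, abs=1e-10)
        assert est.se == pytest.approx(se_slope_o, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(int_o, abs=1e-10)
        assert est.extras["egger_intercept_se"] == pytest.approx(se_int_o, abs=1e-10)

    def test_pvalues_are_t_with_k_minus_2_df(self, rng):
        h = random_harmonized(rng, k=5)
        est = egger(h)
        expected = 2.0 * sps.t.sf(abs(est.beta / est.se), 3)
        assert est.pval == pytest.approx(expected, rel=1e-12)

    def test_k2_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1]))

    def test_orientation_invariance(self, rng):
        h = random_harmonized(rng, k=6)
        flip = np.sign(rng.normal(size=6))
        h2 = make_harmonized(h.bx * flip, h.by * flip, h.se_x, h.se_y)
        a, b = egger(h), egger(h2)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.extras["egger_intercept"] == pytest.approx(
            b.extras["egger_intercept"], rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_odd_k_is_plain_median(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        h = make_harmonized(bx, by, se_y=[0.1] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, rel=1e-12)

    def test_majority_weight_snp_returned(self):
        # middle-ranked SNP carries weight 0.6: cumulative midpoint hits 0.5
        # inside it, so its ratio is the estimate
        bx = np.array([1.0, np.sqrt(3.0), 1.0])
        by = np.array([0.1, 0.5 * np.sqrt(3.0), 0.9])
        h = make_harmonized(bx, by, se_y=[0.1] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, rel=1e-12)

    def test_five_snp_interpolation_oracle(self):
        bx = np.array([0.1, 0.2, 0.1, 0.2, 0.1])
        by = np.array([0.01, 0.08, 0.03, 0.02, 0.05])
        se_y = np.array([0.01, 0.02, 0.01, 0.015, 0.02])
        h = make_harmonized(bx, by, se_y=se_y)
        expected = weighted_median_oracle(by / bx, bx**2 / se_y**2)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_seeded_reproducible(self, rng):
        h = random_harmonized(rng, k=5)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se
        c = weighted_median(h, n_boot=200, seed=8)
        assert a.se != c.se

    def test_k2_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_harmonized([0.1, 0.2], [0.05, 0.1]))


class TestEquivariance:
    """Scaling by and se_y by c scales every estimator's beta and se by c."""

    @pytest.mark.parametrize("c", [2.0, 0.5, 10.0])
    def test_ivw_and_egger(self, rng, c):
        h = random_harmonized(rng, k=6)
        hs = make_harmonized(h.bx, c * h.by, h.se_x, c * h.se_y)
        for fn in (lambda x: ivw(x, "mre"), egger):
            a, b = fn(h), fn(hs)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-10)
            assert b.se == pytest.approx(c * a.se, rel=1e-10)
            assert b.pval == pytest.approx(a.pval, rel=1e-9)

    def test_weighted_median_point_estimate(self, rng):
        c = 3.0
        h = random_harmonized(rng, k=6)
        hs = make_harmonized(h.bx, c * h.by, h.se_x, c * h.se_y)
        a = weighted_median(h, n_boot=10, seed=1)
        b = weighted_median(hs, n_boot=10, seed=1)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-10)

    def test_wald(self):
        h = make_harmonized([0.1], [0.05], se_y=[0.02])
        hs = make_harmonized([0.1], [0.1], se_y=[0.04])
        a, b = wald_ratio(h), wald_ratio(hs)
        assert b.beta == pytest.approx(2 * a.beta)
        assert b.se == pytest.approx(2 * a.se)


class TestRunAllMethods:
    def test_k1_wald_only(self):
        h = make_harmonized([0.1], [0.05])
        out = run_all_methods(h, seed=0)
        assert [e.method for e in out] == ["wald"]

    def test_k2_ivw_only(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        out = run_all_methods(h, seed=0)
        assert [e.method for e in out] == ["ivw"]

    def test_k5_three_methods(self, rng):
        h = random_harmonized(rng, k=5)
        out = run_all_methods(h, n_boot=50, seed=0)
        assert [e.method for e in out] == ["ivw", "egger", "weighted_median"]
        assert all(e.n_snp == 5 for e in out)

    def test_empty_raises(self):
        h = make_harmonized([], [])
        with pytest.raises(InsufficientInstrumentsError):
            run_all_methods(h)

    def test_sign_concordance_without_pleiotropy(self):
        from mrtool.harmonize import HarmonizedSet
        from mrtool.simulate import SimTruth, simulate_pair
        exp, out, _, truth = simulate_pair(
            SimTruth(beta_causal=0.15, n_instruments=40, n_null_snps=0,
                     n_x=50_000, n_y=50_000, seed=99))
        ids = exp.snp_ids
        from mrtool.harmonize import harmonize
        h = harmonize(exp, out, ids)
        out_all = run_all_methods(h, n_boot=100, seed=3)
        assert all(np.sign(e.beta) == np.sign(truth.beta_causal)
                   for e in out_all)
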