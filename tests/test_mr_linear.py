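"""Closed-form and property tests for the linear MR estimators."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sleepmr import mr_linear as mrl
from sleepmr.instruments import HarmonizedInstruments


def make_h(bx, by, se_by, se_bx=None):
    bx = np.asarray(bx, float)
    if se_bx is None:
        se_bx = np.full_like(bx, 0.01)
    table = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(bx))],
            "bx": bx,
            "se_bx": se_bx,
            "by": np.asarray(by, float),
            "se_by": np.asarray(se_by, float),
        }
    )
    return HarmonizedInstruments(table, pd.DataFrame(columns=["snp", "reason"]))


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,se_bx,by,se_by,beta,se",
        [
            (0.1, 0.01, 0.05, 0.01, 0.5, 0.1),
            (0.2, 0.01, 0.05, 0.02, 0.25, 0.1),
            (0.1, 0.01, 0.0, 0.01, 0.0, 0.1),
        ],
    )
    def test_known_values(self, bx, se_bx, by, se_by, beta, se):
        est = mrl.wald_ratio(bx, se_bx, by, se_by)
        assert est.beta == pytest.approx(beta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_zero_bx_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mrl.wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_ci_contract(self):
        est = mrl.wald_ratio(0.1, 0.01, 0.05, 0.01)
        lcl, ucl = est.ci95
        assert lcl == pytest.approx(est.beta - 1.96 * est.se)
        assert ucl == pytest.approx(est.beta + 1.96 * est.se)


class TestIVW:
    def test_three_instrument_fixture(self):
        h = make_h([0.1, 0.2, 0.3], [0.06, 0.08, 0.12], [0.01, 0.01, 0.01])
        est = mrl.ivw(h)
        assert est.beta == pytest.approx(0.058 / 0.14, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(1400), abs=1e-12)

    def test_single_instrument_reduces_to_wald(self):
        h = make_h([0.2], [0.05], [0.02])
        est = mrl.ivw(h)
        wald = mrl.wald_ratio(0.2, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wald.beta, abs=1e-14)
        assert est.se == pytest.approx(wald.se, abs=1e-14)

    def test_linearity_in_outcome(self, rng):
        bx = rng.normal(0.1, 0.03, size=8)
        by = rng.normal(0.05, 0.02, size=8)
        se = rng.uniform(0.01, 0.05, size=8)
        b1 = mrl.ivw(make_h(bx, by, se)).beta
        b2 = mrl.ivw(make_h(bx, 3.0 * by, se)).beta
        assert b2 == pytest.approx(3.0 * b1, rel=1e-12)

    def test_order_and_signflip_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, size=10)
        by = rng.normal(0.05, 0.02, size=10)
        se = rng.uniform(0.01, 0.05, size=10)
        base = mrl.ivw(make_h(bx, by, se)).beta
        perm = rng.permutation(10)
        assert mrl.ivw(make_h(bx[perm], by[perm], se[perm])).beta == pytest.approx(
            base, rel=1e-12
        )
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        assert mrl.ivw(make_h(bx2, by2, se)).beta == pytest.approx(base, rel=1e-12)

    def test_matches_wls_through_origin(self, rng):
        """Oracle: weighted least squares of by on bx without intercept."""
        bx = rng.normal(0.1, 0.05, size=12)
        by = rng.normal(0.05, 0.02, size=12)
        se = rng.uniform(0.01, 0.05, size=12)
        fit = sm.WLS(by, bx[:, None], weights=1 / se**2).fit()
        assert mrl.ivw(make_h(bx, by, se)).beta == pytest.approx(
            fit.params[0], abs=1e-10
        )


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        est = mrl.egger(make_h(bx, by, [0.01, 0.02, 0.015]))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_line_through_origin_matches_ivw(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.5 * bx
        h = make_h(bx, by, [0.01, 0.02, 0.015])
        est = mrl.egger(h)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(mrl.ivw(h).beta, abs=1e-10)

    def test_orientation_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, size=10)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.005, size=10)
        se = rng.uniform(0.01, 0.03, size=10)
        base = mrl.egger(make_h(bx, by, se))
        bx2, by2 = -bx, -by  # flipping every instrument's coding
        flipped = mrl.egger(make_h(bx2, by2, se))
        assert flipped.beta == pytest.approx(base.beta, rel=1e-10)
        assert flipped.egger_intercept == pytest.approx(base.egger_intercept, rel=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        bx = np.abs(rng.normal(0.1, 0.05, size=15)) + 0.01
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.01, size=15)
        se = rng.uniform(0.01, 0.03, size=15)
        est = mrl.egger(make_h(bx, by, se))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / se**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-weight SEs: statsmodels scales inv(X'WX) by the residual MSE
        assert est.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale), rel=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            mrl.egger(make_h([0.1, 0.2], [0.05, 0.06], [0.01, 0.01]))
        with pytest.raises(ValueError):
            mrl.egger(make_h([0.1, 0.1, 0.1], [0.05, 0.06, 0.04], [0.01] * 3))


class TestWeightedMedian:
    def test_three_equal_weight_ratios(self):
        h = make_h([1.0, 1.0, 1.0], [0.4, 0.5, 0.6], [1.0, 1.0, 1.0])
        est = mrl.weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_identical_ratios_degenerate_spread(self):
        h = make_h([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], [1e-8] * 3, se_bx=[1e-8] * 3)
        est = mrl.weighted_median(h, n_boot=100, seed=2)
        assert est.beta == pytest.approx(0.3, abs=1e-9)
        assert est.se < 1e-6

    def test_outlier_with_small_weight_resisted(self):
        """Oracle: interpolation formula keeps the estimate in the
        concordant range when one small-weight ratio is wild."""
        bx = np.array([1.0] * 9 + [0.1])
        by = np.r_[np.linspace(0.45, 0.55, 9), 0.5]  # last ratio = 5.0, weight 1%
        h = make_h(bx, by, [0.1] * 10)
        est = mrl.weighted_median(h, n_boot=50, seed=3)
        assert 0.45 <= est.beta <= 0.55

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(10):
            bx = rng.normal(0.2, 0.05, size=7)
            by = rng.normal(0.1, 0.05, size=7)
            se = rng.uniform(0.01, 0.1, size=7)
            h = make_h(bx, by, se)
            est = mrl.weighted_median(h, n_boot=20, seed=4)
            r = by / bx
            assert r.min() - 1e-12 <= est.beta <= r.max() + 1e-12

    def test_zero_bx_dropped_and_minimum_enforced(self):
        h = make_h([0.0, 0.1, 0.2, 0.3], [0.01, 0.05, 0.1, 0.15], [0.01] * 4)
        est = mrl.weighted_median(h, n_boot=20, seed=5)
        assert est.n_snps == 3 and "dropped 1" in est.note
        with pytest.raises(ValueError):
            mrl.weighted_median(make_h([0.0, 0.0, 0.1], [0, 0, 0.05], [0.01] * 3))

    def test_bootstrap_seeded(self):
        h = make_h([0.1, 0.2, 0.3], [0.06, 0.08, 0.12], [0.01] * 3)
        a = mrl.weighted_median(h, n_boot=200, seed=11)
        b = mrl.weighted_median(h, n_boot=200, seed=11)
        assert a.se == b.se


class TestMetaFixed:
    def test_two_estimate_fixture(self):
        a = mrl.MREstimate("ivw", 0.5, 0.1, 0.0, 5)
        b = mrl.MREstimate("ivw", 0.3, 0.1, 0.0, 5)
        pooled = mrl.meta_fixed([a, b])
        assert pooled.beta == pytest.approx(0.4, abs=1e-12)
        assert pooled.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-6)

    def test_replication_shrinks_se_by_sqrt2(self):
        a = mrl.MREstimate("ivw", 0.42, 0.07, 0.0, 5)
        pooled = mrl.meta_fixed([a, a])
        assert pooled.beta == pytest.approx(0.42)
        assert pooled.se == pytest.approx(0.07 / np.sqrt(2), rel=1e-12)

    def test_infinite_se_gets_zero_weight(self):
        a = mrl.MREstimate("ivw", 0.5, 0.1, 0.0, 5)
        b = mrl.MREstimate("ivw", -3.0, 1e6, 0.0, 5)
        pooled = mrl.meta_fixed([a, b])
        assert pooled.beta == pytest.approx(0.5, abs=1e-6)

    def test_single_estimate_passthrough_with_warning(self):
        a = mrl.MREstimate("ivw", 0.5, 0.1, 0.0, 5)
        pooled = mrl.meta_fixed([a])
        assert pooled.beta == a.beta and "single estimate" in pooled.note


class TestRerunExcluding:
    def test_no_op_equals_ivw(self, rng):
        bx = rng.normal(0.1, 0.03, size=6)
        by = rng.normal(0.05, 0.02, size=6)
        h = make_h(bx, by, rng.uniform(0.01, 0.05, size=6))
        assert mrl.rerun_excluding(h, []).beta == pytest.approx(mrl.ivw(h).beta)

    def test_redundant_instrument_removal_keeps_estimate(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.5 * bx  # perfectly consistent
        h = make_h(bx, by, [0.01] * 3)
        est = mrl.rerun_excluding(h, ["rs1"])
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert "rs1" in est.note

    def test_change_equals_weight_share_identity(self):
        """Oracle: recompute both weighted sums after dropping one SNP."""
        bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.1, 0.2, 0.3, 0.12, 0.22])
        by = 0.5 * bx
        by[0] = 0.2  # discordant ratio 2.0
        se = np.full(10, 0.01)
        h = make_h(bx, by, se)
        full = mrl.ivw(h).beta
        dropped = mrl.rerun_excluding(h, ["rs0"]).beta
        w = bx**2 / se**2
        ratio0 = by[0] / bx[0]
        expected_change = w[0] * (full - ratio0) / (w.sum() - w[0])
        assert dropped - full == pytest.approx(expected_change, rel=1e-10)

    def test_all_excluded_rejected(self):
        h = make_h([0.1], [0.05], [0.01])
        with pytest.raises(ValueError):
            mrl.rerun_excluding(h, ["rs0"])


class TestOverlapBias:
    def test_two_sample_limit(self):
        assert mrl.overlap_bias(0.0, 0.17, 34.0).bias == 0.0

    def test_full_overlap_fixture(self):
        ob = mrl.overlap_bias(1.0, 0.17, 34.0)
        assert ob.bias == pytest.approx(0.17 / 34.0, abs=1e-12)
        assert ob.bias == pytest.approx(0.005, abs=1e-12)

    def test_inverse_proportionality_in_f(self):
        b1 = mrl.overlap_bias(1.0, 0.2, 20.0).bias
        b2 = mrl.overlap_bias(1.0, 0.2, 40.0).bias
        assert b1 == pytest.approx(2 * b2)

    def test_type1_at_zero_bias_is_alpha(self):
        ob = mrl.overlap_bias(0.0, 0.17, 34.0, alpha=0.05, se=0.01)
        assert ob.type1 == pytest.approx(0.05, abs=1e-10)

    def test_type1_inflates_with_bias(self):
        ob = mrl.overlap_bias(1.0, 0.5, 10.0, alpha=0.05, se=0.02)
        assert ob.type1 > 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mrl.overlap_bias(1.5, 0.1, 10.0)
        with pytest.raises(ValueError):
            mrl.overlap_bias(0.5, 0.1, 0.0)
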