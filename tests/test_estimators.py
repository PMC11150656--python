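import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrbmd.estimators import (ivw, mr_egger, summarize_estimate, wald_ratio,
                              weighted_median, weighted_mode)
from mrbmd.exceptions import DomainError, InsufficientInstrumentsError

from conftest import make_pair, pairs_from_ratios, simulated_pairs

# hand-computable instance: ratios {0.2, 0.25, 0.2}, ratio SEs {0.1, 0.1, 0.05}
# -> weights {100, 100, 400}, weighted mean 125/600
ORACLE_RATIOS = [0.2, 0.25, 0.2]
ORACLE_SES = [0.1, 0.1, 0.05]
ORACLE_BETA = 125.0 / 600.0       # 0.208333...
ORACLE_FE_SE = 600.0 ** -0.5      # 0.040825...


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.05, se_out=0.02))
        assert math.isclose(est.beta, 0.5) and math.isclose(est.se, 0.2)

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(make_pair(beta_out=0.0))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(DomainError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_negative_exposure_effect_uses_abs_in_se(self):
        est = wald_ratio(make_pair(beta_exp=-0.1, beta_out=0.05, se_out=0.02))
        assert math.isclose(est.beta, -0.5) and math.isclose(est.se, 0.2)


class TestIVW:
    def test_closed_form_weighted_mean(self):
        pairs = pairs_from_ratios(ORACLE_RATIOS, ORACLE_SES)
        est = ivw(pairs, model="fixed")
        assert math.isclose(est.beta, ORACLE_BETA, rel_tol=1e-12)
        assert math.isclose(est.se, ORACLE_FE_SE, rel_tol=1e-12)

    def test_identical_pairs_degenerate_heterogeneity(self):
        pairs = pairs_from_ratios([0.3] * 4, [0.1] * 4)
        fe = ivw(pairs, model="fixed")
        re = ivw(pairs, model="multiplicative_random")
        assert math.isclose(fe.beta, 0.3) and math.isclose(re.beta, 0.3)
        assert math.isclose(fe.se, re.se)  # Q = 0 -> scale floored at 1

    def test_k1_equals_wald_ratio(self):
        pair = make_pair(beta_exp=0.08, beta_out=0.02, se_out=0.015)
        w = wald_ratio(pair)
        i = ivw([pair])
        assert math.isclose(i.beta, w.beta) and math.isclose(i.se, w.se)
        assert math.isclose(i.pval, w.pval)

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([])

    def test_matches_wls_through_origin(self):
        """Independent route: IVW == statsmodels WLS with no intercept."""
        pairs, _ = simulated_pairs(seed=11)
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        w = np.array([1 / p.se_out**2 for p in pairs])
        fit = sm.WLS(by, bx[:, None], weights=w).fit()
        est = ivw(pairs, model="fixed")
        assert math.isclose(est.beta, fit.params[0], rel_tol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sign_flip_invariance(self, seed):
        pairs, _ = simulated_pairs(seed=seed, n_snps=8)
        rng = np.random.default_rng(seed)
        flipped = []
        for p in pairs:
            if rng.random() < 0.5:
                flipped.append(make_pair(snp_id=p.snp_id, beta_exp=-p.beta_exp,
                                         se_exp=p.se_exp, beta_out=-p.beta_out,
                                         se_out=p.se_out))
            else:
                flipped.append(p)
        assert math.isclose(ivw(pairs).beta, ivw(flipped).beta, rel_tol=1e-12)


class TestMREgger:
    def test_exact_pleiotropic_line(self):
        # beta_out = 0.05 + 0.3 * beta_exp exactly
        bx = [0.05, 0.1, 0.15, 0.2]
        pairs = [make_pair(snp_id=f"rs{i}", beta_exp=b, beta_out=0.05 + 0.3 * b,
                           se_out=0.02) for i, b in enumerate(bx)]
        slope, intercept = mr_egger(pairs)
        assert math.isclose(slope.beta, 0.3, abs_tol=1e-10)
        assert math.isclose(intercept.intercept, 0.05, abs_tol=1e-10)

    def test_zero_intercept_line_pvalue_one(self):
        bx = [0.05, 0.1, 0.15]
        pairs = [make_pair(snp_id=f"rs{i}", beta_exp=b, beta_out=0.3 * b,
                           se_out=0.02) for i, b in enumerate(bx)]
        _, intercept = mr_egger(pairs)
        assert math.isclose(intercept.intercept, 0.0, abs_tol=1e-12)
        assert intercept.pval == pytest.approx(1.0)

    def test_against_statsmodels_wls_oracle(self):
        pairs, _ = simulated_pairs(seed=3, n_snps=10,
                                   pleiotropy_mean=0.01, pleiotropy_sd=0.01)
        bx = np.array([abs(p.beta_exp) for p in pairs])
        by = np.array([p.beta_out * np.sign(p.beta_exp) for p in pairs])
        w = np.array([1 / p.se_out**2 for p in pairs])
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        slope, intercept = mr_egger(pairs)
        assert math.isclose(slope.beta, fit.params[1], rel_tol=1e-10)
        assert math.isclose(intercept.intercept, fit.params[0], rel_tol=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([make_pair(), make_pair(snp_id="rs2")])

    def test_orientation_invariance(self):
        pairs, _ = simulated_pairs(seed=5, n_snps=6)
        flipped = [make_pair(snp_id=p.snp_id, beta_exp=-p.beta_exp,
                             se_exp=p.se_exp, beta_out=-p.beta_out,
                             se_out=p.se_out) for p in pairs]
        s1, i1 = mr_egger(pairs)
        s2, i2 = mr_egger(flipped)
        assert math.isclose(s1.beta, s2.beta, rel_tol=1e-12)
        assert math.isclose(i1.intercept, i2.intercept, rel_tol=1e-12)


class TestWeightedMedian:
    def test_hand_interpolation(self):
        # normalized weights {0.25, 0.25, 0.5} -> S = {0.125, 0.375, 0.75};
        # interpolation of the ratio at S = 0.5 gives 0.2333...
        ratio_ses = [math.sqrt(2), math.sqrt(2), 1.0]
        pairs = pairs_from_ratios([0.1, 0.2, 0.3], ratio_ses)
        est = weighted_median(pairs, n_boot=200, seed=1)
        assert math.isclose(est.beta, 0.2 + 0.125 / 0.375 * 0.1, rel_tol=1e-9)
        assert math.isclose(est.beta, 0.2333, abs_tol=5e-5)

    def test_constant_ratios(self):
        pairs = pairs_from_ratios([0.42] * 3, [0.1, 0.2, 0.3])
        assert math.isclose(weighted_median(pairs, n_boot=50, seed=1).beta, 0.42)

    def test_seed_reproducibility(self):
        pairs, _ = simulated_pairs(seed=9, n_snps=8)
        a = weighted_median(pairs, n_boot=300, seed=5)
        b = weighted_median(pairs, n_boot=300, seed=5)
        assert a == b

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([make_pair()], seed=0)


class TestWeightedMode:
    def test_dominant_cluster(self):
        pairs = pairs_from_ratios([0.30, 0.30, 0.30, 0.9],
                                  [0.05, 0.05, 0.05, 0.5])
        est = weighted_mode(pairs, n_boot=100, seed=2)
        assert abs(est.beta - 0.30) < 0.05

    def test_constant_ratios(self):
        pairs = pairs_from_ratios([0.3] * 3, [0.1] * 3)
        assert weighted_mode(pairs, n_boot=50, seed=1).beta == 0.3

    def test_seed_reproducibility(self):
        pairs, _ = simulated_pairs(seed=13, n_snps=8)
        a = weighted_mode(pairs, n_boot=200, seed=5)
        b = weighted_mode(pairs, n_boot=200, seed=5)
        assert a == b


class TestSummarizeEstimate:
    @pytest.mark.parametrize("beta,se,or_p,ci,pv", [
        (0.280, 0.0781, 1.323, (1.135, 1.542), 0.0003),
        (-0.0488, 0.0195, 0.952, None, 0.012),
    ])
    def test_published_cells_at_reporting_precision(self, beta, se, or_p, ci, pv):
        or_, lo, hi, p = summarize_estimate(beta, se)
        assert round(or_, 3) == or_p
        if ci is not None:
            assert round(lo, 3) == ci[0] and round(hi, 3) == ci[1]
        ndigits = len(str(pv).split(".")[1])
        assert round(p, ndigits) == pv

    def test_null_estimate(self):
        or_, lo, hi, p = summarize_estimate(0.0, 0.1)
        assert or_ == 1.0 and p == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_nonpositive_se_errors(self):
        with pytest.raises(DomainError):
            summarize_estimate(0.1, 0.0)

    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_beta(self, b1, b2, se):
        lo_b, hi_b = sorted((b1, b2))
        r1 = summarize_estimate(lo_b, se)
        r2 = summarize_estimate(hi_b, se)
        assert r1[0] <= r2[0] and r1[1] <= r2[1] and r1[2] <= r2[2]


class TestEstimatorAgreement:
    def test_all_methods_agree_on_clean_data(self):
        """No pleiotropy + strong instruments: all five estimators agree
        within 3 combined SEs."""
        pairs, truth = simulated_pairs(seed=21, n_snps=30)
        ests = {
            "ivw": ivw(pairs),
            "egger": mr_egger(pairs)[0],
            "median": weighted_median(pairs, n_boot=300, seed=4),
            "mode": weighted_mode(pairs, n_boot=100, seed=4),
            "wald_first": wald_ratio(pairs[0]),
        }
        ref = ests["ivw"]
        for name, est in ests.items():
            tol = 3 * max(est.se, ref.se)
            assert abs(est.beta - ref.beta) <= tol, name

    def test_egger_equals_ivw_when_intercept_zero(self):
        bx = [0.05, 0.1, 0.15, 0.2]
        pairs = [make_pair(snp_id=f"rs{i}", beta_exp=b, beta_out=0.3 * b,
                           se_out=0.02) for i, b in enumerate(bx)]
        slope, intercept = mr_egger(pairs)
        assert math.isclose(intercept.intercept, 0.0, abs_tol=1e-12)
        assert math.isclose(slope.beta, ivw(pairs, model="fixed").beta,
                            abs_tol=1e-10)
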