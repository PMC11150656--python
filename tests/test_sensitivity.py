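import math

import numpy as np
import pytest

from mrbmd.estimators import ivw
from mrbmd.exceptions import DomainError, InsufficientInstrumentsError
from mrbmd.sensitivity import (cochran_q, leave_one_out, mr_presso,
                               pleiotropy_screen, snp_r2_from_t, steiger_test)

from conftest import make_pair, pairs_from_ratios, simulated_pairs

ORACLE_RATIOS = [0.2, 0.25, 0.2]
ORACLE_SES = [0.1, 0.1, 0.05]
ORACLE_BETA = 125.0 / 600.0


class TestCochranQ:
    def test_hand_arithmetic(self):
        pairs = pairs_from_ratios(ORACLE_RATIOS, ORACLE_SES)
        res = cochran_q(pairs, beta_ref=ORACLE_BETA)
        # 100*(0.2-beta)^2 + 100*(0.25-beta)^2 + 400*(0.2-beta)^2
        assert math.isclose(res.q, 0.20833, abs_tol=5e-5)
        assert res.df == 2

    def test_identical_ratios(self):
        pairs = pairs_from_ratios([0.3] * 4, [0.1] * 4)
        res = cochran_q(pairs)
        assert res.q == pytest.approx(0.0, abs=1e-20) and res.pval == pytest.approx(1.0)

    def test_minimal_at_ivw_estimate(self):
        pairs = pairs_from_ratios(ORACLE_RATIOS, ORACLE_SES)
        q_at_ivw = cochran_q(pairs, beta_ref=ORACLE_BETA).q
        for ref in np.linspace(ORACLE_BETA - 0.1, ORACLE_BETA + 0.1, 21):
            assert cochran_q(pairs, beta_ref=float(ref)).q >= q_at_ivw - 1e-12

    def test_default_reference_is_fixed_effects_ivw(self):
        pairs, _ = simulated_pairs(seed=2, n_snps=10)
        assert math.isclose(cochran_q(pairs).q,
                            cochran_q(pairs, ivw(pairs, model="fixed").beta).q,
                            rel_tol=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q([make_pair()])


class TestLeaveOneOut:
    def test_concordant_pairs_no_flags(self):
        pairs = pairs_from_ratios([0.2, 0.22, 0.19, 0.21, 0.2], [0.05] * 5)
        records = leave_one_out(pairs)
        assert len(records) == 5
        assert not any(r.sign_flip for r in records)

    def test_dominant_discordant_snp_flagged(self):
        # one huge-weight SNP with opposite-sign ratio determines the overall
        # sign; omitting it flips the estimate
        pairs = pairs_from_ratios([0.3, 0.35, -0.5], [0.5, 0.5, 0.01])
        records = leave_one_out(pairs)
        flags = {r.omitted_snp: r.sign_flip for r in records}
        assert flags["rs3"] and not flags["rs1"] and not flags["rs2"]

    def test_k2_delegates_to_wald(self):
        from mrbmd.estimators import wald_ratio
        pairs = pairs_from_ratios([0.2, 0.3], [0.1, 0.1])
        records = leave_one_out(pairs)
        assert math.isclose(records[0].beta, wald_ratio(pairs[1]).beta)
        assert math.isclose(records[1].beta, wald_ratio(pairs[0]).beta)

    def test_zero_weight_snp_changes_nothing(self):
        pairs, _ = simulated_pairs(seed=4, n_snps=10)
        ghost = make_pair(snp_id="ghost", beta_exp=0.05, se_exp=0.01,
                          beta_out=5.0, se_out=1e6)
        full = ivw(pairs, model="fixed")
        records = leave_one_out(list(pairs) + [ghost], model="fixed")
        ghost_rec = next(r for r in records if r.omitted_snp == "ghost")
        assert math.isclose(ghost_rec.beta, full.beta, rel_tol=1e-9)


class TestMRPresso:
    def test_requires_four_instruments(self):
        pairs = pairs_from_ratios([0.2, 0.3, 0.25], [0.1] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(pairs, seed=1)

    def test_clean_data_not_significant(self):
        pairs, _ = simulated_pairs(seed=100, n_snps=20)
        res = mr_presso(pairs, n_sim=500, seed=42)
        assert res.global_pval > 0.05
        assert res.outlier_indices == []
        assert res.beta_corrected is None

    def test_planted_outlier_recovered(self):
        pairs, truth = simulated_pairs(seed=200, n_snps=20, outlier_count=1,
                                       outlier_scale=10.0)
        res = mr_presso(pairs, n_sim=500, seed=42)
        assert res.global_pval < 0.05
        assert set(truth.outlier_ids) <= set(res.outlier_indices)
        assert res.beta_corrected is not None
        # corrected estimate is closer to the truth than the raw one
        assert abs(res.beta_corrected - truth.beta_causal) <= abs(
            res.beta_raw - truth.beta_causal)

    def test_seed_reproducibility(self):
        pairs, _ = simulated_pairs(seed=300, n_snps=15, outlier_count=1)
        a = mr_presso(pairs, n_sim=200, seed=9)
        b = mr_presso(pairs, n_sim=200, seed=9)
        assert a.global_pval == b.global_pval and a.global_rss == b.global_rss


class TestSteiger:
    def test_single_snp_closed_form(self):
        assert math.isclose(snp_r2_from_t(10.0, 1000), 100.0 / 1098.0,
                            rel_tol=1e-12)

    def test_symmetric_r2_gives_p_one_direction_false(self):
        pair = make_pair(beta_exp=0.1, se_exp=0.02, beta_out=0.1, se_out=0.02,
                         n_exp=10_000, n_out=10_000)
        res = steiger_test([pair])
        assert res.r2_exp == res.r2_out
        assert not res.correct_direction
        assert res.pval == pytest.approx(1.0)

    def test_strong_asymmetry(self):
        # r2_exp ~ 0.09 vs r2_out ~ 1e-4 at n = 10,000 on both sides
        t_exp = math.sqrt(0.09 * 9998 / 0.91)
        t_out = math.sqrt(1e-4 * 9998 / (1 - 1e-4))
        pair = make_pair(beta_exp=t_exp * 0.01, se_exp=0.01,
                         beta_out=t_out * 0.01, se_out=0.01,
                         n_exp=10_000, n_out=10_000)
        res = steiger_test([pair])
        assert res.correct_direction
        assert res.pval < 1e-6

    def test_small_sample_errors(self):
        with pytest.raises(DomainError):
            steiger_test([make_pair()], n_exp=3, n_out=100)

    def test_simulated_causal_direction(self):
        pairs, _ = simulated_pairs(seed=8)
        assert steiger_test(pairs).correct_direction


class TestPleiotropyScreen:
    def test_zero_intercept_line_not_detected(self):
        bx = [0.05, 0.1, 0.15, 0.2]
        pairs = [make_pair(snp_id=f"rs{i}", beta_exp=b, beta_out=0.3 * b,
                           se_out=0.02) for i, b in enumerate(bx)]
        intercept, detected = pleiotropy_screen(pairs)
        assert not detected and intercept.pval > 0.05

    def test_directional_pleiotropy_detected_in_majority_of_seeds(self):
        detected_count = 0
        n_seeds = 20
        for s in range(n_seeds):
            # directional pleiotropy about 3x the outcome-side SE
            pairs, _ = simulated_pairs(seed=500 + s, n_snps=50,
                                       pleiotropy_mean=0.025,
                                       pleiotropy_sd=0.005)
            _, detected = pleiotropy_screen(pairs)
            detected_count += detected
        assert detected_count > n_seeds / 2

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            pleiotropy_screen([make_pair(), make_pair(snp_id="rs2")])
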