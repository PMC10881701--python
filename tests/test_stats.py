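import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from intralobe.stats import (
    covariate_test,
    fisher_exact_rxc,
    fit_two_level_lmm,
    log_ratio_test,
    paired_t_test,
    proportion_increased,
)
from intralobe.synthetic import simulate_paired_tn, simulate_tn_long

from oracles import brute_fisher_2or3_rows


def pairs(tn_ia, tn_control, cycle=1):
    n = len(tn_ia)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)], "cycle": cycle,
        "tn_ia": tn_ia, "tn_control": tn_control,
    })


class TestPairedT:
    def test_hand_computed_example(self):
        # diffs (2, 3, 2): mean 7/3, sd 1/sqrt(3), t = 7, df = 2
        r = paired_t_test(pairs([3, 5, 4], [1, 2, 2]))
        assert r.mean_difference == pytest.approx(7 / 3)
        assert r.t_statistic == pytest.approx(7.0)
        assert r.df == 2
        assert r.p_value == pytest.approx(2 * sps.t.sf(7.0, 2))

    def test_identical_columns(self):
        r = paired_t_test(pairs([4, 6, 5], [4, 6, 5]))
        assert r.mean_difference == 0.0
        assert r.p_value == 1.0
        assert r.ci_low == r.ci_high == 0.0

    def test_antisymmetry(self, rng):
        a = rng.uniform(5, 20, 8)
        b = rng.uniform(5, 20, 8)
        r1 = paired_t_test(pairs(a, b))
        r2 = paired_t_test(pairs(b, a))
        assert r1.mean_difference == pytest.approx(-r2.mean_difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_missing_side_dropped(self):
        df = pairs([3, 5, 4, 7], [1, 2, 2, None])
        r = paired_t_test(df)
        assert r.n == 3

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test(pairs([3], [1]))


class TestLogRatio:
    def test_three_pair_example_matches_log_oracle(self):
        ia, ctrl = [3.0, 5.0, 4.0], [1.0, 2.0, 2.0]
        r = log_ratio_test(pairs(ia, ctrl))
        d = np.log(ia) - np.log(ctrl)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        half = sps.t.ppf(0.975, 2) * d.std(ddof=1) / math.sqrt(3)
        assert r.geometric_ratio == pytest.approx(math.exp(d.mean()))
        assert r.ci_low == pytest.approx(math.exp(d.mean() - half))
        assert r.ci_high == pytest.approx(math.exp(d.mean() + half))
        assert r.p_value == pytest.approx(2 * sps.t.sf(abs(t), 2))

    def test_constant_ratio_degenerate(self):
        ctrl = [2.0, 4.0, 8.0]
        r = log_ratio_test(pairs([2.4, 4.8, 9.6], ctrl))
        assert r.geometric_ratio == pytest.approx(1.2)
        assert r.ci_low == pytest.approx(1.2)
        assert r.ci_high == pytest.approx(1.2)
        assert math.isnan(r.p_value)
        assert r.degenerate

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            log_ratio_test(pairs([3, -1, 4], [1, 2, 2]))

    def test_invariant_to_common_rescaling(self, rng):
        a = rng.uniform(5, 30, 10)
        b = rng.uniform(5, 30, 10)
        r1 = log_ratio_test(pairs(a, b))
        r2 = log_ratio_test(pairs(a * 7.3, b * 7.3))
        assert r1.geometric_ratio == pytest.approx(r2.geometric_ratio)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_parameter_recovery_at_study_conditions(self, rng):
        """Calibrated cohorts (n=27, ratio 1.17, log SD 0.39): the average
        recovered geometric ratio over 200 cohorts is close to 1.17."""
        estimates = [
            log_ratio_test(simulate_paired_tn(27, 1.17, 0.39, rng)).geometric_ratio
            for _ in range(200)
        ]
        log_est = np.log(estimates)
        se = log_est.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(log_est.mean() - np.log(1.17)) <= 3 * se


class TestLMM:
    def test_single_cycle_equals_paired_t(self, rng):
        df = simulate_paired_tn(15, 1.3, 0.4, rng)
        lmm = fit_two_level_lmm(df)
        pt = paired_t_test(df)
        assert lmm.fixed_effect_arm == pytest.approx(pt.mean_difference, rel=1e-6)
        assert lmm.var_cycle_within_patient == 0.0

    def test_variance_components_recovered(self, rng):
        df = simulate_tn_long(40, 4, 0.2, rng, patient_sd=0.7, cycle_sd=0.3,
                              residual_sd=0.2)
        r = fit_two_level_lmm(df, log_scale=True)
        assert r.fixed_effect_arm == pytest.approx(0.2, abs=0.1)
        assert r.var_patient == pytest.approx(0.49, rel=0.6)
        assert r.var_cycle_within_patient == pytest.approx(0.09, rel=0.6)
        assert r.var_residual == pytest.approx(0.04, rel=0.5)

    def test_zero_cycle_variance_fits_at_boundary(self, rng):
        df = simulate_tn_long(30, 3, 0.1, rng, patient_sd=0.5, cycle_sd=0.0,
                              residual_sd=0.3)
        r = fit_two_level_lmm(df, log_scale=True)
        assert r.var_cycle_within_patient == pytest.approx(0.0, abs=0.02)

    def test_nonsignificant_when_no_effect(self, rng):
        df = simulate_tn_long(20, 4, 0.0, rng)
        r = fit_two_level_lmm(df, log_scale=True)
        assert r.p_value > 0.001  # sanity: not wildly anticonservative


class TestCovariate:
    def test_constant_covariate_rejected(self, rng):
        df = simulate_paired_tn(10, 1.2, 0.3, rng)
        df["site"] = "A"
        with pytest.raises(ValueError, match="constant"):
            covariate_test(df, "site")

    def test_null_covariate_p_roughly_uniform(self, rng):
        """A covariate unrelated to the effect yields p-values that are not
        concentrated below alpha (type-I control at the nominal level)."""
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            df = simulate_tn_long(16, 2, 0.15, rng)
            df = df.merge(
                pd.DataFrame({
                    "patient_id": df["patient_id"].unique(),
                    "group": rng.integers(0, 2, df["patient_id"].nunique()),
                }), on="patient_id")
            if covariate_test(df, "group") < 0.05:
                rejections += 1
        assert rejections <= 10  # binomial(60, 0.05) upper tail

    def test_effect_modifier_detected(self, rng):
        """A covariate that amplifies the arm effect is detected far above
        the nominal false-positive rate."""
        detected = 0
        n_rep = 25
        for _ in range(n_rep):
            halves = []
            for g, eff in ((0, 0.0), (1, 0.6)):
                df = simulate_tn_long(12, 2, eff, rng, residual_sd=0.15)
                df["patient_id"] = df["patient_id"] + f"g{g}"
                df["group"] = g
                halves.append(df)
            df = pd.concat(halves, ignore_index=True)
            if covariate_test(df, "group") < 0.05:
                detected += 1
        assert detected >= n_rep * 0.5


class TestFisherExact:
    def test_identical_columns_p_one(self):
        assert fisher_exact_rxc([[6, 6], [18, 18]]) == 1.0
        assert fisher_exact_rxc([[8, 8], [14, 14], [1, 1]]) == 1.0

    def test_diagonal_table(self):
        assert fisher_exact_rxc([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_against_scipy_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact_rxc(t) == pytest.approx(
                sps.fisher_exact(t)[1], rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 5), min_size=2, max_size=2),
                    min_size=2, max_size=3))
    def test_matches_enumeration_oracle(self, table):
        t = np.asarray(table)
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any() or t.sum() > 30:
            return
        assert fisher_exact_rxc(t) == pytest.approx(
            brute_fisher_2or3_rows(t), rel=1e-9)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -2], [1, 2]])


class TestProportionIncreased:
    def test_all_equal_gives_zero(self):
        frac, n_up, n = proportion_increased(pairs([3, 3], [3, 3]))
        assert (frac, n_up, n) == (0.0, 0, 2)

    def test_trial_scale_fraction(self, rng):
        ia = np.full(27, 10.0)
        ctrl = np.where(np.arange(27) < 18, 9.0, 11.0)
        frac, n_up, n = proportion_increased(pairs(ia, ctrl))
        assert n_up == 18 and n == 27
        assert frac == pytest.approx(18 / 27)

    def test_matches_brute_count(self, rng):
        a = rng.uniform(1, 10, 30)
        b = rng.uniform(1, 10, 30)
        frac, n_up, n = proportion_increased(pairs(a, b))
        assert n_up == sum(1 for x, y in zip(a, b) if x > y)
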