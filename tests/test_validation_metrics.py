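"""Discrimination, calibration, classification, and stratification statistics
against independent oracles (exhaustive pair counting, hand arithmetic,
parameter-recovery simulation)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from fragscore.risk_scores import load_model_config, score_patient
from fragscore.synthetic_cohort import generate_calibrated_outcomes
from fragscore.validation_metrics import (
    calibration_slope,
    confusion_metrics,
    delong_test,
    hanley_mcneil_n,
    hosmer_lemeshow,
    roc_auc,
    stratum_accuracy,
    stratum_table,
)
from fragscore.cohort_io import Sex
from tests.conftest import make_patient


def pair_count_auc(scores, outcomes):
    """Exhaustive concordant-pair oracle: concordant + half ties over all
    death x survivor pairs."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else 0.5 if x == y else 0.0
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, (lo, hi) = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert lo <= auc <= hi <= 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 51))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]  # both classes
        s = np.round(rng.normal(y, 1.5), 1)  # rounding creates ties
        auc, _ = roc_auc(s, y)
        assert auc == pytest.approx(pair_count_auc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(y, 1.0, 40)
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(np.exp(3 * s), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 500):
            y = np.repeat([0, 1], n // 2)
            s = rng.normal(y, 1.0, n)
            _, (lo, hi) = roc_auc(s, y)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestDelong:
    def test_model_against_itself(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(y, 1.0, 30)
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_orientation_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(y, 1.0, 40)
        auc_a, auc_b, z, p = delong_test(s, -s, y)
        assert auc_b == pytest.approx(1 - auc_a, abs=1e-12)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = rng.normal(y, 1.0, 40)
        b = rng.normal(y, 2.0, 40)
        _, _, z_ab, p_ab = delong_test(a, b, y)
        _, _, z_ba, p_ba = delong_test(b, a, y)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestHosmerLemeshow:
    def test_exact_fit_gives_zero_statistic(self):
        # two bins where observed deaths equal expected exactly
        p = np.array([0.2] * 10 + [0.8] * 10)
        y = np.array([1, 1] + [0] * 8 + [1] * 8 + [0, 0])
        stat, df, pval = hosmer_lemeshow(p, y, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == 1.0

    def test_hand_computed_two_bin_toy(self):
        # bin1: 10 patients at p=0.3 (E1=3), 5 observed deaths
        # bin2: 10 patients at p=0.5 (E1=5), 4 observed deaths
        p = np.array([0.3] * 10 + [0.5] * 10)
        y = np.array([1] * 5 + [0] * 5 + [1] * 4 + [0] * 6)
        stat, df, _ = hosmer_lemeshow(p, y, groups=2)
        expected = (5 - 3) ** 2 / 3 + (5 - 7) ** 2 / 7 + (4 - 5) ** 2 / 5 + (6 - 5) ** 2 / 5
        assert stat == pytest.approx(expected, abs=1e-12)
        assert df == 2

    def test_ties_consolidate_bins(self):
        # piecewise-constant predictions: only 3 distinct values -> 3 bins
        p = np.array([0.1] * 30 + [0.3] * 30 + [0.6] * 30)
        y = generate_calibrated_outcomes(p, seed=5)
        _, df, _ = hosmer_lemeshow(p, y, groups=10)
        assert df == 3

    def test_development_df_style(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.6, 200)
        y = generate_calibrated_outcomes(p, seed=1)
        _, df_v, _ = hosmer_lemeshow(p, y, groups=10, df_style="validation")
        _, df_d, _ = hosmer_lemeshow(p, y, groups=10, df_style="development")
        assert df_v == 10 and df_d == 8

    def test_rejects_probabilities_outside_unit_interval(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.2, 1.2] * 10, [0, 1] * 10)


class TestCalibrationSlope:
    def test_recovers_unit_slope_single_draw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.6, 5000)
        y = generate_calibrated_outcomes(p, seed=10000)
        res = calibration_slope(p, y)
        assert res.converged
        assert res.slope_ci[0] <= 1.0 <= res.slope_ci[1]

    def test_constant_predictions_flagged_degenerate(self):
        res = calibration_slope([0.3] * 50, [0] * 40 + [1] * 10)
        assert res.degenerate and res.slope is None

    def test_inverse_shrinkage_recovery(self):
        # evaluating logit-shrunk predictions against outcomes from the true
        # probabilities recovers the inverse shrinkage factor: slope ~ 2
        rng = np.random.default_rng(11)
        p_true = rng.uniform(0.05, 0.7, 20000)
        p_shrunk = expit(0.5 * logit(p_true))
        y = generate_calibrated_outcomes(p_true, seed=1111)
        res = calibration_slope(p_shrunk, y)
        assert res.converged
        assert res.slope == pytest.approx(2.0, abs=0.25)

    def test_separation_flagged_not_raised(self):
        p = np.concatenate([np.full(20, 0.01), np.full(20, 0.99)])
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        res = calibration_slope(p, y)
        assert not res.converged or res.slope_ci is None or res.slope is not None


class TestConfusionMetrics:
    def test_perfect_separator(self):
        m = confusion_metrics([1, 2, 8, 9], [0, 0, 1, 1], threshold="youden")
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_threshold_below_min(self):
        m = confusion_metrics([3, 4, 5, 6], [0, 1, 0, 1], threshold=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_published_operating_point_arithmetic(self):
        # 2x2 table TP=44 FN=16 TN=121 FP=26 at threshold 1
        scores = np.array([1] * 44 + [0] * 16 + [0] * 121 + [1] * 26)
        y = np.array([1] * 60 + [0] * 147)
        m = confusion_metrics(scores, y, threshold=1)
        assert m.sensitivity == pytest.approx(0.733, abs=5e-4)
        assert m.specificity == pytest.approx(0.823, abs=5e-4)

    def test_youden_tie_breaks_toward_specificity(self):
        # thresholds 2 and 3 give equal Youden J; 3 has higher specificity
        scores = [1, 2, 3, 4]
        y = [0, 0, 1, 1]
        m = confusion_metrics(scores, y, threshold="youden")
        assert m.threshold == 3.0


class TestStratumAccuracy:
    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, p, o):
        a = stratum_accuracy(p, o)
        assert a == stratum_accuracy(o, p)
        assert 0 < a <= 100

    @given(st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_equality_iff_equal(self, x):
        assert stratum_accuracy(x, x) == 100.0

    def test_zero_conventions(self):
        assert stratum_accuracy(0.0, 0.0) == 100.0
        assert stratum_accuracy(0.0, 5.0) == 0.0
        assert stratum_accuracy(5.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stratum_accuracy(-1.0, 5.0)


class TestStratumTable:
    def _outcomes(self, panels, dead_ids):
        return {p.patient_id: p.patient_id in dead_ids for p in panels}

    def test_observed_mortality_and_empty_strata(self, model_config):
        spec = model_config["nhfs"]
        high = [make_patient(patient_id=f"H{i}", age=90, sex=Sex.MALE, hemoglobin=9.0,
                             cognitive_impairment=True, n_comorbidities=4)
                for i in range(3)]
        panels = [score_patient(p, spec) for p in high]
        outcomes = {p.patient_id: True for p in panels}
        tab = stratum_table(panels, outcomes, spec)
        by_label = {s.label: s for s in tab}
        assert by_label["high"].observed_pct == 100.0
        assert by_label["low"].n == 0 and by_label["low"].observed_pct is None
        assert by_label["low"].accuracy_pct is None

    def test_observed_fraction_fixture(self, model_config):
        # 35 low-risk patients, 4 deaths -> observed 11.4%
        spec = model_config["jiang"]
        patients = [make_patient(patient_id=f"L{i}", age=65) for i in range(35)]
        panels = [score_patient(p, spec) for p in patients]
        outcomes = self._outcomes(panels, {"L0", "L1", "L2", "L3"})
        tab = {s.label: s for s in stratum_table(panels, outcomes, spec)}
        assert round(tab["low"].observed_pct, 1) == 11.4
        assert tab["low"].n == 35

    def test_interval_mode_switches_representative(self, model_config):
        spec = model_config["holt"]
        p = [make_patient(patient_id="A", age=95, asa_grade=4, sex=Sex.MALE)]
        panels = [score_patient(x, spec) for x in p]
        up = stratum_table(panels, {"A": True}, spec, interval_mode="upper")
        lo = stratum_table(panels, {"A": True}, spec, interval_mode="lower")
        high_up = next(s for s in up if s.label == "high")
        high_lo = next(s for s in lo if s.label == "high")
        assert high_up.predicted_pct == 53.2
        assert high_lo.predicted_pct == 5.8


class TestHanleyMcNeil:
    def test_published_scenario_vicinity(self):
        n = hanley_mcneil_n(auc=0.70, ci_halfwidth=0.05, prevalence=0.134)
        assert 1060 <= n <= 1090

    def test_halving_halfwidth_quadruples_n(self):
        n1 = hanley_mcneil_n(0.70, 0.05, 0.134)
        n2 = hanley_mcneil_n(0.70, 0.025, 0.134)
        assert n2 / n1 == pytest.approx(4.0, rel=0.02)

    def test_balanced_prevalence_minimizes_n(self):
        ns = {prev: hanley_mcneil_n(0.75, 0.05, prev)
              for prev in (0.1, 0.25, 0.5, 0.75, 0.9)}
        assert min(ns, key=ns.get) == 0.5

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_n(0.45, 0.05, 0.2)
        with pytest.raises(ValueError):
            hanley_mcneil_n(0.7, 0.05, 1.2)
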