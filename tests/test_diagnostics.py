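"""Diagnostic-accuracy statistics: confusion, exact CIs, single-point AUC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mddtool import (
    ConfusionTable,
    auc_binary,
    build_confusion,
    clopper_pearson,
    performance,
    stratified_performance,
)
from mddtool.diagnostics import EvaluationError, format_p, parse_strata, percent


def cp_bisection_oracle(x, n, level=0.95, tol=1e-10):
    """Invert the binomial tails by bisection — independent of the beta form."""
    a = (1 - level) / 2

    def solve(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else solve(lambda p: stats.binom.sf(x - 1, n, p) < a, 0.0, 1.0)
    upper = 1.0 if x == n else solve(lambda p: stats.binom.cdf(x, n, p) > a, 0.0, 1.0)
    return lower, upper


class TestBuildConfusion:
    def test_study_counts_reconstruct(self, study_cohort_df):
        ct = build_confusion(study_cohort_df)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (17, 18, 10, 134)
        assert ct.n == 179 and ct.reference_positives == 35

    def test_all_concordant_positive(self):
        df = pd.DataFrame(
            {"respondent_id": ["a", "b"], "index_test": ["positive"] * 2,
             "reference": ["positive"] * 2}
        )
        ct = build_confusion(df)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (2, 0, 0, 0)

    def test_single_missed_case(self):
        ct = build_confusion(
            [{"respondent_id": "a", "index_test": "negative", "reference": "positive"}]
        )
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (0, 1, 0, 0)

    def test_order_invariance(self, study_cohort_df):
        shuffled = study_cohort_df.sample(frac=1.0, random_state=0)
        assert build_confusion(shuffled) == build_confusion(study_cohort_df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {"respondent_id": ["a", "a"], "index_test": ["positive"] * 2,
             "reference": ["negative"] * 2}
        )
        with pytest.raises(EvaluationError, match="duplicate"):
            build_confusion(df)


class TestClopperPearson:
    @pytest.mark.parametrize("x,n", [(3, 14), (17, 35), (0, 7), (7, 7), (1, 144)])
    def test_matches_tail_inversion_oracle(self, x, n):
        got = clopper_pearson(x, n)
        expected = cp_bisection_oracle(x, n)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(17, 35), (134, 144), (17, 27), (134, 152)]:
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert clopper_pearson(x, n) == pytest.approx((lo, hi), abs=1e-10)

    def test_boundaries(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(EvaluationError):
            clopper_pearson(5, 4)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true proportion in >= 95% of draws."""
        rng = np.random.default_rng(12345)
        for p in (0.1, 0.5, 0.9):
            for n in (20, 144):
                draws = rng.binomial(n, p, size=2000)
                bounds = {x: clopper_pearson(int(x), n) for x in np.unique(draws)}
                covered = sum(
                    bounds[x][0] <= p <= bounds[x][1] for x in draws
                )
                assert covered / 2000 >= 0.95


class TestPerformance:
    def test_study_table_metrics(self, study_table):
        perf = performance(study_table)
        assert perf.sensitivity.as_percent == 49
        assert perf.specificity.as_percent == 93
        assert perf.ppv.as_percent == 63
        assert perf.npv.as_percent == 88

    def test_study_table_ci_brackets(self, study_table):
        perf = performance(study_table)
        assert perf.sensitivity.ci_percent == (31, 66)
        assert perf.specificity.ci_percent == (88, 97)
        assert perf.ppv.ci_percent == (42, 81)
        assert perf.npv.ci_percent == (82, 93)

    def test_perfect_table(self):
        perf = performance(ConfusionTable(10, 0, 0, 20))
        for metric in (perf.sensitivity, perf.specificity, perf.ppv, perf.npv):
            assert metric.as_percent == 100
            assert metric.ci_percent[1] == 100

    def test_undefined_metrics_flagged_not_zeroed(self):
        perf = performance(ConfusionTable(0, 0, 0, 7))  # no positives at all
        assert not perf.sensitivity.defined
        assert not perf.ppv.defined
        assert perf.specificity.defined
        with pytest.raises(EvaluationError, match="undefined"):
            _ = perf.sensitivity.as_percent


class TestAuc:
    def test_study_table_auc(self, study_table):
        auc = auc_binary(study_table)
        assert round(auc.value, 2) == 0.71
        assert auc.p_value < 0.001

    def test_chance_line(self):
        # sens = 1 - spec = 0.5 -> AUC exactly 0.5
        auc = auc_binary(ConfusionTable(5, 5, 10, 10))
        assert auc.value == pytest.approx(0.5)
        assert auc.p_value == pytest.approx(1.0)

    def test_perfect_classifier(self):
        auc = auc_binary(ConfusionTable(10, 0, 0, 10))
        assert auc.value == 1.0
        assert auc.ci_high == 1.0

    @pytest.mark.parametrize("tp,fn,fp,tn", [(3, 9, 4, 11), (1, 1, 1, 1), (20, 3, 2, 40)])
    def test_bounded_and_equals_mean_of_rates(self, tp, fn, fp, tn):
        ct = ConfusionTable(tp, fn, fp, tn)
        auc = auc_binary(ct)
        sens, spec = tp / (tp + fn), tn / (fp + tn)
        assert 0.0 <= auc.value <= 1.0
        assert auc.value == pytest.approx((sens + spec) / 2)

    def test_undefined_without_both_classes(self):
        assert not auc_binary(ConfusionTable(3, 2, 0, 0)).defined


class TestStratified:
    def test_sensitivity_uses_stratum_positives_only(self, study_cohort_df):
        out = stratified_performance(study_cohort_df)
        sens = {k: v.sensitivity for k, v in out.items()}
        assert (sens["mild"].numerator, sens["mild"].denominator) == (3, 14)
        assert (sens["moderate"].numerator, sens["moderate"].denominator) == (7, 12)
        assert (sens["severe"].numerator, sens["severe"].denominator) == (7, 9)

    def test_specificity_shares_full_negative_pool(self, study_cohort_df):
        out = stratified_performance(study_cohort_df)
        for block in out.values():
            assert block.specificity.denominator == 144
            assert block.specificity.as_percent == 93

    def test_restricted_negative_denominator_option(self, study_cohort_df):
        out = stratified_performance(study_cohort_df, restrict_negatives=True)
        # all synthetic negatives carry BDI 5, outside every stratum
        assert all(not b.specificity.defined for b in out.values())

    def test_full_range_stratum_reproduces_unstratified(self, study_cohort_df):
        out = stratified_performance(study_cohort_df, strata=(("all", 0, 63),))
        whole = performance(build_confusion(study_cohort_df))
        assert out["all"].sensitivity == whole.sensitivity
        assert out["all"].specificity == whole.specificity

    def test_empty_stratum_sensitivity_undefined(self, study_cohort_df):
        out = stratified_performance(study_cohort_df, strata=(("none", 60, 63),))
        assert not out["none"].sensitivity.defined

    def test_overlapping_strata_rejected(self, study_cohort_df):
        with pytest.raises(EvaluationError, match="overlap"):
            stratified_performance(
                study_cohort_df, strata=(("a", 0, 20), ("b", 20, 63))
            )

    def test_missing_bdi_rejected(self, study_cohort_df):
        df = study_cohort_df.drop(columns=["bdi_total"])
        with pytest.raises(EvaluationError, match="bdi_total"):
            stratified_performance(df)


class TestFormatting:
    @pytest.mark.parametrize(
        "p,text", [(0.0005, "<0.001"), (0.0014, "0.001"), (0.28, "0.280"), (math.nan, "n/a")]
    )
    def test_p_value_floor(self, p, text):
        assert format_p(p) == text

    def test_half_up_percent_rounding(self):
        assert percent(0.125) == 13  # banker's rounding would give 12
        assert percent(0.875) == 88

    def test_parse_strata(self):
        strata = parse_strata("14:19,20:28")
        assert [(lo, hi) for _, lo, hi in strata] == [(14, 19), (20, 28)]
        with pytest.raises(EvaluationError):
            parse_strata("abc")
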