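"""Synthetic-cohort generator: determinism, calibration recovery, round trips."""

import numpy as np
import pytest

from mddtool import (
    GeneratorConfig,
    build_confusion,
    cronbach_alpha,
    generate_aes_items,
    generate_bdi_items,
    generate_cohort,
    respond_to_interview,
    run_interview,
)
from mddtool.simulate import ConfigError, _apportion


class TestConfig:
    def test_defaults_validate(self, default_cfg):
        default_cfg.validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"prevalence": 1.5},
            {"severity_mix": (0.5, 0.5, 0.5)},
            {"false_alarm": -0.1},
            {"composition": "other"},
            {"detect_prob": {"mild": 0.2}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kwargs).validate()

    def test_round_trip_through_yaml(self, tmp_path):
        import yaml

        cfg = GeneratorConfig(n=50, prevalence=0.3, seed=9)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert GeneratorConfig.from_file(path) == cfg


class TestCohortStructure:
    def test_fixed_composition_realises_study_counts(self, default_cfg):
        cohort = generate_cohort(default_cfg, seed=0)
        tab = cohort.table
        pos = tab[tab.reference == "positive"]
        assert len(tab) == 179 and len(pos) == 35
        assert pos.severity.value_counts().to_dict() == {
            "mild": 14, "moderate": 12, "severe": 9,
        }

    def test_same_seed_is_bitwise_identical(self, default_cfg):
        a = generate_cohort(default_cfg, seed=11)
        b = generate_cohort(default_cfg, seed=11)
        assert a.patients == b.patients
        assert a.table.equals(b.table)

    def test_different_seeds_differ(self, default_cfg):
        a = generate_cohort(default_cfg, seed=1)
        b = generate_cohort(default_cfg, seed=2)
        assert not a.table.equals(b.table)

    def test_zero_prevalence(self):
        cohort = generate_cohort(GeneratorConfig(n=500, prevalence=0.0), seed=3)
        ct = build_confusion(cohort.table)
        assert ct.reference_positives == 0
        # specificity ~ 1 - false_alarm
        assert ct.tn / ct.reference_negatives == pytest.approx(1 - 10 / 144, abs=0.05)

    def test_bernoulli_composition_converges(self):
        cfg = GeneratorConfig(n=20_000, composition="bernoulli")
        cohort = generate_cohort(cfg, seed=4)
        frac = (cohort.table.reference == "positive").mean()
        assert frac == pytest.approx(0.196, abs=0.01)

    def test_detected_patients_carry_qualifying_patterns(self, default_cfg):
        from mddtool import classify_mdd

        cohort = generate_cohort(default_cfg, seed=5)
        for p in cohort.patients:
            assert classify_mdd(p.profile).mdd_positive == p.detected


class TestBdiCalibration:
    def test_group_means_recover_printed_moments(self):
        """Across seeds the generated BDI totals centre on the calibration
        targets: ~22.3 for cases (severity mixture) and ~7.8 for controls."""
        pos_means, neg_means = [], []
        for seed in range(10):
            cohort = generate_cohort(GeneratorConfig(), seed=seed)
            tab = cohort.table
            pos = tab.reference == "positive"
            pos_means.append(tab.bdi_total[pos].mean())
            neg_means.append(tab.bdi_total[~pos].mean())
        assert np.mean(pos_means) == pytest.approx(22.3, abs=1.5)
        assert np.mean(neg_means) == pytest.approx(7.8, abs=1.5)

    def test_items_within_instrument_range(self, default_cfg, rng):
        items = generate_bdi_items("severe", default_cfg, n=200, rng=rng)
        assert items.shape == (200, 21)
        assert items.min() >= 0 and items.max() <= 3

    def test_zero_variance_latent_gives_identical_sums(self):
        cfg = GeneratorConfig(bdi_item_sd=0.0)
        items = generate_bdi_items("negative", cfg, n=25)
        assert len(set(items.sum(axis=1))) == 1

    def test_unknown_group_rejected(self, default_cfg):
        with pytest.raises(ConfigError, match="group"):
            generate_bdi_items("extreme", default_cfg)

    def test_aes_mean_calibration(self, rng):
        items = generate_aes_items(GeneratorConfig(), n=2000, rng=rng)
        assert items.min() >= 1 and items.max() <= 5
        assert items.sum(axis=1).mean() == pytest.approx(25.4, abs=0.5)


class TestReliabilityCalibration:
    def test_alpha_matches_emulated_cohort(self):
        """Whole-cohort BDI alpha at n=179 stays in the calibrated band."""
        alphas = []
        for seed in range(5):
            cohort = generate_cohort(GeneratorConfig(), seed=seed)
            X = np.array([p.bdi_items for p in cohort.patients], float)
            alphas.append(cronbach_alpha(X))
        assert all(0.85 <= a <= 0.93 for a in alphas)


class TestInterviewBridge:
    def test_detected_severe_positive_interviews_positive(self, bank, default_cfg):
        cohort = generate_cohort(default_cfg, seed=6)
        severe_hit = next(
            p for p in cohort.patients if p.severity == "severe" and p.detected
        )
        _, diag = run_interview(bank, respond_to_interview(severe_hit, bank))
        assert diag.mdd_positive

    def test_missed_mild_positive_interviews_negative(self, bank, default_cfg):
        cohort = generate_cohort(default_cfg, seed=6)
        mild_miss = next(
            p for p in cohort.patients if p.severity == "mild" and not p.detected
        )
        _, diag = run_interview(bank, respond_to_interview(mild_miss, bank))
        assert not diag.mdd_positive

    def test_pipeline_confusion_equals_bookkeeping(self, bank):
        """Interviewing every synthetic patient reproduces the generator's
        internal detection bookkeeping exactly (cross-module identity)."""
        cohort = generate_cohort(GeneratorConfig(n=300), seed=7)
        fixed = lambda: ""
        outcomes = []
        for p in cohort.patients:
            _, diag = run_interview(
                bank, respond_to_interview(p, bank), now=fixed
            )
            outcomes.append(
                {
                    "respondent_id": p.respondent_id,
                    "index_test": "positive" if diag.mdd_positive else "negative",
                    "reference": "positive" if p.reference_positive else "negative",
                }
            )
        assert build_confusion(outcomes) == build_confusion(cohort.table)


class TestApportion:
    @pytest.mark.parametrize(
        "total,props,expected",
        [(35, (0.40, 0.343, 0.257), [14, 12, 9]), (10, (1 / 3, 1 / 3, 1 / 3), [4, 3, 3]),
         (0, (0.5, 0.3, 0.2), [0, 0, 0])],
    )
    def test_largest_remainder(self, total, props, expected):
        assert _apportion(total, np.asarray(props)).tolist() == expected
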