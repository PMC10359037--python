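import numpy as np
import pandas as pd
import pytest

from sleeptap import GeneratorConfig, bin_events, measures_from_events
from sleeptap.binning import BIN_COLUMNS
from sleeptap.config import ConfigurationError
from sleeptap.simulate import (
    generate_demographics,
    generate_domain_scores,
    generate_events,
    generate_surveys,
    simulate_cohort,
)
from sleeptap.sleep import longest_zero_runs


def noise_free_config(**kw):
    base = dict(
        n_patients=3,
        days_per_patient=40,
        sleep_onset_mean_h=23.0,
        sleep_onset_sd_h=0.0,
        sleep_duration_mean_h=8.0,
        sleep_duration_sd_h=0.0,
        onset_jitter_sd_h=0.0,
        disruption_rate=0.0,
        missing_day_prob=0.0,
        seed=1,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestEventGeneration:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(daytime_activity_prob=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(missing_day_prob=-0.1)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(re_variances={"var_intercept": -1.0})

    def test_noise_free_days_have_sleep_duration_as_longest_inactive_run(self):
        # onset 01:00 keeps the sleep interval inside one calendar day, so
        # the daily longest inactive run is the full configured duration
        # (an interval crossing midnight would be truncated by the
        # day-boundary scan — the documented daily-measure bias)
        events, _ = generate_events(
            noise_free_config(sleep_onset_mean_h=1.0, daytime_activity_prob=1.0)
        )
        days = bin_events(events)
        mat = days[BIN_COLUMNS].to_numpy()
        _, lengths = longest_zero_runs(mat)
        assert (lengths == 32).all()

    def test_saturated_daytime_gives_exactly_64_active_bins(self):
        events, _ = generate_events(noise_free_config(daytime_activity_prob=1.0))
        days = bin_events(events)
        active = days[BIN_COLUMNS].to_numpy().sum(axis=1)
        assert (active[1:-1] == 64).all()

    def test_same_seed_reproduces_streams_exactly(self):
        cfg = GeneratorConfig(n_patients=5, days_per_patient=50, seed=77)
        e1, t1 = generate_events(cfg)
        e2, t2 = generate_events(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_timestamps_stay_inside_observation_window(self):
        cfg = GeneratorConfig(n_patients=5, days_per_patient=30, seed=8)
        events, _ = generate_events(cfg)
        ts = pd.to_datetime(events["timestamp"])
        assert ts.min() >= pd.Timestamp("2022-01-03")
        assert ts.max() < pd.Timestamp("2022-01-03") + pd.Timedelta(days=30)

    def test_random_intercept_variance_matches_configuration(self):
        cfg = GeneratorConfig(n_patients=1500, days_per_patient=1, seed=21)
        _, truth = generate_events(cfg)
        var = truth["u0_sleep"].var(ddof=1)
        assert var == pytest.approx(cfg.variance("var_intercept"), rel=0.10)

    def test_weekend_onset_shift_lowers_weekend_overlap(self):
        cfg = GeneratorConfig(
            n_patients=12,
            days_per_patient=90,
            weekend_onset_shift_h=2.0,
            onset_jitter_sd_h=0.2,
            seed=5,
        )
        events, _ = generate_events(cfg)
        _, _, measures = measures_from_events(events)
        from sleeptap.surveys import weekday_weekend_summary

        demo = generate_demographics(cfg)
        tab = weekday_weekend_summary(measures, demo)
        # nights shifted into Saturday/Sunday mornings lower weekend overlap
        assert (tab["overlap_diff"] < 0).mean() > 0.5


class TestSurveyGeneration:
    def _cohort_measures(self, cfg):
        events, truth = generate_events(cfg)
        _, _, measures = measures_from_events(events)
        demo = generate_demographics(cfg)
        return measures, truth, demo

    def test_degenerate_model_yields_constant_scores(self):
        cfg = noise_free_config(
            n_patients=2,
            days_per_patient=70,
            fixed_effects={"intercept": 2.0},
            re_variances={},
            resid_variance=0.0,
        )
        measures, truth, demo = self._cohort_measures(cfg)
        scores = generate_domain_scores(measures, truth, cfg, demo)
        assert (scores["score"] == 2.0).all()

    def test_linear_predictor_is_clamped_to_scale(self):
        cfg = noise_free_config(
            n_patients=1,
            days_per_patient=70,
            fixed_effects={"intercept": 5.3},
            re_variances={},
            resid_variance=0.0,
        )
        measures, truth, demo = self._cohort_measures(cfg)
        scores = generate_domain_scores(measures, truth, cfg, demo)
        assert (scores["score"] == 4.0).all()

    def test_between_person_overlap_effect_propagates_exactly(self):
        # two patients differing only in jitter -> different bp overlap;
        # with only the bp-overlap coefficient active, the score difference
        # must equal the coefficient times the bp-overlap difference
        cfg = noise_free_config(
            n_patients=6,
            days_per_patient=70,
            onset_jitter_sd_h=1.0,
            disruption_rate=3.0,
            fixed_effects={"intercept": 2.49, "bp_overlap": -0.90},
            re_variances={},
            resid_variance=0.0,
            seed=13,
        )
        measures, truth, demo = self._cohort_measures(cfg)
        scores = generate_domain_scores(measures, truth, cfg, demo)
        scores = scores[~scores["insufficient_history"]]
        from sleeptap.surveys import aggregate_presurvey, decompose_within_between

        sched = scores[["patient_id", "date"]].drop_duplicates()
        rows = decompose_within_between(aggregate_presurvey(measures, sched))
        merged = scores.merge(rows[["patient_id", "date", "bp_overlap"]], on=["patient_id", "date"])
        merged = merged[merged["domain"] == "sleep"]
        pred = 2.49 - 0.90 * merged["bp_overlap"]
        assert np.allclose(merged["score"], np.clip(pred, 0, 4), atol=1e-9)

    def test_item_means_round_trip_to_domain_scores(self):
        cfg = GeneratorConfig(n_patients=4, days_per_patient=70, seed=3)
        measures, truth, demo = self._cohort_measures(cfg)
        scores = generate_domain_scores(measures, truth, cfg, demo)
        items = generate_surveys(measures, truth, cfg, demo)
        from sleeptap.surveys import DOMAIN_ITEMS, score_surveys

        scored = score_surveys(items[["patient_id", "date", "item_id", "response"]])
        wide = scores.pivot_table(
            index=["patient_id", "date"], columns="domain", values="score"
        ).reset_index()
        merged = wide.merge(scored, on=["patient_id", "date"], suffixes=("_gen", ""))
        for domain, names in DOMAIN_ITEMS.items():
            n = len(names)
            expected = np.floor(merged[f"{domain}_gen"] * n + 0.5) / n
            assert np.allclose(merged[domain], expected)

    def test_insufficient_history_surveys_are_flagged_not_dropped(self):
        cfg = noise_free_config(n_patients=1, days_per_patient=50)  # one survey at day 44
        measures, truth, demo = self._cohort_measures(cfg)
        # erase all viable days so the survey has no usable history
        measures = measures.assign(viable=False)
        items = generate_surveys(measures, truth, cfg, demo)
        assert len(items) > 0
        assert items["insufficient_history"].all()


class TestCohortDeterminism:
    def test_full_cohort_regenerates_byte_identically(self):
        cfg = GeneratorConfig(n_patients=6, days_per_patient=80, seed=55)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.survey_items, b.survey_items)
        pd.testing.assert_frame_equal(a.demographics, b.demographics)
        pd.testing.assert_frame_equal(a.measures, b.measures)

    def test_demographic_marginals_are_plausible(self):
        cfg = GeneratorConfig(n_patients=4000, days_per_patient=1, seed=2)
        demo = generate_demographics(cfg)
        assert demo["gender_male"].mean() == pytest.approx(0.251, abs=0.03)
        assert demo["location_rural"].mean() == pytest.approx(0.553, abs=0.03)
        assert demo["ethnicity"].isna().mean() == pytest.approx(0.343, abs=0.03)
        assert demo["age"].between(18, 79).all()
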