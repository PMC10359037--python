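import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleeptap import GeneratorConfig, measures_from_events
from sleeptap.simulate import generate_events
from sleeptap.sleep import (
    RunSpan,
    binarize_window,
    compute_esp,
    compute_isp,
    count_disruptions,
    longest_zero_runs,
    overlap_percentage,
)

from conftest import (
    brute_circular_longest_zero_len,
    brute_longest_zero_run,
    brute_two_means_partition,
)


def seq(active_bins):
    s = np.zeros(96, dtype=int)
    s[list(active_bins)] = 1
    return s


class TestInferredSleepPeriod:
    def test_fully_inactive_day_is_one_whole_day_run(self):
        isp = compute_isp(np.zeros(96, dtype=int))
        assert (isp.start_bin, isp.length) == (0, 96)

    def test_fully_active_day_has_no_isp(self):
        assert compute_isp(np.ones(96, dtype=int)) is None

    def test_longest_of_two_runs_wins(self):
        # inactive runs of length 13 (bins 10-22) and 7 (bins 40-46)
        s = np.ones(96, dtype=int)
        s[10:23] = 0
        s[40:47] = 0
        isp = compute_isp(s)
        assert (isp.start_bin, isp.length) == (10, 13)

    def test_tie_broken_by_earliest_start(self):
        s = np.ones(96, dtype=int)
        s[5:10] = 0
        s[50:55] = 0
        assert compute_isp(s).start_bin == 5

    def test_midnight_is_not_crossed(self):
        # inactivity at both edges stays two separate runs (non-circular)
        s = np.ones(96, dtype=int)
        s[:10] = 0
        s[-20:] = 0
        isp = compute_isp(s)
        assert (isp.start_bin, isp.length) == (76, 20)

    def test_agrees_with_exhaustive_run_scan(self):
        rng = np.random.default_rng(123)
        mat = (rng.random((2000, 96)) < rng.uniform(0.1, 0.9, (2000, 1))).astype(int)
        starts, lengths = longest_zero_runs(mat)
        for row, s, ln in zip(mat, starts, lengths):
            expected = brute_longest_zero_run(row)
            if expected is None:
                assert (s, ln) == (-1, 0)
            else:
                assert (s, ln) == expected


class TestBinarization:
    def test_two_separated_clusters(self):
        x = np.r_[np.full(64, 0.9), np.full(32, 0.05)]
        z = binarize_window(x)
        assert (z[:64] == 1).all() and (z[64:] == 0).all()

    def test_constant_profile_is_degenerate(self):
        assert binarize_window(np.full(96, 0.5)) is None

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            x = rng.random(96)
            z = binarize_window(x)
            expected = brute_two_means_partition(x)
            assert np.array_equal(z, expected)

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            binarize_window(np.r_[np.full(95, 0.5), 1.5])


class TestExpectedSleepPeriod:
    def test_nocturnal_block_from_midnight(self):
        z = np.where(np.arange(96) < 32, 0, 1)  # 0s at bins 0-31
        esp = compute_esp(z)
        assert (esp.start_bin, esp.length) == (0, 32)
        assert esp.duration_h == 8.0

    def test_run_crossing_midnight_is_single_circular_run(self):
        z = np.ones(96, dtype=int)
        z[92:] = 0
        z[:28] = 0
        esp = compute_esp(z)
        assert (esp.start_bin, esp.length, esp.circular) == (92, 32, True)

    def test_all_inactive_profile_degenerates_to_full_day(self):
        esp = compute_esp(np.zeros(96, dtype=int))
        assert esp.length == 96

    def test_all_active_profile_has_no_esp(self):
        assert compute_esp(np.ones(96, dtype=int)) is None

    def test_length_agrees_with_circular_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            z = (rng.random(96) < rng.uniform(0.2, 0.8)).astype(int)
            esp = compute_esp(z)
            expected = brute_circular_longest_zero_len(z)
            if expected is None:
                assert esp is None
            else:
                assert esp.length == expected
                # returned span is genuinely a maximal zero run
                assert (z[esp.bins()] == 0).all()
                if esp.length < 96:
                    assert z[(esp.start_bin - 1) % 96] == 1
                    assert z[(esp.start_bin + esp.length) % 96] == 1


class TestOverlapAndDisruption:
    def test_isp_inside_esp_scores_full_overlap(self):
        esp = RunSpan(0, 32, circular=False)  # 00:00-08:00
        isp = RunSpan(3, 25)
        assert overlap_percentage(isp, esp) == 1.0

    def test_twelve_of_thirteen_bins_rounds_to_92_percent(self):
        esp = RunSpan(0, 32)
        isp = RunSpan(20, 13)  # bins 20..32: twelve inside [0, 32)
        frac = overlap_percentage(isp, esp)
        assert frac == pytest.approx(12 / 13)
        assert round(frac * 100) == 92

    def test_disjoint_spans_have_zero_overlap(self):
        assert overlap_percentage(RunSpan(40, 10), RunSpan(0, 32)) == 0.0

    def test_overlap_non_increasing_as_esp_shrinks(self):
        isp = RunSpan(10, 20)
        prev = 1.1
        for ln in range(40, 4, -5):
            frac = overlap_percentage(isp, RunSpan(5, ln))
            assert frac <= prev + 1e-12
            prev = frac

    def test_wrapping_esp_membership(self):
        esp = RunSpan(92, 32, circular=True)  # 23:00-07:00
        isp = RunSpan(0, 16)
        assert overlap_percentage(isp, esp) == 1.0

    def test_five_active_bins_inside_esp_count_as_five_disruptions(self):
        esp = RunSpan(0, 31)  # 00:00-07:45
        day = seq([2, 7, 12, 20, 28, 50, 60])  # five inside, two outside
        assert count_disruptions(day, esp) == 5

    def test_disruption_bounds(self):
        esp = RunSpan(0, 31)
        assert count_disruptions(seq([]), esp) == 0
        assert count_disruptions(np.ones(96, dtype=int), esp) == esp.length


class TestPipelineRecovery:
    def test_noise_free_esp_recovers_configured_duration(self):
        cfg = GeneratorConfig(
            n_patients=4,
            days_per_patient=62,
            onset_jitter_sd_h=0.0,
            disruption_rate=0.0,
            missing_day_prob=0.0,
            sleep_duration_sd_h=0.0,
            seed=9,
        )
        events, truth = generate_events(cfg)
        _, esp_windows, measures = measures_from_events(events)
        valid = esp_windows[esp_windows["valid"]]
        assert len(valid) > 0
        assert np.allclose(valid["esp_duration_h"], cfg.sleep_duration_mean_h, atol=0.25)
        # and noise-free nights have no disruptions
        viable = measures[measures["viable"]]
        assert (viable["disruptions"] == 0).all()


day_strategy = st.lists(st.integers(0, 1), min_size=96, max_size=96)


class TestPropertyBased:
    """Derandomized property tests of the run-length and overlap primitives."""

    @given(day_strategy)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_isp_matches_brute_force_on_arbitrary_days(self, bins):
        bins = np.array(bins, dtype=np.int8)
        isp = compute_isp(bins)
        expected = brute_longest_zero_run(bins)
        if expected is None:
            assert isp is None
        else:
            assert (isp.start_bin, isp.length) == expected
            assert (bins[isp.bins()] == 0).all()

    @given(day_strategy, st.integers(0, 95), st.integers(1, 96))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_disruptions_bounded_by_esp_length_and_active_count(self, bins, start, length):
        bins = np.array(bins, dtype=np.int8)
        esp = RunSpan(start, length, circular=start + length > 96)
        d = count_disruptions(bins, esp)
        assert 0 <= d <= min(esp.length, int(bins.sum()))

    @given(st.integers(0, 95), st.integers(1, 96), st.integers(0, 95), st.integers(1, 96))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_overlap_is_a_fraction_and_full_iff_contained(self, s1, l1, s2, l2):
        isp = RunSpan(s1, l1, circular=s1 + l1 > 96)
        esp = RunSpan(s2, l2, circular=s2 + l2 > 96)
        frac = overlap_percentage(isp, esp)
        assert 0.0 <= frac <= 1.0
        contained = set(isp.bins().tolist()) <= set(esp.bins().tolist())
        assert (frac == 1.0) == contained
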