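"""Artifact-rejection stages: speed, range, gap-edge, deviation, sparsity."""
import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from pupilprep import (
    FilterSettings,
    build_trendline,
    compute_dilation_speed,
    filter_range,
    filter_sparsity,
    filter_speed_outliers,
    filter_trendline_deviation,
    mad_threshold,
    reject_gap_edges,
    run_filter_pipeline,
)
from pupilprep.filtering import evaluate_trendline
from pupilprep.io_model import InsufficientDataError, RawRecording


def oracle_median(values):
    """Sort-based median, independent of numpy."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def oracle_mad_threshold(values, multiplier):
    med = oracle_median(values)
    mad = oracle_median([abs(v - med) for v in values])
    return med + multiplier * mad


def oracle_dilation_speed(t, d):
    out = []
    for i in range(len(t)):
        speeds = []
        if i > 0:
            speeds.append(abs((d[i] - d[i - 1]) / (t[i] - t[i - 1])))
        if i < len(t) - 1:
            speeds.append(abs((d[i + 1] - d[i]) / (t[i + 1] - t[i])))
        out.append(max(speeds))
    return out


class TestDilationSpeed:
    @pytest.mark.parametrize(
        "t, d, expected",
        [
            ([0.0, 0.1, 0.2], [4.0, 4.1, 3.0], [1.0, 11.0, 11.0]),
            ([0.0, 0.1, 0.2, 0.3], [4.0, 4.0, 4.0, 4.0], [0.0, 0.0, 0.0, 0.0]),
            ([0.0, 1.0, 3.0], [0.0, 2.0, 2.0], [2.0, 2.0, 0.0]),
        ],
    )
    def test_hand_computed_values(self, t, d, expected):
        np.testing.assert_allclose(compute_dilation_speed(t, d), expected)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_dilation_speed([0.0], [4.0])

    @given(
        d=st.lists(st.floats(1.5, 9.0), min_size=2, max_size=40),
        shift=st.floats(-2, 2),
        scale=st.floats(0.1, 10),
    )
    @hyp_settings(max_examples=200, derandomize=True)
    def test_invariances(self, d, shift, scale):
        """Constant shifts leave speeds alone; value/time scalings act linearly."""
        t = np.arange(len(d), dtype=float) * 0.004
        d = np.asarray(d)
        base = compute_dilation_speed(t, d)
        np.testing.assert_allclose(compute_dilation_speed(t, d + shift), base, atol=1e-9)
        np.testing.assert_allclose(
            compute_dilation_speed(t, d * scale), base * scale, rtol=1e-9, atol=1e-12
        )
        np.testing.assert_allclose(
            compute_dilation_speed(t * scale, d), base / scale, rtol=1e-9, atol=1e-12
        )


class TestMadThreshold:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            ([1, 1, 1, 10], 5, 1.0),  # degenerate MAD = 0
            ([1, 2, 3, 4, 100], 2, 5.0),
            ([3.3] * 7, 12, 3.3),  # constant series
        ],
    )
    def test_hand_computed_values(self, x, n, expected):
        assert mad_threshold(np.array(x, dtype=float), n) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mad_threshold(np.array([]), 2.0)

    @given(
        x=st.lists(st.floats(0, 100), min_size=1, max_size=50),
        n=st.floats(0.5, 20),
    )
    @hyp_settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_oracle_exactly(self, x, n):
        assert mad_threshold(np.array(x), n) == oracle_mad_threshold(x, n)


class TestRangeGate:
    def test_default_bounds(self, fsettings):
        mask = filter_range(np.array([1.0, 2.0, 9.5]), fsettings)
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_bounds_inclusive(self, fsettings):
        np.testing.assert_array_equal(
            filter_range(np.array([1.5, 9.0]), fsettings), [True, True]
        )

    def test_idempotent(self, fsettings):
        d = np.array([1.0, 4.0, np.nan, 9.5, 2.0])
        m1 = filter_range(d, fsettings)
        d2 = d.copy()
        d2[~m1] = np.nan  # rerun on survivors
        m2 = filter_range(d2, fsettings)
        survivors = m1 & ~np.isnan(d)
        assert m2[survivors].all()


class TestSpeedFilter:
    def test_single_spike_rejected_with_only_adjacent_casualties(self, fsettings):
        rng = np.random.default_rng(1)
        t = np.arange(100) * 0.01
        d = 4.0 + 0.3 * np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.01, 100)
        d[50] += 3.0
        mask, thr = filter_speed_outliers(t, d, fsettings)
        assert not mask[50]
        assert set(np.flatnonzero(~mask)) <= {49, 50, 51}
        speeds = oracle_dilation_speed(t, d)
        assert thr == oracle_mad_threshold(speeds, fsettings.speed_mad_multiplier)

    def test_constant_series_rejects_nothing(self, fsettings):
        t = np.arange(10) * 0.01
        mask, _ = filter_speed_outliers(t, np.full(10, 4.0), fsettings)
        assert mask.all()

    def test_two_consecutive_spikes_both_rejected(self, fsettings):
        t = np.arange(10) * 0.1
        d = np.full(10, 4.0)
        d[4] += 3.0
        d[5] += 2.0
        mask, _ = filter_speed_outliers(t, d, fsettings)
        assert not mask[4] and not mask[5]


class TestGapEdges:
    def test_margin_around_long_gap(self, fsettings):
        t = np.arange(0, 1.0, 0.001)
        present = ~((t >= 0.4) & (t < 0.5))  # ~101 ms gap between present samples
        mask = reject_gap_edges(t, present, fsettings)
        assert not mask[349] and not mask[550]  # within 50 ms of a boundary
        assert mask[348] and mask[551]  # 51 ms away: retained

    def test_short_gap_ignored(self, fsettings):
        t = np.arange(0, 1.0, 0.001)
        present = ~((t >= 0.4) & (t < 0.46))  # ~61 ms, not > 75 ms
        mask = reject_gap_edges(t, present, fsettings)
        assert mask[present].all()

    def test_gap_at_recording_start_has_only_trailing_edge(self, fsettings):
        t = np.arange(0, 1.0, 0.001)
        present = t >= 0.2
        mask = reject_gap_edges(t, present, fsettings)
        rejected = present & ~mask
        assert t[rejected].min() == pytest.approx(0.2)
        assert t[rejected].max() == pytest.approx(0.25)

    def test_applying_twice_equals_once(self, fsettings):
        rng = np.random.default_rng(5)
        t = np.arange(0, 2.0, 0.004)
        present = rng.random(t.size) > 0.2
        m1 = reject_gap_edges(t, present, fsettings)
        m2 = reject_gap_edges(t, present, fsettings)
        np.testing.assert_array_equal(m1, m2)


class TestTrendline:
    def test_straight_line_reproduced(self, fsettings):
        t = np.arange(0, 5, 0.01)
        d = 3.0 + 0.2 * t
        grid, trend = build_trendline(t, d, fsettings)
        central = (grid > 0.5) & (grid < 4.5)
        np.testing.assert_allclose(
            trend[central], 3.0 + 0.2 * grid[central], atol=5e-3
        )

    def test_constant_series_constant_trend(self, fsettings):
        t = np.arange(0, 2, 0.01)
        grid, trend = build_trendline(t, np.full(t.size, 4.0), fsettings)
        np.testing.assert_allclose(trend, 4.0, atol=1e-9)

    def test_trend_resists_far_off_cluster(self, fsettings):
        t = np.arange(0, 2, 0.01)
        d = np.full(t.size, 4.0)
        d[100:105] += 2.0
        grid, trend = build_trendline(t, d, fsettings)
        rmse = np.sqrt(np.mean((evaluate_trendline(grid, trend, t) - 4.0) ** 2))
        assert rmse < 2.0 / 10

    def test_too_few_samples_raises(self, fsettings):
        with pytest.raises(InsufficientDataError):
            build_trendline(np.array([0.0]), np.array([4.0]), fsettings)


class TestDeviationFilter:
    def test_cluster_fully_rejected(self, fsettings):
        rng = np.random.default_rng(0)
        t = np.arange(0, 2, 0.004)  # 250 Hz
        d = 4.0 + rng.normal(0, 0.02, t.size)
        cluster = slice(250, 255)
        d[cluster] += 0.2  # 10x noise SD
        mask, _, _ = filter_trendline_deviation(t, d, np.ones(t.size, bool), fsettings)
        assert not mask[cluster].any()

    def test_clean_trace_rejection_below_5pct(self, fsettings):
        rng = np.random.default_rng(2)
        t = np.arange(0, 10, 0.01)
        d = 4.5 + 0.4 * np.sin(2 * np.pi * 0.2 * t) + rng.normal(0, 0.02, t.size)
        mask, _, _ = filter_trendline_deviation(t, d, np.ones(t.size, bool), fsettings)
        assert (~mask).mean() <= 0.05

    def test_samples_dragged_out_by_cluster_are_reinstated(self, fsettings):
        rng = np.random.default_rng(0)
        t = np.arange(0, 2, 0.01)
        d = 4.0 + rng.normal(0, 0.02, t.size)
        d[100:110] += 2.0
        mask, verdicts, _ = filter_trendline_deviation(
            t, d, np.ones(t.size, bool), fsettings
        )
        assert not mask[100:110].any()
        reinstated = ~verdicts[0] & mask
        assert reinstated.any()  # pass-1 casualties back in the final valid set

    def test_reinstatement_limited_to_pass1_scope(self, fsettings):
        """Samples invalid at entry can never come back."""
        rng = np.random.default_rng(3)
        t = np.arange(0, 2, 0.01)
        d = 4.0 + rng.normal(0, 0.02, t.size)
        incoming = np.ones(t.size, bool)
        incoming[20:40] = False
        mask, _, _ = filter_trendline_deviation(t, d, incoming, fsettings)
        # the stage layer never touches out-of-scope samples; combined with
        # the incoming mask they therefore stay rejected
        assert mask[~incoming].all()
        assert not (mask & incoming)[20:40].any()


class TestSparsity:
    def test_short_island_rejected(self, fsettings):
        t = np.arange(0, 1.0, 0.005)
        current = np.zeros(t.size, bool)
        current[(t < 0.4)] = True  # long section
        current[(t >= 0.46) & (t < 0.5)] = True  # ~45 ms island
        current[(t >= 0.56)] = True  # long section
        mask = filter_sparsity(t, current, fsettings)
        island = (t >= 0.46) & (t < 0.5) & current
        assert not mask[island].any()
        assert mask[current & ~island].all()

    def test_long_run_retained(self, fsettings):
        t = np.arange(0, 1.0, 0.005)
        current = (t >= 0.4) & (t < 0.6)  # 200 ms
        mask = filter_sparsity(t, current, fsettings)
        assert mask[current].all()

    def test_single_isolated_sample_rejected(self, fsettings):
        t = np.array([0.0, 0.5, 1.0])
        current = np.array([True, True, True])
        mask = filter_sparsity(t, current, fsettings)
        assert not mask.any()  # all runs have zero duration

    def test_idempotent(self, fsettings):
        rng = np.random.default_rng(8)
        t = np.arange(0, 2.0, 0.004)
        current = rng.random(t.size) > 0.3
        m1 = filter_sparsity(t, current, fsettings)
        m2 = filter_sparsity(t, current & m1, fsettings)
        assert not np.any(current & m1 & ~m2)


class TestPipeline:
    def test_synthetic_scenario_detection(self, default_scenario_run):
        rec, ledger, _ = default_scenario_run
        masks, reports = run_filter_pipeline(rec)
        for eye in rec.eyes:
            art = ledger.artifact_mask(eye)
            clean = ledger.clean_mask(eye)
            rejected = ~masks[eye].combined
            assert (art & rejected).sum() / art.sum() >= 0.95
            assert (clean & rejected).sum() / clean.sum() <= 0.05

    def test_artifact_free_trace_mostly_retained(self, smooth_trace):
        t, d = smooth_trace
        rec = RawRecording(t, d, np.full(t.size, np.nan))
        masks, _ = run_filter_pipeline(rec)
        assert masks["left"].combined.mean() >= 0.95

    def test_stages_only_turn_samples_off(self, default_scenario_run):
        rec, _, _ = default_scenario_run
        masks, _ = run_filter_pipeline(rec)
        for eye in rec.eyes:
            vm = masks[eye]
            assert vm.combined.sum() <= vm.layers["present"].sum()

    def test_range_and_sparsity_idempotent_on_survivors(self, default_scenario_run):
        rec, _, _ = default_scenario_run
        s = FilterSettings()
        masks, _ = run_filter_pipeline(rec, s)
        for eye in rec.eyes:
            valid = masks[eye].combined
            d = rec.eye(eye)
            assert filter_range(d, s)[valid].all()
            assert filter_sparsity(rec.timestamps, valid, s)[valid].all()

    def test_report_counts_and_thresholds(self, default_scenario_run):
        rec, _, _ = default_scenario_run
        masks, reports = run_filter_pipeline(rec)
        for eye in rec.eyes:
            rep = reports[eye]
            total_rejected = sum(rep.stage_rejections.values())
            assert rep.n_present - total_rejected == rep.n_valid
            assert rep.thresholds["speed_mm_per_s"] > 0
            assert rep.settings["speed_mad_multiplier"] == 16
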