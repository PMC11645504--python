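"""Pupil preprocessing: range filter, dilation speed, MAD rejection, EMA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazemarkers as gm
from gazemarkers.pupil import (
    PUPIL_MAX_MM,
    PUPIL_MIN_MM,
    mad_threshold,
    trial_pupil_metrics,
)


class TestRangeFilter:
    def test_out_of_range_removed(self):
        t, p = gm.range_filter([0, 10, 20], [3.0, 0.9, 3.1])
        assert list(p) == [3.0, 3.1]
        assert list(t) == [0, 20]

    def test_bounds_are_inclusive(self):
        t, p = gm.range_filter([0, 10], [9.0, 1.5])
        assert list(p) == [9.0, 1.5]

    def test_all_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            t, p = gm.range_filter([0, 10], [12.0, 12.0])
        assert p.size == 0

    def test_invalid_flag_removes_sample(self):
        t, p = gm.range_filter([0, 10], [3.0, 3.0], valid=[True, False])
        assert list(t) == [0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = np.arange(50.0)
        p = rng.uniform(0.5, 10.5, 50)
        t1, p1 = gm.range_filter(t, p)
        t2, p2 = gm.range_filter(t1, p1)
        assert np.array_equal(p1, p2) and np.array_equal(t1, t2)


class TestDilationSpeed:
    def test_constant_trace_has_zero_speed(self):
        s = gm.dilation_speed([0, 10, 20, 30], [3.0, 3.0, 3.0, 3.0])
        assert np.all(s == 0)

    def test_symmetric_two_sided_max(self):
        # |(3.1-3.0)/10| = |(3.0-3.1)/10| = 0.01 mm/ms
        s = gm.dilation_speed([0, 10, 20], [3.0, 3.1, 3.0])
        assert s[1] == pytest.approx(0.01)

    def test_asymmetric_takes_larger_side(self):
        # backward 0.01, forward 0.02 -> 0.02 mm/ms
        s = gm.dilation_speed([0, 10, 20], [3.0, 3.1, 3.3])
        assert s[1] == pytest.approx(0.02)

    def test_endpoints_use_one_sided_speed(self):
        s = gm.dilation_speed([0, 10, 20], [3.0, 3.1, 3.3])
        assert s[0] == pytest.approx(0.01)
        assert s[2] == pytest.approx(0.02)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            gm.dilation_speed([0, 10, 10], [3.0, 3.1, 3.2])


class TestMADFilter:
    def test_worked_example(self):
        """s = [1, 2, 100]: median 2, MAD 1, T = 3.5, one sample above."""
        s = np.array([1.0, 2.0, 100.0])
        assert np.median(s) == 2.0
        assert mad_threshold(s) == pytest.approx(3.5)
        removed = s > mad_threshold(s)
        assert list(removed) == [False, False, True]  # only the 100 goes

    def test_spiked_trace_loses_spike_sample(self):
        t = np.arange(12.0)
        p = np.full(12, 3.0)
        p[6] = 5.0  # single-sample spike
        tf, pf = gm.mad_outlier_filter(t, p)
        assert 6.0 not in tf  # the spike itself is removed
        assert np.all(pf <= 3.0)

    def test_constant_speed_keeps_everything(self):
        t = np.arange(5.0)
        p = 3.0 + 0.01 * t  # constant slope -> constant s, MAD 0
        tf, pf = gm.mad_outlier_filter(t, p)
        assert tf.size == 5

    def test_matches_bruteforce_median_mad_on_random_traces(self):
        """Threshold agrees with a naive sort-based median/MAD to 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            s = rng.exponential(1.0, rng.integers(3, 40))

            def naive_median(v):
                v = sorted(v)
                k = len(v)
                return v[k // 2] if k % 2 else (v[k // 2 - 1] + v[k // 2]) / 2

            med = naive_median(s)
            mad = naive_median([abs(x - med) for x in s])
            assert mad_threshold(s) == pytest.approx(med + 1.5 * mad, abs=1e-12)

    def test_too_few_samples_pass_through(self):
        with pytest.warns(UserWarning):
            t, p = gm.mad_outlier_filter([0, 1], [3.0, 9.0])
        assert t.size == 2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_removed_set_shrinks_as_scalar_grows(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 100, 30))
        t += np.arange(30) * 1e-3  # ensure strictly increasing
        p = rng.uniform(2, 5, 30)
        sizes = [gm.mad_outlier_filter(t, p, n)[0].size for n in (0.5, 1.5, 3.0, 10.0)]
        assert sizes == sorted(sizes)


class TestMergeEyes:
    def test_mean_of_common_timestamps(self):
        t, p = gm.merge_eyes([10.0], [3.0], [10.0], [3.2])
        assert list(t) == [10.0]
        assert p[0] == pytest.approx(3.1)

    def test_one_eyed_timestamps_dropped(self):
        t, p = gm.merge_eyes([0.0, 10.0], [3.0, 3.0], [10.0], [3.2])
        assert list(t) == [10.0]

    def test_identical_eyes_identity(self):
        tl = np.arange(5.0)
        pl = np.linspace(3, 4, 5)
        t, p = gm.merge_eyes(tl, pl, tl, pl)
        assert np.allclose(p, pl)

    def test_disjoint_eyes_warn(self):
        with pytest.warns(UserWarning):
            t, p = gm.merge_eyes([0.0], [3.0], [1.0], [3.0])
        assert t.size == 0


class TestResampleSmooth:
    def test_constant_preserved(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 1000, 300))
        p = np.full(300, 3.0)
        tg, pg = gm.resample_smooth(t, p)
        assert np.allclose(pg, 3.0)

    def test_output_on_2ms_grid(self):
        t = np.arange(0, 500, 7.3)  # nonuniform relative to output grid
        p = np.linspace(3, 4, t.size)
        tg, pg = gm.resample_smooth(t, p)
        assert np.allclose(np.diff(tg), 2.0)

    def test_gap_not_interpolated(self):
        t = np.concatenate([np.arange(0, 200, 4.0), np.arange(260, 460, 4.0)])
        p = np.full(t.size, 3.0)
        tg, pg = gm.resample_smooth(t, p)
        # no output timestamps inside the 60 ms gap
        assert not np.any((tg > 197) & (tg < 259))
        # spacing within each segment still uniform
        seg_breaks = np.nonzero(np.diff(tg) > 2.01)[0]
        assert seg_breaks.size == 1


class TestPupilMetrics:
    def test_constant_trace(self):
        m = gm.pupil_metrics(np.full(100, 3.0))
        assert (m.avg, m.max, m.min, m.sd) == (3.0, 3.0, 3.0, 0.0)

    def test_two_point_trace_uses_sample_sd(self):
        m = gm.pupil_metrics(np.array([2.0, 4.0]))
        assert m.avg == 3.0
        assert m.sd == pytest.approx(np.std([2.0, 4.0], ddof=1))

    def test_ordering_invariant_on_random_traces(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(1.5, 9.0, rng.integers(2, 50))
            m = gm.pupil_metrics(p)
            assert m.min <= m.avg <= m.max
            assert m.sd >= 0


class TestFullPipeline:
    def _trace(self, rng, n=400, noise=0.01):
        t = np.arange(n) * 4.0
        p = 4.0 + 0.3 * np.sin(2 * np.pi * t / 3000.0) + rng.normal(0, noise, n)
        return t, p

    def test_output_always_within_feasible_range(self):
        """No pipeline output lies outside [1.5, 9.0] mm, whatever the input."""
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = rng.integers(10, 60)
            t = np.sort(rng.uniform(0, 2000, n)) + np.arange(n) * 1e-3
            p = rng.uniform(0.0, 12.0, n)  # includes infeasible values
            tg, pg = gm.preprocess_trial(t, p, p + rng.normal(0, 0.01, n))
            if pg.size:
                assert pg.min() >= PUPIL_MIN_MM - 1e-9
                assert pg.max() <= PUPIL_MAX_MM + 1e-9

    def test_spike_rejection_rate(self):
        """>=95% of injected large spikes removed, <=5% of clean samples lost."""
        rng = np.random.default_rng(42)
        t, p = self._trace(rng, noise=0.0)  # smooth clean signal
        clean = p.copy()
        spike_idx = rng.choice(np.arange(20, 380, 8), 5, replace=False)
        p_sp = clean.copy()
        p_sp[spike_idx] += 2.0  # large step spikes, far beyond 10x MAD
        tl, pl = gm.range_filter(t, p_sp)
        tf, pf = gm.mad_outlier_filter(tl, pl)
        surviving = np.isin(t, tf)
        spikes_removed = np.mean(~surviving[spike_idx])
        clean_mask = np.ones(t.size, bool)
        clean_mask[spike_idx] = False
        clean_lost = np.mean(~surviving[clean_mask])
        assert spikes_removed >= 0.95
        assert clean_lost <= 0.05

    def test_trial_metrics_from_raw_samples(self, screen):
        """Constant noiseless pupil input yields Avg=Max=Min=baseline, Sd=0."""
        rng = np.random.default_rng(0)
        ph = gm.PhenotypeParams(
            pupil_sd_mm=0.0, pupil_noise_mm=0.0, artifact_prob=0.0,
            blink_prob=0.0, gaze_noise_px=0.0, pupil_baseline_sd_mm=0.0,
        )
        spec = gm.TrialSpec("prosaccade", 15, "right")
        samples, _ = gm.generate_trial(ph, spec, screen, rng, 250)
        m = trial_pupil_metrics(samples)
        assert m.avg == pytest.approx(4.0, abs=1e-9)
        assert m.max == pytest.approx(4.0, abs=1e-9)
        assert m.min == pytest.approx(4.0, abs=1e-9)
        assert m.sd == pytest.approx(0.0, abs=1e-9)
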