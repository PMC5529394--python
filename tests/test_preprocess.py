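"""Per-run preprocessing: detrending, filtering, nuisance regression."""

import numpy as np
import pytest

import reachdecode as rd
from reachdecode.core import RunTimeSeries
from reachdecode.preprocess import (
    highpass,
    linear_detrend,
    normalize_baseline,
    regress_out_motion,
    remove_low_intensity_voxels,
    trial_average,
)


def _ts(values, tr=1.0, run=1, motion=None):
    return RunTimeSeries(np.asarray(values, dtype=float), tr=tr, run=run, motion=motion)


def _sinusoid(freq_hz, T=564, tr=1.0):
    t = np.arange(T) * tr
    return np.sin(2 * np.pi * freq_hz * t)[:, None]


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(100.0)
        ts = _ts((3.0 + 0.5 * t)[:, None])
        out = linear_detrend(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_zero_input_stays_zero(self):
        out = linear_detrend(_ts(np.zeros((50, 3))))
        np.testing.assert_allclose(out.values, 0.0)

    def test_residual_orthogonal_to_line(self):
        rng = np.random.default_rng(0)
        ts = _ts(rng.normal(size=(80, 5)))
        out = linear_detrend(ts)
        t = np.arange(80.0)
        assert np.all(np.abs(out.values.sum(axis=0)) < 1e-8)
        assert np.all(np.abs(t @ out.values) < 1e-8)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            linear_detrend(_ts(np.zeros((2, 1))))


class TestHighpass:
    def test_slow_component_attenuated(self):
        ts = _ts(_sinusoid(0.002))
        out = highpass(ts, cutoff=0.01)
        # amplitude at the stimulated frequency via FFT
        f_in = np.abs(np.fft.rfft(ts.values[:, 0]))
        f_out = np.abs(np.fft.rfft(out.values[:, 0]))
        peak = np.argmax(f_in)
        assert f_out[peak] <= 0.1 * f_in[peak]

    def test_fast_component_retained(self):
        ts = _ts(_sinusoid(0.05))
        out = highpass(ts, cutoff=0.01)
        # compare amplitude at the stimulated frequency via FFT
        f_in = np.abs(np.fft.rfft(ts.values[:, 0]))
        f_out = np.abs(np.fft.rfft(out.values[:, 0]))
        peak = np.argmax(f_in)
        assert f_out[peak] >= 0.9 * f_in[peak]

    def test_dc_removed(self):
        out = highpass(_ts(np.full((200, 2), 7.0)), cutoff=0.01)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(_ts(np.zeros((100, 1))), cutoff=0.6)


class TestMotionRegression:
    def test_motion_spanned_signal_removed(self):
        rng = np.random.default_rng(1)
        motion = rng.normal(size=(120, 6))
        voxel = motion @ rng.normal(size=6) + 2.0
        ts = _ts(voxel[:, None], motion=motion)
        out = regress_out_motion(ts)
        assert np.abs(out.values).max() <= 1e-8

    def test_zero_motion_mean_centers(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(60, 3)) + 5.0
        out = regress_out_motion(_ts(values, motion=np.zeros((60, 6))))
        np.testing.assert_allclose(out.values, values - values.mean(axis=0), atol=1e-9)

    def test_residual_orthogonal_to_motion_columns(self):
        rng = np.random.default_rng(3)
        motion = rng.normal(size=(90, 6))
        ts = _ts(rng.normal(size=(90, 4)), motion=motion)
        out = regress_out_motion(ts)
        assert np.all(np.abs(motion.T @ out.values) < 1e-7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regress_out_motion(_ts(np.zeros((50, 1))), np.zeros((40, 6)))


class TestBaseline:
    def test_constant_signal_zeroed(self):
        out = normalize_baseline(_ts(np.full((40, 2), 3.3)), [(0, 10)])
        np.testing.assert_allclose(out.values, 0.0)

    def test_invariant_to_global_offset(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(40, 3))
        a = normalize_baseline(_ts(values), [(5, 15)])
        b = normalize_baseline(_ts(values + 42.0), [(5, 15)])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_known_baseline_subtracted_exactly(self):
        values = np.ones((30, 1))
        values[:10] = 7.5  # baseline window value
        out = normalize_baseline(_ts(values), [(0, 10)])
        np.testing.assert_allclose(out.values[:10], 0.0)
        np.testing.assert_allclose(out.values[10:], 1.0 - 7.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            normalize_baseline(_ts(np.zeros((20, 1))), [])


class TestTrialAverage:
    def _design(self):
        return rd.generate_design(runs=1, reps_per_direction=1, n_rest=2,
                                  trial_duration=10.0, lead_in=0.0, seed=0)

    def test_boxcar_amplitude_recovered(self):
        design = self._design()
        T = int(design.onset.max() + 10)
        values = np.zeros((T, 1))
        reach = design[design.condition == "reach"]
        for _, row in reach.iterrows():
            a = int(row.onset + 3)
            values[a : a + 7] = row.direction + 1.0  # distinct amplitude per trial
        out = trial_average(_ts(values), design, shift=3.0)
        np.testing.assert_allclose(out.values[:, 0], reach.direction + 1.0)

    def test_rest_trials_produce_no_rows(self):
        design = self._design()
        T = int(design.onset.max() + 10)
        out = trial_average(_ts(np.ones((T, 2))), design, shift=0.0)
        assert out.n_trials == (design.condition == "reach").sum()

    def test_zero_shift_full_window_is_plain_mean(self):
        design = self._design()
        T = int(design.onset.max() + 10)
        rng = np.random.default_rng(5)
        values = rng.normal(size=(T, 2))
        out = trial_average(_ts(values), design, shift=0.0)
        reach = design[design.condition == "reach"]
        for i, (_, row) in enumerate(reach.iterrows()):
            a = int(row.onset)
            np.testing.assert_allclose(out.values[i], values[a : a + 10].mean(axis=0))

    def test_window_overrunning_run_rejected(self):
        design = self._design()
        T = int(design.onset.max()) + 5  # run truncated
        with pytest.raises(ValueError):
            trial_average(_ts(np.zeros((T, 1))), design, shift=4.0)

    def test_shift_outside_trial_rejected(self):
        design = self._design()
        with pytest.raises(ValueError):
            trial_average(_ts(np.zeros((200, 1))), design, shift=10.0)


class TestLowIntensityRemoval:
    def test_equal_intensities_keep_all(self):
        keep = remove_low_intensity_voxels(np.full((20, 5), 3.0), 0.1)
        assert np.array_equal(keep, np.arange(5))

    def test_dead_voxel_removed(self):
        values = np.ones((20, 4))
        values[:, 2] = 0.0
        keep = remove_low_intensity_voxels(values, 0.1)
        assert 2 not in keep

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0.0, 10.0, size=(30, 40))
        thr = 0.4
        keep = remove_low_intensity_voxels(values, thr)
        means = values.mean(axis=0)
        expected = [v for v in range(40) if means[v] >= thr * means.mean()]
        assert list(keep) == expected

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            remove_low_intensity_voxels(np.array([[-1.0, -1.0]]), 0.1)


def test_per_run_processing_differs_from_concatenated():
    """Concatenating runs before detrending is not equivalent on drifting data."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=(100, 3))
    t = np.arange(100.0)[:, None]
    run1 = base + 0.05 * t  # different drifts per run
    run2 = base - 0.08 * t
    per_run = np.vstack(
        [linear_detrend(_ts(run1)).values, linear_detrend(_ts(run2)).values]
    )
    joint = linear_detrend(_ts(np.vstack([run1, run2]))).values
    assert np.abs(per_run - joint).max() > 0.1


def test_full_pipeline_recovers_signal_from_drifting_input(design):
    """End-to-end preprocessing undoes drift well enough to recover tuning."""
    gt = rd.generate_ground_truth(30, noise_sd=0.0, seed=21)
    expected = rd.generate_trial_responses(design, gt)
    runs = rd.generate_timeseries(design, gt, drift_amplitude=2.0, seed=22)
    R = rd.preprocess_runs(runs, design, regress_motion=False)
    corr = np.corrcoef(R.values.ravel(), expected.values.ravel())[0, 1]
    assert corr > 0.85
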