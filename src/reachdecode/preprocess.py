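"""Per-run preprocessing of voxel time series into trial responses.

The pipeline order is fixed: linear detrend -> high-pass (0.01 Hz) -> motion
regression -> baseline normalization -> hemodynamic-shifted trial averaging.
Every stage operates strictly within one run.  Low-intensity voxel removal
acts on the raw intensities before filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ResponseMatrix, RunTimeSeries

__all__ = [
    "linear_detrend",
    "highpass",
    "regress_out_motion",
    "normalize_baseline",
    "rest_windows",
    "trial_average",
    "remove_low_intensity_voxels",
    "preprocess_runs",
]


def _residualize(values: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of every voxel column on the columns of X."""
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def linear_detrend(ts: RunTimeSeries) -> RunTimeSeries:
    """Remove each voxel's best-fit line over time (mean and linear trend)."""
    T = ts.n_volumes
    if T < 3:
        raise ValueError("need at least 3 volumes to detrend")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    return ts.with_values(_residualize(ts.values, X))


def highpass(ts: RunTimeSeries, cutoff: float = 0.01) -> RunTimeSeries:
    """Remove slow drifts below ``cutoff`` Hz by discrete-cosine regression.

    The DCT nuisance set contains every cosine with frequency below the
    cutoff (plus the constant), the standard fMRI drift model; regressing it
    out attenuates components below the cutoff while passing faster ones.
    """
    T = ts.n_volumes
    nyquist = 0.5 / ts.tr
    if not 0 < cutoff < nyquist:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    order = int(np.floor(2.0 * T * ts.tr * cutoff))
    t = np.arange(T, dtype=float)
    cols = [np.ones(T)]
    for j in range(1, order + 1):
        cols.append(np.cos(np.pi * j * (2.0 * t + 1.0) / (2.0 * T)))
    return ts.with_values(_residualize(ts.values, np.column_stack(cols)))


def regress_out_motion(ts: RunTimeSeries, motion: np.ndarray | None = None) -> RunTimeSeries:
    """Residualize every voxel on the six rigid-body motion parameters.

    Uses ``ts.motion`` when no explicit motion array is given. The regression
    includes an intercept, so the output is mean-centered.
    """
    if motion is None:
        motion = ts.motion
    if motion is None:
        raise ValueError("no motion parameters available")
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (ts.n_volumes, 6):
        raise ValueError("motion must be volumes x 6")
    X = np.column_stack([np.ones(ts.n_volumes), motion])
    return ts.with_values(_residualize(ts.values, X))


def rest_windows(
    design: pd.DataFrame,
    run: int,
    shift: float,
    tr: float,
    window: float | None = None,
) -> list[tuple[int, int]]:
    """Volume-index windows of the rest (center-hold) trials of one run.

    Windows are shifted by the same hemodynamic delay as reaching trials so
    the baseline estimate aligns with the signal epochs being averaged.
    """
    rest = design[(design["run"] == run) & (design["condition"] == "rest")]
    out = []
    for _, row in rest.iterrows():
        dur = float(row["duration"])
        win = dur - shift if window is None else window
        a = int(round((row["onset"] + shift) / tr))
        b = int(round((row["onset"] + shift + win) / tr))
        out.append((a, b))
    return out


def normalize_baseline(ts: RunTimeSeries, windows: list[tuple[int, int]]) -> RunTimeSeries:
    """Subtract each voxel's mean over the baseline windows of this run."""
    vols: list[int] = []
    for a, b in windows:
        vols.extend(range(max(a, 0), min(b, ts.n_volumes)))
    if not vols:
        raise ValueError("baseline windows are empty")
    baseline = ts.values[np.asarray(vols)].mean(axis=0)
    return ts.with_values(ts.values - baseline)


def trial_average(
    ts: RunTimeSeries,
    design: pd.DataFrame,
    shift: float = 4.0,
    window: float | None = None,
) -> ResponseMatrix:
    """Average each reaching trial's shifted window into one response row.

    Row i is the mean signal over ``[onset + shift, onset + shift + window)``
    in volumes; ``window`` defaults to the trial duration minus the shift
    (capped at the trial end). Rest trials produce no rows.
    """
    reach = design[(design["run"] == ts.run) & (design["condition"] == "reach")]
    if reach.empty:
        raise ValueError(f"run {ts.run} has no reaching trials")
    durations = reach["duration"].to_numpy(dtype=float)
    if shift < 0 or np.any(shift >= durations):
        raise ValueError("shift must lie in [0, trial_duration)")
    rows = []
    for _, row in reach.iterrows():
        dur = float(row["duration"])
        win = min(window, dur - shift) if window is not None else dur - shift
        if win <= 0:
            raise ValueError("averaging window is empty")
        a = int(round((row["onset"] + shift) / ts.tr))
        b = int(round((row["onset"] + shift + win) / ts.tr))
        if b > ts.n_volumes:
            raise ValueError("averaging window overruns the end of the run")
        rows.append(ts.values[a:b].mean(axis=0))
    return ResponseMatrix(
        np.vstack(rows),
        reach["run"].to_numpy(dtype=int),
        reach["direction"].to_numpy(dtype=float),
    )


def remove_low_intensity_voxels(
    values: np.ndarray | RunTimeSeries | list[RunTimeSeries],
    threshold_fraction: float = 0.1,
) -> np.ndarray:
    """Indices of voxels whose mean raw intensity clears the threshold.

    A voxel is dropped when its temporal-mean intensity is below
    ``threshold_fraction`` times the grand mean intensity across all voxels.
    Raises if nothing survives (degenerate input).
    """
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in [0, 1)")
    if isinstance(values, RunTimeSeries):
        arr = values.values
    elif isinstance(values, list):
        arr = np.vstack([ts.values for ts in values])
    else:
        arr = np.asarray(values, dtype=float)
    means = arr.mean(axis=0)
    keep = means >= threshold_fraction * means.mean()
    if not np.any(keep):
        raise ValueError("all voxels fall below the intensity threshold")
    return np.flatnonzero(keep)


def preprocess_runs(
    runs: list[RunTimeSeries],
    design: pd.DataFrame,
    shift: float = 4.0,
    cutoff: float = 0.01,
    low_intensity_threshold: float = 0.1,
    regress_motion: bool = True,
    window: float | None = None,
) -> ResponseMatrix:
    """Full per-run pipeline from raw time series to a ResponseMatrix.

    Applies low-intensity voxel removal on the raw intensities, then per run:
    detrend, high-pass, motion regression (when motion records exist and
    ``regress_motion``), baseline normalization against the rest-trial
    windows, and trial averaging; concatenates all runs' trial rows.
    The retained raw-voxel indices are recorded on the result.
    """
    keep = remove_low_intensity_voxels(runs, low_intensity_threshold)
    blocks = []
    for ts in runs:
        ts = ts.with_values(ts.values[:, keep])
        ts = linear_detrend(ts)
        ts = highpass(ts, cutoff)
        if regress_motion and ts.motion is not None:
            ts = regress_out_motion(ts)
        win = rest_windows(design, ts.run, shift, ts.tr, window)
        if win:
            ts = normalize_baseline(ts, win)
        blocks.append(trial_average(ts, design, shift, window))
    values = np.vstack([b.values for b in blocks])
    run_labels = np.concatenate([b.runs for b in blocks])
    dirs = np.concatenate([b.directions for b in blocks])
    return ResponseMatrix(values, run_labels, dirs, voxel_index=keep)
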