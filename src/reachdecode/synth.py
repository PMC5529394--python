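"""Synthetic center-out reaching experiments with known directional tuning.

The study conditions emulated here: six runs, each with 40 reaching trials
(five repetitions of eight target directions in pseudo-random order) and five
rest trials interleaved between them, 12 s per trial, TR 1 s, and a 24 s
lead-in so one run lasts 9 min 24 s.  Voxel ground truth assigns a fraction
of voxels smooth von-Mises-shaped directional tuning expressed as nonnegative
channel weights; the remainder are untuned.  Responses can be produced
directly at the trial level (channel model plus i.i.d. Gaussian noise) or as
BOLD-like run time series with hemodynamic delay, slow drift, motion-coupled
artifacts and per-volume noise, together with the exact motion record, so the
preprocessing stages can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ResponseMatrix, RunTimeSeries
from .encoder import BasisSet, build_design

__all__ = [
    "GroundTruth",
    "generate_design",
    "generate_ground_truth",
    "generate_trial_responses",
    "generate_motion",
    "generate_timeseries",
    "DEFAULT_NOISE_SD",
]

#: Trial-level response noise (response units) calibrated so that single-trial
#: leave-one-run-out reconstruction lands in the ~50 degree MAE regime.
DEFAULT_NOISE_SD = 1.45

_DIRECTIONS = np.arange(8) * 45.0


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic ROI.

    ``weights`` is k x n_voxels nonnegative channel weights (all-zero columns
    for untuned voxels); ``motion_coupling`` (n_voxels x 6) scales how much of
    each rigid-body motion parameter leaks into each voxel's signal.
    """

    weights: np.ndarray
    tuned: np.ndarray
    noise_sd: float
    motion_gain: float
    motion_coupling: np.ndarray
    basis: BasisSet
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tuned = np.asarray(self.tuned, dtype=bool)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if np.any(self.weights < 0):
            raise ValueError("channel weights must be nonnegative")
        if np.any(self.weights[:, ~self.tuned] != 0):
            raise ValueError("untuned voxels must have all-zero weights")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


def _rest_positions(rng: np.random.Generator, total: int, n_rest: int) -> set[int]:
    """Rest-slot positions: strictly between reaching trials, no two adjacent."""
    if n_rest == 0:
        return set()
    if 2 * n_rest - 1 > total - 2:
        raise ValueError("too many rest trials to interleave without adjacency")
    while True:
        pos = np.sort(rng.choice(np.arange(1, total - 1), size=n_rest, replace=False))
        if n_rest == 1 or np.all(np.diff(pos) > 1):
            return {int(p) for p in pos}


def generate_design(
    runs: int = 6,
    reps_per_direction: int = 5,
    n_rest: int = 5,
    trial_duration: float = 12.0,
    lead_in: float = 24.0,
    directions=_DIRECTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the trial table of a center-out reaching session.

    Returns a DataFrame with columns ``trial_id, run, condition, direction,
    onset, duration``; onsets are seconds from run start and strictly
    increasing within a run. Direction order is randomized per run and rest
    trials are pseudo-randomly interleaved between reaching trials.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if reps_per_direction < 1:
        raise ValueError("reps_per_direction must be >= 1")
    if n_rest < 0:
        raise ValueError("n_rest must be >= 0")
    if trial_duration <= 0 or lead_in < 0:
        raise ValueError("trial_duration must be positive and lead_in nonnegative")
    directions = np.asarray(directions, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    trial_id = 0
    for run in range(1, runs + 1):
        reach_dirs = rng.permutation(np.repeat(directions, reps_per_direction))
        total = reach_dirs.size + n_rest
        rest_at = _rest_positions(rng, total, n_rest)
        it = iter(reach_dirs)
        for slot in range(total):
            onset = lead_in + slot * trial_duration
            if slot in rest_at:
                rows.append((trial_id, run, "rest", np.nan, onset, trial_duration))
            else:
                rows.append((trial_id, run, "reach", float(next(it)), onset, trial_duration))
            trial_id += 1
    return pd.DataFrame(
        rows, columns=["trial_id", "run", "condition", "direction", "onset", "duration"]
    )


def generate_ground_truth(
    n_voxels: int,
    tuned_fraction: float = 0.5,
    weight_model: str = "von-mises",
    amplitude: float = 1.0,
    kappa: float = 2.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    motion_gain: float = 0.0,
    basis: BasisSet | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-voxel ground-truth channel weights.

    ``von-mises`` (default): each tuned voxel gets a random preferred
    direction; its channel weights are the nonnegative projections of a
    von-Mises-shaped tuning curve (concentration ``kappa``) onto the channels,
    rescaled so the voxel's peak directional response equals its amplitude
    (jittered uniformly in [0.5, 1.5] x ``amplitude``).  ``sparse``: one or two
    random channels per tuned voxel carry weight.  Exactly
    ``round(tuned_fraction * n_voxels)`` voxels are tuned.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if not 0.0 <= tuned_fraction <= 1.0:
        raise ValueError("tuned_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    basis = basis or BasisSet()
    rng = np.random.default_rng(seed)
    n_tuned = int(round(tuned_fraction * n_voxels))
    tuned = np.zeros(n_voxels, dtype=bool)
    tuned[rng.permutation(n_voxels)[:n_tuned]] = True
    tuned_idx = np.flatnonzero(tuned)

    W = np.zeros((basis.k, n_voxels))
    prefs = rng.uniform(0.0, 360.0, n_tuned)
    amps = amplitude * rng.uniform(0.5, 1.5, n_tuned)
    theta = np.arange(0.0, 360.0)
    B = build_design(theta, basis)  # (360, k)
    if weight_model == "von-mises":
        for j, pref, amp in zip(tuned_idx, prefs, amps):
            f = np.exp(kappa * (np.cos(np.deg2rad(theta - pref)) - 1.0))
            w = B.T @ f / theta.size  # nonnegative projection onto channels
            peak = float(np.max(B @ w))
            W[:, j] = amp * w / peak
    elif weight_model == "sparse":
        for j, amp in zip(tuned_idx, amps):
            channels = rng.choice(basis.k, size=rng.integers(1, 3), replace=False)
            w = np.zeros(basis.k)
            w[channels] = rng.uniform(0.5, 1.0, channels.size)
            peak = float(np.max(B @ w))
            W[:, j] = amp * w / peak
    else:
        raise ValueError(f"unknown weight_model {weight_model!r}")

    coupling = motion_gain * rng.normal(0.0, 1.0, (n_voxels, 6))
    if motion_gain == 0:
        coupling = np.zeros((n_voxels, 6))
    return GroundTruth(
        weights=W,
        tuned=tuned,
        noise_sd=float(noise_sd),
        motion_gain=float(motion_gain),
        motion_coupling=coupling,
        basis=basis,
        seed=int(seed),
    )


def generate_trial_responses(design: pd.DataFrame, gt: GroundTruth) -> ResponseMatrix:
    """Trial-level responses ``S w + noise`` for every reaching trial.

    Row i equals the channel profile of trial i's direction times the true
    weights, plus i.i.d. Gaussian noise of standard deviation ``gt.noise_sd``
    per voxel. Rest trials contribute no rows.
    """
    reach = design[design["condition"] == "reach"]
    if reach.empty:
        raise ValueError("design contains no reaching trials")
    S = build_design(reach["direction"].to_numpy(dtype=float), gt.basis)
    clean = S @ gt.weights
    rng = np.random.default_rng([gt.seed, 101])
    values = clean + rng.normal(0.0, gt.noise_sd, clean.shape)
    return ResponseMatrix(
        values,
        reach["run"].to_numpy(dtype=int),
        reach["direction"].to_numpy(dtype=float),
    )


def _run_volumes(design: pd.DataFrame, run: int, tr: float) -> int:
    run_df = design[design["run"] == run]
    return int(round(float((run_df["onset"] + run_df["duration"]).max()) / tr))


def generate_motion(
    design: pd.DataFrame,
    tr: float = 1.0,
    walk_sd: float = 0.02,
    task_amplitude: float = 0.1,
    direction_coupled: bool = True,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Synthetic rigid-body motion per run (volumes x 6, sampled at TR).

    A demeaned random walk models slow head drift; every reaching trial adds a
    movement-epoch bump (2 s starting 4 s after trial onset, matching the cue
    -> move -> hold trial timeline). With ``direction_coupled`` the bump's
    translation/rotation mix depends on the reach direction — the mechanism by
    which task-locked head motion can masquerade as directional information.
    Translations are in mm, rotations in radians (scaled down by 50).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = np.random.default_rng(seed)
    scales = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
    out: dict[int, np.ndarray] = {}
    for run in sorted(design["run"].unique()):
        T = _run_volumes(design, run, tr)
        walk = np.cumsum(rng.normal(0.0, walk_sd, (T, 6)), axis=0)
        walk -= walk.mean(axis=0)
        m = walk * scales
        run_df = design[(design["run"] == run) & (design["condition"] == "reach")]
        for _, tr_row in run_df.iterrows():
            a = int(round((tr_row["onset"] + 4.0) / tr))
            b = min(int(round((tr_row["onset"] + 6.0) / tr)), T)
            if direction_coupled:
                d = np.deg2rad(tr_row["direction"])
                u = np.array(
                    [np.cos(d), np.sin(d), 0.3, 0.5 * np.cos(d), 0.5 * np.sin(d), 0.2]
                )
            else:
                u = np.array([0.7, 0.7, 0.3, 0.35, 0.35, 0.2])
            m[a:b] += task_amplitude * u * scales
        out[int(run)] = m
    return out


def generate_timeseries(
    design: pd.DataFrame,
    gt: GroundTruth,
    tr: float = 1.0,
    hemodynamic_delay: float = 4.0,
    drift_amplitude: float = 0.0,
    baseline_level: float = 100.0,
    motion: dict[int, np.ndarray] | None = None,
    seed: int | None = None,
) -> list[RunTimeSeries]:
    """BOLD-like run time series for a design and ground truth.

    Each reaching trial contributes a boxcar of its trial response delayed by
    ``hemodynamic_delay``; on top of that come a per-voxel baseline offset,
    optional linear plus slow sinusoidal (0.005 Hz) drift scaled by
    ``drift_amplitude``, motion-coupled signal ``motion @ coupling^T`` when a
    motion record is supplied, and i.i.d. per-volume Gaussian noise of
    standard deviation ``gt.noise_sd``.  The exact motion series used is
    attached to each returned :class:`RunTimeSeries`.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if hemodynamic_delay < 0:
        raise ValueError("hemodynamic_delay must be nonnegative")
    rng = np.random.default_rng([gt.seed if seed is None else seed, 202])
    n = gt.n_voxels
    baseline = baseline_level * rng.uniform(0.9, 1.1, n)

    reach = design[design["condition"] == "reach"]
    S = build_design(reach["direction"].to_numpy(dtype=float), gt.basis)
    clean = S @ gt.weights  # one response row per reach trial
    reach = reach.reset_index(drop=True)

    out: list[RunTimeSeries] = []
    for run in sorted(design["run"].unique()):
        T = _run_volumes(design, run, tr)
        X = np.zeros((T, n))
        rows = np.flatnonzero(reach["run"].to_numpy() == run)
        for i in rows:
            onset = float(reach.loc[i, "onset"])
            dur = float(reach.loc[i, "duration"])
            a = int(round((onset + hemodynamic_delay) / tr))
            b = min(int(round((onset + hemodynamic_delay + dur) / tr)), T)
            X[a:b] += clean[i]
        if drift_amplitude > 0:
            t = np.arange(T) * tr
            slope = drift_amplitude * rng.uniform(-1.0, 1.0, n)
            X += slope[None, :] * (2.0 * t[:, None] / t[-1] - 1.0)
            amp = drift_amplitude * rng.uniform(0.3, 1.0, n)
            phase = rng.uniform(0.0, 2.0 * np.pi, n)
            X += amp[None, :] * np.sin(2.0 * np.pi * 0.005 * t[:, None] + phase[None, :])
        X += baseline
        run_motion = None
        if motion is not None:
            run_motion = np.asarray(motion[int(run)], dtype=float)
            if run_motion.shape != (T, 6):
                raise ValueError(f"motion for run {run} must be {T} x 6")
            X += run_motion @ gt.motion_coupling.T
        if gt.noise_sd > 0:
            X += rng.normal(0.0, gt.noise_sd, X.shape)
        out.append(RunTimeSeries(X, tr=tr, run=int(run), motion=run_motion))
    return out
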