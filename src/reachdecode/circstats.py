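"""Circular statistics for evaluating reconstructed directions.

Angles cross every public interface in degrees and are converted to radians
internally, in one place.  Provides the mean resultant direction, angular
variance AV = 1 - ||r||, the Jammalamadaka-SenGupta circular correlation,
wrapped absolute error on the circle (<= 180 degrees), and trial-averaged
reconstruction summaries.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "MeanDirection",
    "mean_direction",
    "angular_variance",
    "circular_correlation",
    "wrapped_abs_error",
    "mean_absolute_error",
    "trial_averaged_reconstruction",
]

_EPS_RESULTANT = 1e-12


class MeanDirection(NamedTuple):
    """Mean angle (degrees; NaN when the resultant vanishes) and ||r||."""

    angle: float
    resultant_length: float


def _to_rad(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.deg2rad(a)


def mean_direction(angles_deg) -> MeanDirection:
    """Vector-addition mean of a sample of angles.

    Unit vectors are summed and normalized by the count; the mean angle is the
    atan2 of the resultant and ``resultant_length`` its norm in [0, 1]. A
    vanishing resultant (e.g. two opposite angles) leaves the mean angle
    undefined, flagged as NaN.
    """
    a = _to_rad(angles_deg)
    if a.size == 0:
        raise ValueError("need at least one angle")
    C = float(np.cos(a).mean())
    S = float(np.sin(a).mean())
    r = float(np.hypot(C, S))
    if r < _EPS_RESULTANT:
        return MeanDirection(np.nan, r)
    return MeanDirection(float(np.rad2deg(np.arctan2(S, C)) % 360.0), r)


def angular_variance(angles_deg) -> float:
    """AV = 1 - ||r||: 0 for identical angles, 1 for evenly spread angles."""
    return 1.0 - mean_direction(angles_deg).resultant_length


def circular_correlation(alpha_deg, beta_deg) -> float:
    """Jammalamadaka-SenGupta circular correlation between two angle samples.

    rho = sum(sin(a - abar) sin(b - bbar)) /
          sqrt(sum(sin^2(a - abar)) * sum(sin^2(b - bbar)))

    with abar, bbar the circular means. Returns NaN when either sample is
    degenerate (all sine deviations zero).
    """
    a = _to_rad(alpha_deg)
    b = _to_rad(beta_deg)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("samples must have equal length >= 2")
    abar = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    bbar = np.arctan2(np.sin(b).mean(), np.cos(b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if den < _EPS_RESULTANT:
        return np.nan
    return float(np.sum(sa * sb) / den)


def wrapped_abs_error(predicted_deg, actual_deg) -> np.ndarray | float:
    """Angular distance on the circle, in [0, 180] degrees."""
    p = np.asarray(predicted_deg, dtype=float)
    q = np.asarray(actual_deg, dtype=float)
    d = np.abs(p - q) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def mean_absolute_error(predicted_deg, actual_deg) -> float:
    """Mean wrapped absolute error (MAE) across trials, degrees."""
    return float(np.mean(wrapped_abs_error(predicted_deg, actual_deg)))


def trial_averaged_reconstruction(
    predicted_deg, actual_deg
) -> tuple[pd.DataFrame, float]:
    """Per-target-direction circular summaries and the MAE of mean directions.

    Groups reconstructed angles by their actual target direction; per target
    reports the vector-addition mean direction, resultant length, AV, the
    single-trial MAE and the trial count. The second return value is the MAE
    between the per-target mean directions and the targets themselves (NaN
    propagates from undefined means).
    """
    pred = np.asarray(predicted_deg, dtype=float)
    act = np.asarray(actual_deg, dtype=float)
    if pred.shape != act.shape or pred.size == 0:
        raise ValueError("predicted and actual must be equal-length, nonempty")
    rows = []
    for target in np.unique(act):
        sel = act == target
        md = mean_direction(pred[sel])
        rows.append(
            {
                "direction": float(target),
                "mean_direction": md.angle,
                "resultant_length": md.resultant_length,
                "angular_variance": 1.0 - md.resultant_length,
                "mae_single_trial": mean_absolute_error(pred[sel], act[sel]),
                "n_trials": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    mae_of_means = float(
        np.mean(wrapped_abs_error(table["mean_direction"], table["direction"]))
    )
    return table, mae_of_means
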