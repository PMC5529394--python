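"""Sparse-classifier voxel selection by selection counts.

A sparse multinomial logistic classifier is fitted repeatedly to bootstrap
resamples of the training trials; each voxel's selection count (SC value) is
the number of resamples in which it receives any nonzero weight.  Voxels with
an SC value of zero are treated as irrelevant and removed before model
fitting.  Selection must only ever see training-fold trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

__all__ = ["SelectionResult", "smlr_fit", "select_voxels"]


@dataclass
class SelectionResult:
    """Per-voxel selection counts and the retained voxel index set."""

    sc_values: np.ndarray
    retained: np.ndarray
    repetitions: int

    def __post_init__(self) -> None:
        self.sc_values = np.asarray(self.sc_values, dtype=int)
        self.retained = np.asarray(self.retained, dtype=int)
        if np.any(self.sc_values < 0) or np.any(self.sc_values > self.repetitions):
            raise ValueError("sc_values must lie in [0, repetitions]")


def smlr_fit(
    values: np.ndarray,
    labels: np.ndarray,
    sparsity_control: float = 1.0,
) -> np.ndarray:
    """Sparse multinomial logistic weights (classes x voxels).

    Realized as L1-penalized one-vs-rest logistic regression on standardized
    responses; the L1 penalty drives most per-voxel weights exactly to zero.
    ``sparsity_control`` is the inverse penalty strength (smaller = sparser).
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if X.shape[0] <= classes.size:
        raise ValueError("need more trials than classes")
    if sparsity_control <= 0:
        raise ValueError("sparsity_control must be positive")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xz = (X - mu) / np.where(sd < 1e-12, 1.0, sd)
    base = LogisticRegression(
        l1_ratio=1.0, C=sparsity_control, solver="liblinear", tol=1e-3, max_iter=200
    )
    clf = OneVsRestClassifier(base).fit(Xz, y)
    return np.vstack([est.coef_ for est in clf.estimators_])


def select_voxels(
    values: np.ndarray,
    labels: np.ndarray,
    repetitions: int = 10,
    sparsity_control: float = 1.0,
    seed=0,
) -> SelectionResult:
    """Selection-count voxel screening over bootstrap resamples.

    Fits :func:`smlr_fit` on ``repetitions`` bootstrap resamples of the
    training trials (resampled until at least two classes are present) and
    counts, per voxel, the resamples in which it carries any nonzero weight.
    Retained = SC value > 0. If nothing is retained, a warning is issued and
    all voxels are kept so the pipeline can proceed.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    m, n = X.shape
    sc = np.zeros(n, dtype=int)
    for _ in range(repetitions):
        for _attempt in range(100):
            idx = rng.integers(0, m, m)
            if np.unique(y[idx]).size >= 2:
                break
        else:
            raise ValueError("could not draw a resample with two classes")
        W = smlr_fit(X[idx], y[idx], sparsity_control)
        sc += np.any(np.abs(W) > 1e-12, axis=0)
    retained = np.flatnonzero(sc > 0)
    if retained.size == 0:
        warnings.warn(
            "no voxel was ever selected; falling back to all voxels",
            RuntimeWarning,
            stacklevel=2,
        )
        retained = np.arange(n)
    return SelectionResult(sc_values=sc, retained=retained, repetitions=repetitions)
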