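"""Invertible channel-encoding model for movement direction.

A voxel's directional tuning is modelled as a nonnegative linear combination
of ``k`` half-wave rectified sinusoidal channels with preferred directions
equally spaced around the circle.  Writing ``S`` (trials x k) for the channel
responses evoked by the trained directions and ``R1`` (trials x voxels) for
the measured responses, the forward model is ``R1 = S w`` with a channel
weight matrix ``w`` (k x voxels).  Weights are estimated by ridge regression,

    w_hat = (S^T S + lambda I_k)^{-1} S^T R1,

with ``lambda`` chosen by the lowest bootstrap-averaged Bayesian information
criterion.  Decoding inverts the fitted model on held-out responses ``R2``,

    S_hat = R2 w_hat^T (w_hat w_hat^T + eps I_k)^{-1},

and matches each estimated channel profile against idealized channel profiles
by Pearson correlation — over the eight trained directions for 8-way
classification, or over a dense angular grid for continuous reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSet",
    "EncodingFit",
    "basis_response",
    "build_design",
    "fit_weights",
    "select_lambda",
    "invert_model",
    "classify",
    "reconstruct",
    "CANONICAL_DIRECTIONS",
]

#: The eight trained center-out target directions (degrees).
CANONICAL_DIRECTIONS = np.arange(8) * 45.0

# Relative tolerance used to detect ties when matching patterns; among tied
# candidates the smallest angle wins.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class BasisSet:
    """``k`` directional channels equally spaced on the circle.

    ``phase_deg`` rotates all channel centers jointly; ``power`` raises the
    rectified cosine to an exponent (1 = plain half-wave rectification).
    """

    k: int = 6
    phase_deg: float = 0.0
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two channels")
        if self.power <= 0:
            raise ValueError("power must be positive")

    @property
    def centers(self) -> np.ndarray:
        """Channel preferred directions in degrees, sorted, spacing 360/k."""
        return (np.arange(self.k) * 360.0 / self.k + self.phase_deg) % 360.0


@dataclass
class EncodingFit:
    """A fitted encoding model: weights, ridge parameter, voxel subset."""

    weights: np.ndarray  # (k, n)
    lam: float
    voxel_index: np.ndarray
    basis: BasisSet = field(default_factory=BasisSet)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def basis_response(angle_deg, basis: BasisSet | None = None) -> np.ndarray:
    """Channel responses to one movement direction.

    Component ``j`` is ``max(0, cos(angle - center_j)) ** power``.  Angles are
    interpreted modulo 360 degrees.
    """
    basis = basis or BasisSet()
    delta = np.deg2rad(float(angle_deg) - basis.centers)
    resp = np.maximum(0.0, np.cos(delta))
    if basis.power != 1.0:
        resp = resp**basis.power
    return resp


def build_design(angles_deg, basis: BasisSet | None = None) -> np.ndarray:
    """Stack :func:`basis_response` rows for a sequence of directions."""
    basis = basis or BasisSet()
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        return np.zeros((0, basis.k))
    delta = np.deg2rad(angles[:, None] - basis.centers[None, :])
    S = np.maximum(0.0, np.cos(delta))
    if basis.power != 1.0:
        S = S**basis.power
    return S


def fit_weights(S: np.ndarray, R1: np.ndarray, lam: float) -> np.ndarray:
    """Ridge estimate ``(S^T S + lam I)^{-1} S^T R1`` of the channel weights."""
    S = np.asarray(S, dtype=float)
    R1 = np.asarray(R1, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    k = S.shape[1]
    if lam == 0 and np.linalg.matrix_rank(S) < k:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; use lambda > 0"
        )
    A = S.T @ S + lam * np.eye(k)
    return np.linalg.solve(A, S.T @ R1)


def _ridge_bic(s: np.ndarray, UtR: np.ndarray, R: np.ndarray, lam: float) -> float:
    """BIC of one ridge fit from the SVD pieces of the design.

    ``m ln(RSS/m) + df ln(m)`` with ``df`` the trace of the ridge hat matrix
    and RSS summed over all voxels.
    """
    m = R.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(s > 0, s**2 / (s**2 + lam), 0.0)  # hat-matrix eigenvalues
    # residual = R - U diag(shrink) U^T R, so
    # ||residual||^2 = ||R||^2 - 2*sum(shrink*|UtR|^2) + sum(shrink^2*|UtR|^2)
    rss = float(
        np.sum(R**2)
        - 2 * np.sum(shrink[:, None] * UtR**2)
        + np.sum((shrink**2)[:, None] * UtR**2)
    )
    df = float(np.sum(shrink))
    rss = max(rss, 1e-300)
    return m * np.log(rss / m) + df * np.log(m)


def select_lambda(
    S: np.ndarray,
    R1: np.ndarray,
    grid=None,
    n_boot: int = 50,
    seed=0,
) -> float:
    """Pick the ridge parameter with the lowest bootstrap-mean BIC.

    Trials (rows of ``S`` and ``R1`` jointly) are resampled with replacement
    ``n_boot`` times; for every grid value the BIC of the ridge fit on each
    resample is computed and the grid value minimizing the mean BIC is
    returned (smallest value on ties).
    """
    S = np.asarray(S, dtype=float)
    R1 = np.asarray(R1, dtype=float)
    if grid is None:
        grid = np.logspace(-3, 3, 13)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("lambda grid values must be nonnegative")
    rng = np.random.default_rng(seed)
    m = S.shape[0]
    bic = np.zeros((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, m, m)
        Sb, Rb = S[idx], R1[idx]
        U, s, _ = np.linalg.svd(Sb, full_matrices=False)
        UtR = U.T @ Rb
        for j, lam in enumerate(grid):
            bic[b, j] = _ridge_bic(s, UtR, Rb, lam)
    return float(grid[int(np.argmin(bic.mean(axis=0)))])


def invert_model(R2: np.ndarray, weights: np.ndarray, ridge_eps="auto") -> np.ndarray:
    """Estimate channel responses ``S_hat = R2 w^T (w w^T + eps I)^{-1}``.

    ``ridge_eps="auto"`` scales the stabilizer to 1e-6 times the mean diagonal
    of ``w w^T``; pass 0 to demand the exact inverse (raises if singular).
    """
    R2 = np.atleast_2d(np.asarray(R2, dtype=float))
    W = np.asarray(weights, dtype=float)
    k = W.shape[0]
    G = W @ W.T
    if ridge_eps == "auto":
        eps = 1e-6 * float(np.trace(G)) / k
    else:
        eps = float(ridge_eps)
    if eps < 0:
        raise ValueError("ridge_eps must be nonnegative")
    A = G + eps * np.eye(k)
    if eps == 0 and np.linalg.matrix_rank(A) < k:
        raise np.linalg.LinAlgError("w w^T is singular; use ridge_eps > 0")
    return np.linalg.solve(A, (R2 @ W.T).T).T


def _match_patterns(S_hat: np.ndarray, angles: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Per row of ``S_hat``, the candidate angle with the highest Pearson r.

    Ties (within a relative tolerance) go to the smallest angle. Rows with no
    variance cannot be correlated; they fall back to the nearest candidate in
    Euclidean distance, with a warning.
    """
    S_hat = np.atleast_2d(np.asarray(S_hat, dtype=float))
    P = build_design(angles, basis)
    k = basis.k

    def _zscore(A):
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        const = sd[:, 0] < 1e-12
        return (A - mu) / np.where(sd < 1e-12, 1.0, sd), const

    Pz, p_const = _zscore(P)
    if np.any(p_const):  # cannot happen for k>=3 rectified cosines, but guard
        raise ValueError("candidate pattern has no variance")
    Z, const = _zscore(S_hat)
    C = Z @ Pz.T / k
    if np.any(const):
        warnings.warn(
            "constant channel-estimate row(s); falling back to Euclidean matching",
            RuntimeWarning,
            stacklevel=3,
        )
        diff = S_hat[const][:, None, :] - P[None, :, :]
        C[const] = -np.sqrt(np.sum(diff**2, axis=2))
    cmax = C.max(axis=1, keepdims=True)
    tol = _TIE_RTOL * np.maximum(1.0, np.abs(cmax))
    pick = np.argmax(C >= cmax - tol, axis=1)  # first True = smallest angle
    return np.asarray(angles, dtype=float)[pick]


def classify(
    S_hat: np.ndarray,
    candidates=None,
    basis: BasisSet | None = None,
) -> np.ndarray:
    """8-way direction read-out of estimated channel responses.

    Each row of ``S_hat`` is matched by Pearson correlation against the
    idealized channel profiles of the candidate directions (the eight trained
    targets by default).
    """
    basis = basis or BasisSet()
    if candidates is None:
        candidates = CANONICAL_DIRECTIONS
    candidates = np.sort(np.asarray(candidates, dtype=float) % 360.0)
    return _match_patterns(S_hat, candidates, basis)


def reconstruct(
    S_hat: np.ndarray,
    basis: BasisSet | None = None,
    grid_step: float = 1.0,
) -> np.ndarray:
    """Continuous direction read-out over a dense circular grid.

    Candidate profiles are generated for every angle ``0, grid_step, ...,
    360 - grid_step``; the best Pearson match is returned per trial, so the
    output is not restricted to the trained directions.
    """
    basis = basis or BasisSet()
    if grid_step <= 0 or abs(360.0 / grid_step - round(360.0 / grid_step)) > 1e-9:
        raise ValueError("grid_step must divide 360")
    grid = np.arange(0.0, 360.0, grid_step)
    return _match_patterns(S_hat, grid, basis)
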