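"""Shared data containers for the direction-decoding pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ResponseMatrix", "RunTimeSeries"]


@dataclass
class ResponseMatrix:
    """Trial-averaged voxel responses.

    Rows are reaching trials, columns are voxels. ``runs`` and ``directions``
    carry the per-trial run label and movement direction (degrees). This is the
    object every decoder consumes: the training block and the held-out block of
    a cross-validation fold are both row subsets of one ``ResponseMatrix``.
    """

    values: np.ndarray
    runs: np.ndarray
    directions: np.ndarray
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.runs = np.asarray(self.runs, dtype=int)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (trials x voxels) array")
        m = self.values.shape[0]
        if self.runs.shape != (m,) or self.directions.shape != (m,):
            raise ValueError("runs and directions must have one entry per trial")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index, dtype=int)
            if self.voxel_index.shape != (self.values.shape[1],):
                raise ValueError("voxel_index must have one entry per voxel")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset_trials(self, idx: np.ndarray) -> "ResponseMatrix":
        idx = np.asarray(idx)
        return ResponseMatrix(
            self.values[idx], self.runs[idx], self.directions[idx], self.voxel_index
        )

    def subset_voxels(self, idx: np.ndarray) -> "ResponseMatrix":
        idx = np.asarray(idx)
        vi = self.voxel_index[idx] if self.voxel_index is not None else idx.copy()
        return ResponseMatrix(self.values[:, idx], self.runs, self.directions, vi)


@dataclass
class RunTimeSeries:
    """Voxel time series of one run sampled at a fixed TR.

    ``values`` is volumes x voxels; ``motion`` holds the six rigid-body
    parameters (three translations in mm, three rotations in radians) sampled
    at the same TR, or ``None`` when no motion record exists.
    """

    values: np.ndarray
    tr: float
    run: int
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] == 0:
            raise ValueError("values must be a non-empty volumes x voxels array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.values.shape[0], 6):
                raise ValueError("motion must be volumes x 6")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "RunTimeSeries":
        return replace(self, values=values)
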