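"""File formats: trial tables as CSV, arrays as HDF5, optional NIfTI-1.

Motion parameters follow the SPM realignment-parameter dialect: six
whitespace/comma-delimited columns, three translations (mm) then three
rotations (radians), one row per volume.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ResponseMatrix, RunTimeSeries
from .encoder import BasisSet
from .synth import GroundTruth

__all__ = [
    "save_design",
    "load_design",
    "save_motion",
    "load_motion",
    "save_ground_truth",
    "load_ground_truth",
    "save_timeseries",
    "load_timeseries",
    "save_response_matrix",
    "load_response_matrix",
    "export_nifti",
    "load_nifti_dataset",
]


def save_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def load_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "run", "condition", "direction", "onset", "duration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    return df


def save_motion(motion: dict[int, np.ndarray], path) -> None:
    """All runs' motion in one CSV with a leading run column."""
    frames = []
    for run, m in sorted(motion.items()):
        df = pd.DataFrame(
            m, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        )
        df.insert(0, "run", run)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_motion(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return {
        int(run): g[cols].to_numpy(dtype=float) for run, g in df.groupby("run")
    }


def load_motion_txt(path) -> np.ndarray:
    """One run's SPM-style rp_*.txt: six columns, no header."""
    return np.loadtxt(path)


def save_ground_truth(gt: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=gt.weights, track_times=False)
        f.create_dataset("tuned", data=gt.tuned, track_times=False)
        f.create_dataset("motion_coupling", data=gt.motion_coupling, track_times=False)
        f.attrs["noise_sd"] = gt.noise_sd
        f.attrs["motion_gain"] = gt.motion_gain
        f.attrs["seed"] = gt.seed
        f.attrs["basis_k"] = gt.basis.k
        f.attrs["basis_phase_deg"] = gt.basis.phase_deg
        f.attrs["basis_power"] = gt.basis.power


def load_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        basis = BasisSet(
            k=int(f.attrs["basis_k"]),
            phase_deg=float(f.attrs["basis_phase_deg"]),
            power=float(f.attrs["basis_power"]),
        )
        return GroundTruth(
            weights=f["weights"][()],
            tuned=f["tuned"][()].astype(bool),
            noise_sd=float(f.attrs["noise_sd"]),
            motion_gain=float(f.attrs["motion_gain"]),
            motion_coupling=f["motion_coupling"][()],
            basis=basis,
            seed=int(f.attrs["seed"]),
        )


def save_timeseries(runs: list[RunTimeSeries], path) -> None:
    with h5py.File(path, "w") as f:
        for ts in runs:
            g = f.create_group(f"run_{ts.run}")
            g.create_dataset("values", data=ts.values, track_times=False)
            g.attrs["tr"] = ts.tr
            g.attrs["run"] = ts.run
            if ts.motion is not None:
                g.create_dataset("motion", data=ts.motion, track_times=False)


def load_timeseries(path) -> list[RunTimeSeries]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            out.append(
                RunTimeSeries(
                    values=g["values"][()],
                    tr=float(g.attrs["tr"]),
                    run=int(g.attrs["run"]),
                    motion=g["motion"][()] if "motion" in g else None,
                )
            )
    return out


def save_response_matrix(R: ResponseMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=R.values, track_times=False)
        f.create_dataset("runs", data=R.runs, track_times=False)
        f.create_dataset("directions", data=R.directions, track_times=False)
        if R.voxel_index is not None:
            f.create_dataset("voxel_index", data=R.voxel_index, track_times=False)


def load_response_matrix(path) -> ResponseMatrix:
    with h5py.File(path, "r") as f:
        return ResponseMatrix(
            values=f["values"][()],
            runs=f["runs"][()],
            directions=f["directions"][()],
            voxel_index=f["voxel_index"][()] if "voxel_index" in f else None,
        )


def export_nifti(runs: list[RunTimeSeries], path) -> None:
    """Write flattened ROI time series (voxels x 1 x 1 x time) as NIfTI-1.

    Runs are concatenated along time; run boundaries are recoverable from the
    trial table, not the image.
    """
    import nibabel as nib

    data = np.concatenate([ts.values for ts in runs], axis=0)  # time x voxels
    img = nib.Nifti1Image(
        np.ascontiguousarray(data.T[:, None, None, :]), affine=np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, runs[0].tr))
    nib.save(img, str(path))


def load_nifti_dataset(
    bold_path,
    mask_path,
    design: pd.DataFrame,
    motion: dict[int, np.ndarray] | None = None,
    tr: float | None = None,
) -> list[RunTimeSeries]:
    """Ingest a real 4-D BOLD image restricted to an ROI mask.

    The image's time axis is split into runs using the trial table's per-run
    extents (each run's volume count is its last trial offset, rounded to
    TR). Voxels inside the nonzero mask become columns.
    """
    import nibabel as nib

    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 1.0
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError("mask and BOLD image shapes disagree")
    flat = data[mask].T  # time x voxels
    out = []
    offset = 0
    for run in sorted(design["run"].unique()):
        run_df = design[design["run"] == run]
        T = int(round(float((run_df["onset"] + run_df["duration"]).max()) / tr))
        if offset + T > flat.shape[0]:
            raise ValueError("BOLD image has fewer volumes than the trial table implies")
        out.append(
            RunTimeSeries(
                values=flat[offset : offset + T],
                tr=tr,
                run=int(run),
                motion=None if motion is None else motion[int(run)],
            )
        )
        offset += T
    return out
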