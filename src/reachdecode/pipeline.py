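"""Experiment configuration and end-to-end orchestration.

One YAML-serializable :class:`ExperimentConfig` plus a master seed determine
every output byte-for-byte.  The master seed is expanded into per-stage seeds
by a fixed counter scheme so stages can be re-run independently.  Three
entry points mirror the life cycle of an experiment: :func:`cmd_simulate`
writes a synthetic dataset, :func:`cmd_run` executes preprocessing, voxel
selection and the configured decoder under cross-validation, and
:func:`cmd_report` aggregates summaries across repeated experiments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from . import synth
from .circstats import trial_averaged_reconstruction
from .encoder import BasisSet
from .evaluate import (
    CVResult,
    lodo_folds,
    loro_folds,
    run_combined,
    run_encoding_cv,
    run_mvpa,
)
from .preprocess import preprocess_runs

__all__ = ["ExperimentConfig", "cmd_simulate", "cmd_run", "cmd_report"]

log = logging.getLogger("reachdecode")

# Offsets added to the master seed per stage, so that e.g. regenerating the
# dataset does not change the fold-level randomness of the decoder.
_STAGE = {"design": 1, "ground_truth": 2, "motion": 3, "timeseries": 4, "decode": 5}


@dataclass
class ExperimentConfig:
    """All tunable parameters of one synthetic decoding experiment."""

    # design
    runs: int = 6
    reps_per_direction: int = 5
    n_rest: int = 5
    trial_duration: float = 12.0
    lead_in: float = 24.0
    tr: float = 1.0
    # ground truth
    n_voxels: int = 100
    tuned_fraction: float = 0.5
    weight_model: str = "von-mises"
    amplitude: float = 1.0
    kappa: float = 2.0
    noise_sd: float = synth.DEFAULT_NOISE_SD
    motion_gain: float = 0.0
    # time-series generation
    hemodynamic_delay: float = 4.0
    drift_amplitude: float = 0.0
    baseline_level: float = 100.0
    motion_walk_sd: float = 0.02
    motion_task_amplitude: float = 0.1
    # preprocessing
    shift: float = 4.0
    cutoff: float = 0.01
    low_intensity_threshold: float = 0.1
    regress_motion: bool = True
    # voxel selection
    select: bool = True
    selection_reps: int = 10
    sparsity_control: float = 1.0
    # encoder
    k: int = 6
    phase_deg: float = 0.0
    power: float = 1.0
    lambda_grid: list = field(default_factory=lambda: list(np.logspace(-3, 3, 13)))
    n_boot: int = 50
    ridge_eps: str | float = "auto"
    grid_step: float = 1.0
    # evaluation
    scheme: str = "loro"  # loro | lodo
    model: str = "mvpa"  # mvpa | encoding | combined
    mode: str = "classify"  # classify | reconstruct (encoding only)
    from_timeseries: bool = False
    seed: int = 0

    @property
    def basis(self) -> BasisSet:
        return BasisSet(k=self.k, phase_deg=self.phase_deg, power=self.power)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 101 + _STAGE[stage]) % (2**31 - 1)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = [float(v) for v in d["lambda_grid"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def cmd_simulate(config: ExperimentConfig, outdir) -> dict[str, Path]:
    """Write a complete synthetic dataset (trials, ground truth, data files).

    Produces ``trials.csv``, ``ground_truth.h5``, ``motion.csv`` and either
    ``timeseries.h5`` (when ``from_timeseries``) or ``responses.h5``; plus the
    resolved ``config.yaml`` for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = synth.generate_design(
        runs=config.runs,
        reps_per_direction=config.reps_per_direction,
        n_rest=config.n_rest,
        trial_duration=config.trial_duration,
        lead_in=config.lead_in,
        seed=config.stage_seed("design"),
    )
    gt = synth.generate_ground_truth(
        config.n_voxels,
        tuned_fraction=config.tuned_fraction,
        weight_model=config.weight_model,
        amplitude=config.amplitude,
        kappa=config.kappa,
        noise_sd=config.noise_sd,
        motion_gain=config.motion_gain,
        basis=config.basis,
        seed=config.stage_seed("ground_truth"),
    )
    motion = synth.generate_motion(
        design,
        tr=config.tr,
        walk_sd=config.motion_walk_sd,
        task_amplitude=config.motion_task_amplitude,
        seed=config.stage_seed("motion"),
    )
    paths = {
        "config": outdir / "config.yaml",
        "trials": outdir / "trials.csv",
        "ground_truth": outdir / "ground_truth.h5",
        "motion": outdir / "motion.csv",
    }
    config.to_yaml(paths["config"])
    rio.save_design(design, paths["trials"])
    rio.save_ground_truth(gt, paths["ground_truth"])
    rio.save_motion(motion, paths["motion"])
    if config.from_timeseries:
        runs_ts = synth.generate_timeseries(
            design,
            gt,
            tr=config.tr,
            hemodynamic_delay=config.hemodynamic_delay,
            drift_amplitude=config.drift_amplitude,
            baseline_level=config.baseline_level,
            motion=motion,
            seed=config.stage_seed("timeseries"),
        )
        paths["timeseries"] = outdir / "timeseries.h5"
        rio.save_timeseries(runs_ts, paths["timeseries"])
    else:
        R = synth.generate_trial_responses(design, gt)
        paths["responses"] = outdir / "responses.h5"
        rio.save_response_matrix(R, paths["responses"])
    log.info("simulated dataset in %s (%d trials)", outdir, len(design))
    return paths


def _decode(config: ExperimentConfig, R) -> CVResult:
    folds = loro_folds(R) if config.scheme == "loro" else lodo_folds(R)
    common = dict(
        select=config.select,
        selection_reps=config.selection_reps,
        sparsity_control=config.sparsity_control,
        seed=config.stage_seed("decode"),
    )
    if config.model == "mvpa":
        res = run_mvpa(R, folds, **common)
    elif config.model == "encoding":
        res = run_encoding_cv(
            R,
            folds,
            mode=config.mode,
            basis=config.basis,
            lambda_grid=np.asarray(config.lambda_grid, dtype=float),
            n_boot=config.n_boot,
            grid_step=config.grid_step,
            ridge_eps=config.ridge_eps,
            **common,
        )
    elif config.model == "combined":
        res = run_combined(
            R,
            folds,
            basis=config.basis,
            lambda_grid=np.asarray(config.lambda_grid, dtype=float),
            n_boot=config.n_boot,
            ridge_eps=config.ridge_eps,
            **common,
        )
    else:
        raise ValueError(f"unknown model {config.model!r}")
    res.scheme = config.scheme
    return res


def cmd_run(config: ExperimentConfig, dataset_dir, outdir) -> dict:
    """Execute the configured pipeline on a simulated (or ingested) dataset.

    Reads the dataset written by :func:`cmd_simulate`; when it holds raw time
    series, runs the preprocessing chain first. Writes per-fold results
    (``cv_result.csv``), a JSON summary, per-direction circular summaries for
    reconstruction, and a provenance log. Returns the summary dict.
    """
    dataset_dir = Path(dataset_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        trials_path = dataset_dir / "trials.csv"
        if not trials_path.exists():
            raise FileNotFoundError(f"no trial table at {trials_path}")
        design = rio.load_design(trials_path)
        ts_path = dataset_dir / "timeseries.h5"
        if ts_path.exists():
            stage = "preprocess"
            runs_ts = rio.load_timeseries(ts_path)
            R = preprocess_runs(
                runs_ts,
                design,
                shift=config.shift,
                cutoff=config.cutoff,
                low_intensity_threshold=config.low_intensity_threshold,
                regress_motion=config.regress_motion,
            )
            log.info("preprocessed %d runs -> %d trials x %d voxels",
                     len(runs_ts), R.n_trials, R.n_voxels)
        else:
            stage = "load"
            R = rio.load_response_matrix(dataset_dir / "responses.h5")
        stage = "decode"
        res = _decode(config, R)
    except Exception as exc:  # re-raise with the failing stage named
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc

    import pandas as pd

    rows = []
    if res.fold_accuracies is not None:
        for fold, acc in zip(res.folds, res.fold_accuracies):
            rows.append({"fold": fold.name, "model": res.model, "metric": "accuracy",
                         "value": acc})
    summary = {
        "scheme": res.scheme,
        "model": res.model,
        "n_trials": int(R.n_trials),
        "n_voxels": int(R.n_voxels),
        "seed": config.seed,
    }
    if res.fold_accuracies is not None:
        summary["accuracy"] = res.accuracy
        summary["fold_accuracies"] = [float(a) for a in res.fold_accuracies]
    if res.predicted is not None and res.model == "encoding-reconstruct":
        summary["mae_single_trial"] = res.mae
        table, mae_means = trial_averaged_reconstruction(res.predicted, res.actual)
        summary["mae_trial_averaged"] = mae_means
        table.to_csv(outdir / "circular_summary.csv", index=False)
        pd.DataFrame(
            {"predicted": res.predicted, "actual": res.actual, "run": res.runs}
        ).to_csv(outdir / "reconstructed.csv", index=False)
        for fold, row in zip(res.folds, table.itertuples()):
            rows.append({"fold": fold.name, "model": res.model, "metric": "mae",
                         "value": row.mae_single_trial})
    pd.DataFrame(rows).to_csv(outdir / "cv_result.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    config.to_yaml(outdir / "config.yaml")
    if "lambda" in res.extra:
        log.info("selected lambda per fold: %s", res.extra["lambda"])
    log.info("retained voxels per fold: %s", res.extra.get("retained_sizes"))
    log.info("folds: %s", [f.name for f in res.folds])
    log.removeHandler(handler)
    handler.close()
    return summary


def cmd_report(summaries: list[dict] | list, outdir) -> dict:
    """Aggregate summaries of repeated experiments (mean and SD per metric).

    Accepts summary dicts or paths to ``summary.json`` files. Numeric scalar
    metrics shared across inputs are averaged; the report is written as
    ``report.json`` and a tidy ``report.csv``.
    """
    import pandas as pd

    if not summaries:
        raise ValueError("no summaries to report")
    loaded = []
    for s in summaries:
        if isinstance(s, dict):
            loaded.append(s)
        else:
            loaded.append(json.loads(Path(s).read_text()))
    keys = [
        k
        for k in loaded[0]
        if isinstance(loaded[0][k], (int, float)) and not isinstance(loaded[0][k], bool)
        and all(k in s for s in loaded)
    ]
    report = {"n_experiments": len(loaded)}
    rows = []
    for k in keys:
        vals = np.asarray([float(s[k]) for s in loaded])
        report[f"{k}_mean"] = float(vals.mean())
        report[f"{k}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({"metric": k, "mean": report[f"{k}_mean"], "sd": report[f"{k}_sd"]})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame(rows).to_csv(outdir / "report.csv", index=False)
    return report
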