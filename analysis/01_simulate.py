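"""Simulate one synthetic center-out session and summarize its design.

Writes the dataset (trial table, ground truth, motion, responses) under
scratch/dataset and a per-run design summary under results/.
"""

from pathlib import Path

import pandas as pd

from reachdecode import io as rio
from reachdecode.pipeline import ExperimentConfig, cmd_simulate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    config = ExperimentConfig(seed=1)
    paths = cmd_simulate(config, ROOT / "scratch" / "dataset")
    design = rio.load_design(paths["trials"])
    reach = design[design.condition == "reach"]

    summary = (
        reach.groupby("run")
        .agg(reach_trials=("trial_id", "size"), first_onset=("onset", "min"))
        .reset_index()
    )
    summary["rest_trials"] = (
        design[design.condition == "rest"].groupby("run").size().to_numpy()
    )
    summary.to_csv(RESULTS / "design_summary.csv", index=False)

    print(f"dataset written to {paths['trials'].parent}")
    print(f"total reaching trials: {len(reach)} "
          f"({reach.groupby('direction').size().iloc[0]} per direction)")
    print(summary.to_string(index=False))
    print("run length:", float((design.onset + design.duration).max()), "s")


if __name__ == "__main__":
    main()
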