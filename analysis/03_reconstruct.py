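"""Continuous reconstruction of movement direction, known vs unknown targets.

For each synthetic subject the encoding model reconstructs every trial's
direction over a 1-degree grid twice: with the target direction included in
fitting (leave-one-run-out) and with it held out entirely
(leave-one-direction-out). Reports single-trial and trial-averaged MAE, the
per-direction angular variance, and the per-direction circular correlation
between the two reconstructions — the reconstruction summaries and the
per-direction correlation table of the analysis.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import reachdecode as rd
from reachdecode.circstats import (
    circular_correlation,
    trial_averaged_reconstruction,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

N_SUBJECTS = 5


def main() -> None:
    mae_rows, rho_rows = [], []
    for s in range(N_SUBJECTS):
        design = rd.generate_design(seed=s)
        gt = rd.generate_ground_truth(100, seed=100 + s)
        R = rd.generate_trial_responses(design, gt)
        loro = rd.run_encoding_cv(R, rd.loro_folds(R), mode="reconstruct", seed=s)
        lodo = rd.run_encoding_cv(R, rd.lodo_folds(R), mode="reconstruct", seed=s)
        for tag, res in (("known (LORO)", loro), ("unknown (LODO)", lodo)):
            table, mae_avg = trial_averaged_reconstruction(res.predicted, res.actual)
            mae_rows.append({"subject": s, "scheme": tag,
                             "mae_single_trial": res.mae,
                             "mae_trial_averaged": mae_avg,
                             "mean_angular_variance": table.angular_variance.mean()})
            table.insert(0, "scheme", tag)
            table.insert(0, "subject", s)
            table.to_csv(RESULTS / "circular_summary.csv", mode="a",
                         header=(s == 0 and tag.startswith("known")), index=False)
        for d in np.unique(R.directions):
            sel = R.directions == d
            rho_rows.append({"subject": s, "direction": d,
                             "rho": circular_correlation(lodo.predicted[sel],
                                                         loro.predicted[sel])})

    mae = pd.DataFrame(mae_rows)
    mae.to_csv(RESULTS / "reconstruction.csv", index=False)
    rho = pd.DataFrame(rho_rows)
    rho.to_csv(RESULTS / "circular_correlation.csv", index=False)

    print(f"Reconstruction over {N_SUBJECTS} synthetic subjects (1-degree grid):")
    for tag, g in mae.groupby("scheme"):
        print(f"  {tag}: single-trial MAE {g.mae_single_trial.mean():.1f} deg -> "
              f"trial-averaged MAE {g.mae_trial_averaged.mean():.1f} deg "
              f"(mean AV {g.mean_angular_variance.mean():.2f})")
    pivot = rho.pivot(index="direction", columns="subject", values="rho").round(2)
    print("\nPer-direction circular correlation, known vs unknown reconstruction:")
    print(pivot.to_string())
    print(f"median rho: {rho.rho.median():.2f}")


if __name__ == "__main__":
    main()
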