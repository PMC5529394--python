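"""Head-motion control: tuned ROI vs untuned motion-coupled control ROI.

Both synthetic ROIs share one trial design and one head-motion record whose
movement-epoch bumps depend on reach direction — the scenario in which
task-locked motion could masquerade as directional tuning. The identical
time-series pipeline (with and without motion regression) is run on both,
the analogue of contrasting the task-driven motor cortex with the
ipsilateral control region.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import reachdecode as rd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

N_SUBJECTS = 5


def main() -> None:
    rows = []
    for s in range(N_SUBJECTS):
        design = rd.generate_design(seed=s)
        motion = rd.generate_motion(design, seed=500 + s)
        gt_t = rd.generate_ground_truth(80, tuned_fraction=0.5, motion_gain=2.0,
                                        seed=600 + s)
        gt_u = rd.generate_ground_truth(80, tuned_fraction=0.0, motion_gain=2.0,
                                        seed=700 + s)
        for regress in (True, False):
            res_t, res_u = rd.control_roi_experiment(
                design, gt_t, gt_u, motion, regress_motion=regress, seed=s
            )
            rows.append({"subject": s, "motion_regression": regress,
                         "tuned_roi": res_t.accuracy, "untuned_roi": res_u.accuracy})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "motion_control.csv", index=False)

    print(f"LORO accuracy, {N_SUBJECTS} synthetic subjects (chance = 12.5%):")
    for regress, g in table.groupby("motion_regression"):
        label = "with motion regression   " if regress else "without motion regression"
        print(f"  {label}: tuned ROI {100 * g.tuned_roi.mean():5.1f}%  "
              f"untuned control ROI {100 * g.untuned_roi.mean():5.1f}%")
    print("An untuned region decodes at chance once motion is regressed out; "
          "residual task-locked motion alone inflates it only slightly.")


if __name__ == "__main__":
    main()
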