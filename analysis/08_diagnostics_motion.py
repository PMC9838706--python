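#!/usr/bin/env python
"""Model diagnostics and the head-motion control analysis.

Checks the summary mediation regressions for misspecification (RESET)
and heteroscedasticity (White/Wooldridge), then repeats the summary
mediation after regressing the motion summaries (mean FD, high-motion
proportion) out of age, outcome, moderators and every voxel.
"""

import json
from pathlib import Path

import numpy as np

import medvox as mv
from medvox.diagnostics import diagnostic_report
from medvox.simulate import read_cohort, VoxelStack, MOTION_COLUMNS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.tsv")
    stack = VoxelStack.load_nifti(OUT / "stack.nii", OUT / "stack_mask.nii")
    cfg = mv.SimulationConfig.from_yaml(OUT / "config.yaml")
    maps = mv.run_voxelwise(cohort, stack, q=0.05, floor=cfg.missing_floor)

    A, C = cohort["A"].to_numpy(), cohort["C"].to_numpy()
    M = mv.summary_mediator(maps, stack)
    fit = mv.fit_mediation(A, M, C)

    record = {"white": diagnostic_report(fit), "reset": {}}
    for eq, (y, X) in {
        "eq1": (C, np.column_stack([A])),
        "eq2": (C, np.column_stack([M, A])),
        "eq3": (M, np.column_stack([A])),
    }.items():
        F, df, p = mv.reset_test(y, X)
        record["reset"][eq] = {"F": F, "df": list(df), "p": p}

    res_cohort, res_stack = mv.residualize_all(cohort, stack, list(MOTION_COLUMNS))
    M_res = res_stack.summary(maps.summary_mask)
    fit_res = mv.fit_mediation(res_cohort["A"], M_res, res_cohort["C"])
    record["motion_control"] = {
        "mean_fd_mm": float(cohort["motion_mean_fd"].mean()),
        "ab_raw": fit.ab,
        "ab_motion_residualized": fit_res.ab,
        "p_joint_motion_residualized": fit_res.p_joint,
    }
    with open(OUT / "diagnostics.json", "w") as fh:
        json.dump(record, fh, indent=2)
    print(json.dumps(record, indent=2))


if __name__ == "__main__":
    main()
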