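#!/usr/bin/env python
"""ICA-LiNGAM causal direction with the watershed-cluster bootstrap.

Fits the three-variable model (age, summary mediator, outcome) on
standardized data, splits the mediating voxels into watershed clusters
of the ab map, and bootstraps the cluster-mean directionality (subjects
resampled; clusters discarded on sign mismatch with the all-voxel
reference or non-triangularity), reporting BC 95% CIs.
"""

import json
from pathlib import Path

import numpy as np

import medvox as mv
from medvox.simulate import read_cohort, VoxelStack

OUT = Path(__file__).resolve().parents[1] / "results"
N_BOOT = 1000  # desk-scale stand-in for an exhaustive bootstrap


def main() -> None:
    cohort = read_cohort(OUT / "cohort.tsv")
    stack = VoxelStack.load_nifti(OUT / "stack.nii", OUT / "stack_mask.nii")
    cfg = mv.SimulationConfig.from_yaml(OUT / "config.yaml")
    maps = mv.run_voxelwise(cohort, stack, q=0.05, floor=cfg.missing_floor)

    A, C = cohort["A"].to_numpy(), cohort["C"].to_numpy()
    M = mv.summary_mediator(maps, stack)
    ref = mv.lingam_fit(np.column_stack([A, M, C]), ["A", "B", "C"],
                        seed=cfg.seed + 4)

    ab_vol = stack.to_volume(
        np.where(maps.mediation_mask, maps.ab, 0.0), fill=0.0
    )
    med_vol = stack.to_volume(maps.mediation_mask.astype(float), fill=0.0) > 0
    labels3d = mv.watershed_partition(ab_vol, med_vol)
    labels = labels3d[tuple(stack.ijk.T)]

    cb = mv.cluster_bootstrap_direction(
        cohort, stack, labels, ref, n_boot=N_BOOT, seed=cfg.seed + 5,
        n_restarts=2,
    )
    record = {
        "causal_order": [ref.var_names[i] for i in ref.causal_order],
        "triangular": ref.triangular,
        "all_voxel_scores": ref.scores(),
        "n_clusters": int(labels.max()),
        "cluster_mean_scores": cb.mean_scores,
        "bc_ci_95": {k: list(v) for k, v in cb.ci.items()},
        "discard_sign_rate": cb.discard_sign_rate,
        "discard_triangular_rate": cb.discard_triangular_rate,
        "missing_resample_frac": cb.missing_resample_frac,
        "n_boot": N_BOOT,
        "undirected_coefficient_reading": (
            "the nonzero coefficient of each pair, ignoring direction"
        ),
    }
    with open(OUT / "lingam.json", "w") as fh:
        json.dump(record, fh, indent=2)
    print(json.dumps(record, indent=2))


if __name__ == "__main__":
    main()
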