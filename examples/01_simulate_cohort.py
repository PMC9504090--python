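"""Generate a small synthetic study and inspect its ground truth.

The generator emulates a pediatric resting-state + ASL protocol: two
150-frame TR=2 s BOLD runs and one 45-pair pCASL series per subject on a
3 mm grid, plus a covariate table with a planted group -> mediator ->
outcome chain.  Everything is reproducible bit-exactly from the master
seed.
"""

import numpy as np

from pnvf import CohortSpec, simulate_cohort

spec = CohortSpec(n_chd=4, n_control=8, master_seed=7)
cohort = simulate_cohort(spec)

anat = cohort.anatomy
print(f"grid {anat.dims} at {anat.voxel_mm} mm; "
      f"{int((anat.gray > 0.66).sum())} gray-matter voxels")
print("network sizes (voxels):",
      [int(anat.network_mask(k).sum()) for k in range(1, anat.n_networks + 1)])

print("\ncovariate table (first rows):")
print(cohort.table[["subject_id", "group", "age", "gender", "nno",
                    "cognition"]].head().to_string(index=False))

truth = cohort.truth
print("\nplanted within-network correlation targets (first 4 subjects):")
print(np.round(truth.network_r[:4], 3))
print("\ntrue gray-matter CBF: "
      f"{truth.true_cbf[anat.gray > 0.66].mean():.1f} mL/100 g/min mean")
sub = cohort.subjects[0]
run, trace = sub.runs[0]
print(f"\nsubject {sub.subject_id}: BOLD run shape {run.data.shape} "
      f"(TR {run.tr} s), ASL series {sub.asl.n_volumes} volumes "
      f"({sub.asl.n_pairs} control/label pairs)")
# The correlation targets are what FCS estimates downstream; the CHD
# group's network-1 values are lower through the mediator chain.
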