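"""Scrub and filter one BOLD run, then map connectivity strength.

The preprocessing chain is: grand-mean normalization to 1000, framewise
displacement + DVARS, censoring at FD > 0.2 mm or DVARS > 25, nuisance
regression (motion + quadratic drift) on retained frames, band-pass
0.009-0.08 Hz.  FCS is each gray voxel's mean positive-clipped Pearson
correlation with every other gray voxel.
"""

import numpy as np

from pnvf import CohortSpec, PipelineConfig, fcs_map, simulate_cohort, subject_gray_mask
from pnvf.pipeline import preprocess_run

cfg = PipelineConfig()
cohort = simulate_cohort(CohortSpec(n_chd=1, n_control=1, master_seed=3))
anat = cohort.anatomy
run, trace = cohort.subjects[0].runs[0]

clean, censor, fd, dv = preprocess_run(run, trace, anat.brain_mask, cfg)
print(f"frames retained: {censor.n_retained}/{censor.n_frames} "
      f"(FD max {fd.max():.2f} mm, DVARS max {dv.max():.1f})")
print("censored frame indices:", np.where(~censor.keep)[0].tolist())

gray = subject_gray_mask(anat.gray, cfg.gray_threshold, excluded=anat.excluded)
fm = fcs_map(clean, gray)
net1 = anat.network_mask(1) & gray
bg = gray & (anat.networks == 0)
print(f"\nFCS over {int(gray.sum())} gray voxels: "
      f"mean {fm.data[gray].mean():.3f}, range "
      f"[{fm.data[gray].min():.3f}, {fm.data[gray].max():.3f}]")
print(f"mean FCS inside network 1: {fm.data[net1].mean():.3f} vs "
      f"background {fm.data[bg].mean():.3f}")
# Network voxels share a band-limited signal, so their average
# correlation with the rest of gray matter is visibly higher.
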