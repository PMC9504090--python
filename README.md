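# pnvf — an MRI proxy of neurovascular function

`pnvf` implements a resting-state MRI proxy of neurovascular function —
the capability of the vasculature to supply baseline metabolic demand —
for studies comparing clinical groups (here, pediatric and young-adult
congenital heart disease vs normal referents) and relating brain
physiology to covariates such as nitric-oxide availability and
cognitive scores.

The proxy is computed per voxel as

```
Pnvf = − FCS / max(CBF, 20 mL·100 g⁻¹·min⁻¹)
```

where **FCS** (functional connectivity strength) is the average of the
positive-clipped Pearson correlations between a gray-matter voxel's
BOLD time course and all other gray-matter voxel time courses — a proxy
of baseline metabolic/connectivity demand — and **CBF** is absolute
perfusion quantified from a pCASL acquisition through a two-compartment
kinetic model with a slice-dependent post-labeling delay.  Higher
(less negative) Pnvf means the vasculature over-supplies resting
demand; the negative FCS/CBF form is preferred over CBF/FCS because the
noisier quantity (FCS) should sit in the numerator.

Around this core the package provides the complete analysis chain:

- **BOLD preprocessing** — grand-mean normalization to 1000, framewise
  displacement and DVARS, frame censoring at FD > 0.2 mm or DVARS > 25,
  run/subject retention rules (≥ 50 frames per run, ≥ 150 total),
  motion + drift nuisance regression, 0.009–0.08 Hz band-pass with
  interpolation across censored frames.
- **pCASL CBF** — voxelwise GLM for the fractional control−label
  change, forward kinetic model, inversion by bracketed bisection.
- **Pnvf assembly** — per-run maps, run averaging, participant-average
  (≥ 50%) group gray mask, interpolation fill of in-mask holes, and
  voxelwise test–retest reliability.
- **P_ET_CO2 proxy estimators** — the global 0.02–0.04 Hz gray-matter
  signal and a Pnvf-weighted variant with cross-run weighting, their
  per-subject Fisher agreement statistic, and the group test.
- **Voxelwise statistics** — mass-univariate GLMs, t→Z conversion,
  σ = 4 mm smoothing, residual-smoothness estimation, Monte-Carlo
  cluster-extent calibration (125 voxels @ Z > 2.5 at full scale;
  relaxed 200 @ Z > 2.0 for reduced-n analyses), cluster extraction.
- **Mediation** — three-variable mediation with bootstrap (1000
  repetitions) BCa intervals, run voxelwise with the Pnvf map as
  mediator (group → Pnvf → cognition) or outcome (group → nNO → Pnvf).
- **Synthetic cohort generator** — a tissue-probability phantom with
  planted connectivity networks, two 150-frame TR = 2 s BOLD runs and a
  45-pair TR = 4.1 s pCASL series per subject, motion spikes, a
  low-frequency global driver, and a covariate table with a known
  group → mediator → outcome chain, so every estimator can be validated
  against ground truth.

## Worked example

```sh
python examples/02_preprocess_and_fcs.py
```

prints, for one synthetic subject:

```
frames retained: 146/150 (FD max 0.83 mm, DVARS max 51.0)
censored frame indices: [40, 41, 100, 101]

FCS over 1740 gray voxels: mean 0.102, range [0.029, 0.182]
mean FCS inside network 1: 0.129 vs background 0.082
```

The two scheduled motion spikes corrupt two frame pairs, which the
FD/DVARS rules censor; voxels inside the planted network share a
band-limited signal and therefore show visibly higher connectivity
strength than background gray matter.  The remaining examples walk
through CBF quantification (`03`, including the slice-dependent decay
of the labeled bolus and a ~7% gray-matter CBF error over 45 noisy
pairs), Pnvf maps and reliability (`04`), the calibrated group cluster
analysis (`05`), BCa mediation (`06`), and the CO2-estimator agreement
(`07`).

A thin CLI covers the two shell-level entry points:

```sh
pnvf simulate --out sim/ --seed 7          # write a cohort to disk
pnvf run --out results/ --seed 7           # simulate + full analysis
```

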