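# Methods

This note documents the models, parameter choices and numerical
conventions behind `pnvf`, and what the synthetic-data validation does
and does not establish.

## The proxy

Neurovascular function (nvf) is defined as the vasculature's capability
to supply baseline metabolic demand. The package's proxy is

    Pnvf_v = − FCS_v / max(CBF_v, 20)          [−(unitless)/(mL·100 g⁻¹·min⁻¹)]

per gray-matter voxel v. FCS — the mean positive-clipped Pearson
correlation of v's BOLD time course with every other gray-matter voxel
(self excluded, divisor N−1) — stands in for baseline metabolic
("connectivity") demand, which resting BOLD cannot measure absolutely.
CBF is the supply side. The ratio is oriented as −FCS/CBF rather than
CBF/FCS because relative error in a ratio is dominated by the
denominator and FCS is by far the noisier factor. The 20 mL·100 g⁻¹·min⁻¹
perfusion floor (well below normal gray matter) bounds the ratio where
CBF estimates are unreliably low; since FCS ≤ 1, |Pnvf| ≤ 1/20
everywhere. The subject value is the mean of the two per-run maps.

## BOLD preprocessing

Order of operations: grand-mean normalization (target 1000) →
FD/DVARS → censoring → nuisance regression on retained frames →
band-pass. The steps are standard; their fixed order is a package
convention since they are separable only approximately.

- FD is the sum of absolute frame-to-frame differences of the three
  translations plus the three rotations converted to arc length at a
  50 mm head radius; the first frame is 0 by convention.
- DVARS is the RMS over in-brain voxels of the successive-difference
  image, in mode-1000 units (so the threshold 25 is a 2.5% signal
  change). Frames are censored when FD > 0.2 mm **or** DVARS > 25,
  boundary values retained (strict inequality). Runs keep ≥ 50 retained
  frames or are discarded; subjects keep ≥ 150 frames across both runs
  or are excluded (discarded runs do not contribute frames).
- Nuisance regressors are the six motion parameters plus Legendre
  polynomials of order 0–2 per run ("drift"); no global-signal
  regressor is included. Coefficients are fit on retained frames only;
  residuals are formed for all frames so that interpolation acts on
  residualized data. Rank deficiency is reported with the names of the
  collinear columns.
- Band-pass 0.009–0.08 Hz is a zero-phase brick-wall spectral filter
  (DC always removed, band edges inclusive). Censored frames are
  linearly interpolated before filtering and re-dropped afterwards —
  the standard remedy for censoring-induced spectral leakage. A
  brick-wall filter keeps the band limit exact for bin-aligned
  components, which also makes the effective-degrees-of-freedom
  accounting below exact.

Note that any OLS regression removes the signal's projection onto its
design — of order sqrt(p/n) ≈ 0.25 of the norm of a generic signal at
p = 9, n = 150. "Nuisance-free" signal preservation therefore holds in
the orthogonal-complement sense, which is how the suite tests it.

## FCS

Time courses on retained frames are standardized once; correlations are
computed in row blocks (default 2048 rows) of the standardized matrix,
clipped at zero per block, and accumulated — the N×N matrix is never
materialized, so ~5·10⁴-voxel masks are handled in O(N·block) memory.
Blocked and brute-force results agree to 1e-10 (an acceptance check at
500 voxels × 150 frames). Zero-variance voxels are flagged; their
correlations are defined as 0. The subject gray mask is probability
> 0.66 (strict, configurable) minus excluded-region labels.

## pCASL kinetic model and CBF

The forward model tracks label created at the tagging plane during
u ∈ [0, τ] (τ = 1500 ms) through an arterial phase (arrival δa, blood
T1) and a tissue phase (arrival δt, tissue T1), read out at
t = τ + w_s, with the slice-dependent post-labeling delay
w_s = 1200 ms + 40 ms × slice (2-D ascending readout; at the 10th slice
w ≈ 1600 ms). Both phase integrals are closed-form exponentials and the
prediction is linear in flow, zero at zero flow, and strictly
increasing — the exact expression is documented in `pnvf/asl.py` and
anchored by the forward/inverse round trip rather than by any single
literature parameterization. Kinetic defaults (α = 0.85, λ = 0.9 mL/g,
T1 blood 1650 ms, T1 gray 1330 ms, transit times 800/1200 ms) are
configurable literature-style values.

The fractional change (control−label)/control is estimated per voxel by
a GLM with control level and label contrast as effects of interest plus
optional nuisance columns; a non-positive control estimate flags the
voxel invalid. Quantification inverts the forward model by bisection
bracketed on [0, 300] mL·100 g⁻¹·min⁻¹ (60 iterations, far below the
1e-4 relative round-trip tolerance); negative fractional changes clamp
to zero flow and out-of-range ones to the upper bracket, both flagged.
Bisection is kept although the default model is linear so that any
monotone kinetic variant can be swapped in.

## Group assembly

The group gray mask averages subject gray-probability volumes and keeps
voxels with mean ≥ 0.5 (inclusive, vs the strict subject-level > 0.66 —
both mirror their respective conventions and are configurable). In-mask
voxels missing from a subject map are filled by iterated local
interpolation over the 26-neighbor stencil (exact for locally linear
fields; equivalent to trilinear interpolation for single-voxel holes);
voxels unreachable by iteration take the nearest defined value. Filled
voxels are flagged; defined voxels are bit-unchanged.

Test–retest reliability is the across-subject Pearson correlation of
run-1 vs run-2 Pnvf at each voxel, summarized by the mask mean and the
fraction of voxels above r = 0.7.

## P_ET_CO2 proxy estimators

Both estimators band-pass to 0.02–0.04 Hz, the band that tracks
measured end-tidal CO2. The global estimator averages the gray-matter
signal; the weighted estimator uses zero-meaned Pnvf values as spatial
weights, normalized by Σ|w| (scale-irrelevant for correlations), with
the stringent cross-run scheme: run 1 weighted by run-2 Pnvf and vice
versa, results averaged. A spatially constant Pnvf map is a signaled
error (zero weights), not a silent zero.

Per-subject agreement is Pearson r over common retained frames. Because
the narrow band leaves few independent samples, the Fisher statistic is
scaled by an effective frame count: for a filter with power transfer
|H|², Bartlett's variance inflation gives n_eff = (Σ|H|²)²/Σ|H|⁴ over
the two-sided spectrum — for the brick-wall filter, simply the number
of retained Fourier bins (14 for 150 frames at TR 2 s). The package
reports z = atanh(r)·√(n_eff−3) (and raw atanh(r) alongside): a
z-statistic, which is the only reading under which group-level values
of order 10 are possible for |r| < 1. r = ±1 caps atanh at 18 and is
flagged. The group test is a one-sample t of per-subject z against 0 —
calibrated under the null regardless of the n_eff approximation, since
the null z-distribution is symmetric about zero.

One emergent property of the synthetic model worth knowing: a shared
driver inflates FCS most where its coupling is strongest, so the
measured Pnvf deviation pattern can anti-align with a planted
gain-deviation pattern and flip the weighted estimator's sign. Validity
tests therefore assert on |r| (the null hypothesis being zero
correlation); the monotone growth of |group z| with coupling gain is
tested at the time-series level where the sign is controlled.

## Voxelwise GLMs and cluster inference

Per-voxel OLS with the contrast t-statistic; df = n − rank −
df_reduction, where the reduction accounts for non-independent rows
(repeat scans; e.g. 88 rows, 4 columns, reduction 3 → df 81). t → Z is
the probability-preserving transform Φ⁻¹(F_t(t)), evaluated through the
survival function on the matching tail so it is finite and monotone out
to |t| ≈ 80; perfect fits report a capped |t|. Z maps are smoothed with
a mask-normalized σ = 4 mm Gaussian (no bleed across the mask edge; a
constant field is a fixed point; kernel SD = 4/3 voxel at 3 mm).

Cluster calibration simulates stationary Gaussian null fields: white
noise, convolved to the target smoothness (intrinsic FWHM estimated
from residuals, combined in quadrature with the exogenous σ = 4 mm
kernel), re-standardized within the mask, thresholded (strict >), and
26-connectivity components measured (6/18/26 configurable — the
"contiguous voxels" rule does not define contiguity). The empirical
probability that a null map contains any cluster ≥ k voxels is the
cluster-level false-positive bound of the rule "k voxels at Z > z";
under the global null this familywise rate coincides with cluster-level
FDR, which is how a rule like 125 @ Z > 2.5 maps to q < 0.05. The
stationary simulation approximates per-voxel residual-autocorrelation
noise maps; this is a documented approximation.

Residual smoothness is estimated per axis from the lag-1 spatial
autocorrelation ρ of standardized residuals via the Gaussian-kernel
model ρ = exp(−1/(4σ²)) (σ in voxels), FWHM = 2.3548σ. When ρ falls at
or below the value a one-voxel-FWHM field would produce, the estimator
reports the one-voxel resolution floor — white residuals report
FWHM = voxel size, and a field smoothed at σ = 4 mm is recovered within
a few percent.

## Mediation

Paths a (X→M) and b (M→Y adjusted for X) are OLS with covariates (age
and gender in the study analyses) in both regressions; the indirect
effect is a·b, and c = c′ + a·b holds exactly for OLS with shared
covariates. Inference: subjects resampled as whole rows (map value and
covariates jointly) with replacement, default 1000 repetitions; BCa
intervals with bias correction z₀ from the fraction of bootstrap
estimates below the point estimate (clamped to [1/(B+1), B/(B+1)]) and
acceleration from jackknife skewness. The two-sided p is the smallest
level at which the BCa interval excludes zero, found on a 0.001 grid
(closed under the monotonicity of the adjusted endpoints) and floored
at 2/B; the bootstrap tail-mass p is exposed as an option. The signed
map statistic is z = sign(ab)·Φ⁻¹(1−p/2); p = 1 maps to z = 0. The
p-floor caps attainable |z| at Φ⁻¹(1−1/B) — a real power constraint at
voxel-level thresholds, which is why reduced-power analyses use the
relaxed cluster rule.

Voxelwise mediation shares one bootstrap index matrix across voxels and
is vectorized through Frisch–Waugh partialling; it is bit-identical to
running the scalar routine per voxel with the same matrix (tested). The
z map is smoothed and thresholded exactly like the correlational maps.

## The synthetic cohort

Anatomy is an ellipsoidal phantom (default 24×24×18 voxels at 3 mm):
white core, gray shell, CSF rim, with disjoint spherical "networks"
(default 3, radius 4.5 voxels, centers ≥ 10 voxels apart) inside deep
gray matter and a small inferior excluded region standing in for
template-based cerebellum removal.

A BOLD voxel's signal is baseline × (1 + g_v·c(t) + w_k·η_k(t) +
u·ξ_v(t) + ε): η_k a shared band-limited (0.01–0.08 Hz) network course,
ξ_v a voxel-specific one, c(t) a 0.02–0.04 Hz global driver standing in
for end-tidal CO2, ε thermal noise. With shared weight
w = u·√(r/(1−r)), two same-network voxels have population correlation r
at zero thermal noise. Motion enters twice — a six-parameter trace
(slow random walk plus scheduled single-frame spikes, driving FD) and a
multiplicative intensity disturbance on spike frames (driving DVARS) —
so both censoring criteria can be validated independently.

Generator defaults define the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 24 CHD / 64 control | demographic table of the emulated study |
| run length / TR | 150 frames / 2.0 s | acquisition protocol |
| ASL | 45 pairs, TR 4.1 s | acquisition protocol |
| ages | uniform 6–25 y | recruitment span |
| repeat-scan flags | 3 subjects | emulated study |
| idiosyncratic BOLD amplitude u | 1% | typical resting-state fluctuation |
| thermal noise | 0.5% | 3 T EPI at this voxel size |
| global-driver gain | 0.2% mean | modest physiological global signal |
| baseline network correlation | 0.72 | strong within-network coupling |
| CHD effect on network-1 r | −0.03 direct − 0.5·mediator | planted effect; total ≈ −0.53 through the chain |
| mediator model | m = −group + N(0, 0.35) | ~3 SD group separation |
| outcome model | y = m + N(0, 0.25) | cognition carried by the mediator |
| mediator→CBF coupling | −12%/unit in network 1 | NO-dependent vascular tone channel |
| gray / white CBF | 60 / 20 mL·100 g⁻¹·min⁻¹ | textbook perfusion values |
| ASL intensity noise | σ = 1.2 (M0 = 1000) | yields ~7% gray-matter CBF error, matching reported pCASL repeatability |
| motion spikes | 0.5 / 0.8 mm at frames 40 / 100 | exercises both censoring rules |

The planted effect sizes are deliberately large for a desk-scale study:
detection power that the real study achieved with ~45k voxels and 88
subjects must be reproduced here with ~2×10³ mask voxels and 32
subjects, and the mediation chain feeds Pnvf through both connectivity
and perfusion so the per-voxel b-path survives voxel-level noise.
Covariates are reported both on standardized scales (used by the
ground-truth bookkeeping) and in natural units (an nNO-like column in
nL/min, a cognition-like composite at mean ~110/SD 15).

What the generator does **not** emulate: real head anatomy, EPI/k-space
artifacts, registration error, slice timing, spatially structured
physiological noise, non-Gaussian motion, or any nonlinearity between
neural coupling and BOLD. Passing tests therefore demonstrate that the
estimators recover what they claim from data obeying the stated signal
model at protocol-matched dimensions — not that the pipeline is robust
to every artifact of real MRI data.

## Problem sizes used by the validation suite

The suite runs the full study end-to-end on 20 replicate cohorts of
16 + 16 subjects on the 24×24×18 grid, with 2000 bootstrap repetitions
for voxelwise mediation and 200 calibration simulations per threshold —
sizes chosen so a complete validation runs on a laptop in minutes.
Cluster-rule calibration at full scale (the 45,000-voxel mask) uses
200–300 simulations. The group analysis uses the 2.5/calibrated-extent
rule; voxelwise mediation uses the relaxed 2.0 threshold with its own
calibrated extent, mirroring the reduced-power convention, because the
bootstrap p-floor caps voxel |z| near 3. Null calibrations (CO2
agreement, BCa coverage) use 200 Monte-Carlo cohorts/datasets with
two-MC-SD tolerance bands.

## Known limitations

- The stationary-Gaussian null for cluster calibration ignores
  nonstationary smoothness; real data would warrant per-voxel noise
  maps.
- n_eff for the Fisher statistic assumes white pre-filter spectra.
- The brick-wall filter rings for broadband transients; with the
  scrubbing rules applied first this is benign, but heavy censoring
  plus filtering will distort edges of long gaps.
- BCa p-values inherit bootstrap granularity (floor 2/B); voxelwise
  inference at stringent thresholds needs B ≥ 2000.
- The trilinear fill is exact only for locally linear fields; large
  holes are filled by iterated local averaging, which is smoother than
  true trilinear interpolation.
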