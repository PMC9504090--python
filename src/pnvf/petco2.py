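"""End-tidal CO2 proxy estimators from resting BOLD and their agreement.

Two estimators of the P_ET_CO2-driven BOLD fluctuation are built per
run: the global estimator (mean gray-matter signal band-passed to
0.02-0.04 Hz, the band that tracks measured P_ET_CO2) and a
Pnvf-weighted estimator (zero-meaned Pnvf values weight the voxel time
courses before the same filtering).  Cross-run stringency: run 1 is
weighted by the Pnvf map computed from run 2 and vice versa, and the two
agreements are averaged.

Agreement is summarized per subject by a Fisher statistic
z = atanh(r) * sqrt(n_eff - 3), where n_eff is an effective frame count
discounting the autocorrelation the narrow passband induces; the raw
atanh(r) is reported alongside.  The group-level test is a one-sample t
of the per-subject z against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .preproc import BoldRun, bandpass_timecourses, effective_frames


class Petco2Error(ValueError):
    pass


class DegenerateWeightsError(Petco2Error):
    """Raised when spatially constant Pnvf yields all-zero weights."""


ATANH_CAP = 18.0  # |atanh(r)| cap for |r| -> 1 (flagged)


@dataclass
class Co2Estimate:
    timecourse: np.ndarray  # full-length, band-limited
    keep: np.ndarray  # retained-frame mask
    passband: tuple
    tr: float
    source_run: int
    weighting: str  # 'uniform' | 'pnvf'
    cross_run: bool = False


@dataclass
class AgreementResult:
    r: float
    fisher_z: float
    atanh_r: float
    n_eff: float
    capped: bool


def global_estimator(
    run: BoldRun, gray_mask: np.ndarray, f_lo: float = 0.02, f_hi: float = 0.04
) -> Co2Estimate:
    """Unweighted gray-matter mean per frame, band-passed 0.02-0.04 Hz."""
    gray_mask = np.asarray(gray_mask, dtype=bool)
    if not gray_mask.any():
        raise Petco2Error("empty gray mask")
    keep = run.keep if run.keep is not None else np.ones(run.n_frames, dtype=bool)
    mean_tc = run.data[gray_mask].mean(axis=0)
    filtered = bandpass_timecourses(mean_tc[None, :], run.tr, f_lo, f_hi, keep=keep)[0]
    return Co2Estimate(timecourse=filtered, keep=keep.copy(), passband=(f_lo, f_hi),
                       tr=run.tr, source_run=run.run_index, weighting="uniform")


def weighted_estimator(
    run: BoldRun,
    pnvf_volume: np.ndarray,
    gray_mask: np.ndarray,
    f_lo: float = 0.02,
    f_hi: float = 0.04,
) -> Co2Estimate:
    """Pnvf-weighted average of voxel time courses, band-passed.

    Weights are the zero-meaned Pnvf values over the gray mask,
    normalized by sum |w| so the estimator scale is comparable across
    subjects (scale does not affect correlations).  A spatially constant
    Pnvf map gives all-zero weights and is signaled, not silently zeroed.
    """
    gray_mask = np.asarray(gray_mask, dtype=bool)
    if not gray_mask.any():
        raise Petco2Error("empty gray mask")
    w = np.asarray(pnvf_volume, dtype=float)[gray_mask]
    w = w - w.mean()
    denom = np.abs(w).sum()
    if denom == 0:
        raise DegenerateWeightsError("spatially constant Pnvf yields zero weights")
    keep = run.keep if run.keep is not None else np.ones(run.n_frames, dtype=bool)
    tc = (w @ run.data[gray_mask]) / denom
    filtered = bandpass_timecourses(tc[None, :], run.tr, f_lo, f_hi, keep=keep)[0]
    return Co2Estimate(timecourse=filtered, keep=keep.copy(), passband=(f_lo, f_hi),
                       tr=run.tr, source_run=run.run_index, weighting="pnvf",
                       cross_run=True)


def estimator_agreement(est_a: Co2Estimate, est_b: Co2Estimate,
                        min_frames: int = 10) -> AgreementResult:
    """Pearson correlation over common retained frames with the Fisher
    statistic z = atanh(r) * sqrt(n_eff - 3)."""
    if est_a.timecourse.size != est_b.timecourse.size:
        raise Petco2Error("estimator lengths differ")
    common = est_a.keep & est_b.keep
    n_common = int(common.sum())
    if n_common < min_frames:
        raise Petco2Error(f"only {n_common} common retained frames (< {min_frames})")
    a = est_a.timecourse[common]
    b = est_b.timecourse[common]
    if a.std() == 0 or b.std() == 0:
        raise Petco2Error("zero-variance estimator time course")
    r = float(np.corrcoef(a, b)[0, 1])
    f_lo = min(est_a.passband[0], est_b.passband[0])
    f_hi = max(est_a.passband[1], est_b.passband[1])
    n_eff = effective_frames(est_a.timecourse.size, est_a.tr, f_lo, f_hi)
    n_eff = min(n_eff, float(n_common))
    capped = abs(r) >= 1.0 - 1e-12
    atanh_r = float(np.clip(np.arctanh(np.clip(r, -1 + 1e-16, 1 - 1e-16)),
                            -ATANH_CAP, ATANH_CAP))
    fisher = atanh_r * np.sqrt(max(n_eff - 3.0, 1.0))
    return AgreementResult(r=r, fisher_z=float(fisher), atanh_r=atanh_r,
                           n_eff=n_eff, capped=capped)


def cross_run_agreement(
    run1: BoldRun,
    run2: BoldRun,
    pnvf_run1: np.ndarray,
    pnvf_run2: np.ndarray,
    gray_mask: np.ndarray,
    f_lo: float = 0.02,
    f_hi: float = 0.04,
) -> AgreementResult:
    """The study's stringent cross-run scheme: weighted estimator for run
    i uses Pnvf from run j != i; results from the two pairings are
    averaged."""
    results = []
    for run, pnvf_other in ((run1, pnvf_run2), (run2, pnvf_run1)):
        glob = global_estimator(run, gray_mask, f_lo, f_hi)
        wtd = weighted_estimator(run, pnvf_other, gray_mask, f_lo, f_hi)
        results.append(estimator_agreement(glob, wtd))
    r = float(np.mean([res.r for res in results]))
    return AgreementResult(
        r=r,
        fisher_z=float(np.mean([res.fisher_z for res in results])),
        atanh_r=float(np.mean([res.atanh_r for res in results])),
        n_eff=float(np.mean([res.n_eff for res in results])),
        capped=any(res.capped for res in results),
    )


@dataclass
class GroupTestResult:
    mean: float
    sem: float
    p: float
    t: float
    n: int


def group_test(fisher_zs) -> GroupTestResult:
    """One-sample t-test of the per-subject Fisher statistics against 0."""
    z = np.asarray(fisher_zs, dtype=float)
    if z.size < 3:
        raise Petco2Error("group test needs at least 3 subjects")
    if np.allclose(z, 0.0):
        return GroupTestResult(mean=0.0, sem=float(z.std(ddof=1) / np.sqrt(z.size)),
                               p=1.0, t=0.0, n=z.size)
    t, p = sps.ttest_1samp(z, 0.0)
    return GroupTestResult(mean=float(z.mean()),
                           sem=float(z.std(ddof=1) / np.sqrt(z.size)),
                           p=float(p), t=float(t), n=z.size)
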