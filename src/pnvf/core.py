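"""The neurovascular-function proxy map (Pnvf) and its reliability.

Pnvf is computed per voxel as the negative of the ratio of functional
connectivity strength to cerebral blood flow, with a perfusion floor of
20 mL/100 g/min for robustness.  The final subject map is the mean over
the two BOLD runs; group analyses run on a participant-average gray
mask, with in-mask holes filled by local interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class PnvfError(ValueError):
    pass


@dataclass
class PnvfMap:
    """Pnvf values (units: -1 / (mL/100 g/min), FCS being unitless).

    ``filled`` flags voxels populated by interpolation rather than
    measurement; ``runs`` records which run indices were averaged."""

    data: np.ndarray
    mask: np.ndarray
    runs: tuple = (0,)
    filled: np.ndarray | None = None


def pnvf_map(fcs: np.ndarray, cbf: np.ndarray, mask: np.ndarray | None = None,
             cbf_floor: float = 20.0, run_index: int = 0) -> PnvfMap:
    """Pnvf_v = -FCS_v / max(CBF_v, floor); floor default 20 mL/100 g/min."""
    fcs = np.asarray(fcs, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if fcs.shape != cbf.shape:
        raise PnvfError(f"misaligned grids: FCS {fcs.shape} vs CBF {cbf.shape}")
    if mask is None:
        mask = np.ones(fcs.shape, dtype=bool)
    data = np.zeros(fcs.shape)
    data[mask] = -fcs[mask] / np.maximum(cbf[mask], cbf_floor)
    return PnvfMap(data=data, mask=np.asarray(mask, dtype=bool), runs=(run_index,))


def average_runs(*maps: PnvfMap) -> PnvfMap:
    """Voxelwise mean over the per-run maps (a single map passes through)."""
    maps = [m for m in maps if m is not None]
    if not maps:
        raise PnvfError("no valid run maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.data.shape != first.data.shape:
            raise PnvfError("run maps must share the common grid")
    data = np.mean([m.data for m in maps], axis=0)
    runs = tuple(r for m in maps for r in m.runs)
    return PnvfMap(data=data, mask=first.mask, runs=runs)


def group_gray_mask(gray_probs: list, threshold: float = 0.5) -> np.ndarray:
    """Participant-wide average gray probability >= threshold (inclusive)."""
    if len(gray_probs) < 2:
        raise PnvfError("group mask needs at least 2 subjects")
    mean = np.mean([np.asarray(g, dtype=float) for g in gray_probs], axis=0)
    mask = mean >= threshold
    if not mask.any():
        raise PnvfError("group gray mask is empty")
    return mask


def fill_missing(map_: PnvfMap, group_mask: np.ndarray) -> PnvfMap:
    """Fill in-mask voxels missing from the subject map by local
    interpolation over the 26-neighborhood stencil, iterated until all
    reachable holes are filled; unreachable voxels take the nearest
    defined value.  Defined voxels are left bit-unchanged; all filled
    voxels are flagged.

    The symmetric stencil reproduces trilinear interpolation exactly for
    locally linear fields (a single hole surrounded by defined
    neighbors recovers the linear interpolant).
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    defined = map_.mask & group_mask
    if not defined.any():
        raise PnvfError("subject map is entirely missing within the group mask")
    data = map_.data.copy()
    missing = group_mask & ~defined
    filled_flag = missing.copy()
    have = defined.copy()
    stencil = np.ones((3, 3, 3))
    while missing.any():
        vals = np.where(have, data, 0.0)
        s = ndimage.correlate(vals, stencil, mode="constant")
        c = ndimage.correlate(have.astype(float), stencil, mode="constant")
        # correlate with the full 3x3x3 kernel includes the center; defined
        # centers are excluded because missing voxels have no value yet
        reachable = missing & (c > 0)
        if not reachable.any():
            # isolated voxels: nearest defined value
            _, idx = ndimage.distance_transform_edt(~have, return_indices=True)
            data[missing] = data[tuple(i[missing] for i in idx)]
            break
        data[reachable] = s[reachable] / c[reachable]
        have |= reachable
        missing &= ~reachable
    return PnvfMap(data=data, mask=group_mask, runs=map_.runs, filled=filled_flag)


@dataclass
class RetestSummary:
    mean_r: float
    frac_above: float
    threshold: float
    n_subjects: int


def test_retest_map(run1_maps: np.ndarray, run2_maps: np.ndarray,
                    mask: np.ndarray | None = None,
                    r_threshold: float = 0.7) -> tuple:
    """Voxelwise across-subject Pearson correlation between run-1 and
    run-2 values.

    ``run1_maps``/``run2_maps`` are (n_subjects, ...) stacks.  Returns
    (r volume, RetestSummary) with the mean r over the mask and the
    fraction of voxels with r > ``r_threshold``.
    """
    a = np.asarray(run1_maps, dtype=float)
    b = np.asarray(run2_maps, dtype=float)
    if a.shape != b.shape:
        raise PnvfError("run stacks must have identical shape")
    n = a.shape[0]
    if n < 3:
        raise PnvfError("test-retest needs at least 3 subjects with both runs")
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    num = (am * bm).sum(axis=0)
    den = np.sqrt((am**2).sum(axis=0) * (bm**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    if mask is None:
        mask = np.ones(r.shape, dtype=bool)
    vals = r[np.asarray(mask, dtype=bool)]
    summary = RetestSummary(
        mean_r=float(vals.mean()),
        frac_above=float((vals > r_threshold).mean()),
        threshold=r_threshold,
        n_subjects=n,
    )
    return r, summary
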