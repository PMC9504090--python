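"""Functional connectivity strength (FCS).

FCS for a gray-matter voxel is the average of the Pearson correlations
between its time course and the time courses of all other gray-matter
voxels, with negative correlations set to zero.  The N x N correlation
matrix is never materialized: standardized time courses are processed in
row blocks with clipping applied per block, which matches brute-force
pairwise computation to floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import BoldRun


class FcsError(ValueError):
    pass


@dataclass
class FcsMap:
    """Per-voxel connectivity strength in [0, 1] on the mask."""

    data: np.ndarray  # 3-D volume, zero off-mask
    mask: np.ndarray
    run_index: int
    zero_variance: np.ndarray  # flagged voxels whose correlations were defined as 0


def subject_gray_mask(
    gray_prob: np.ndarray,
    threshold: float = 0.66,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Gray-matter voxels: probability strictly greater than ``threshold``
    (default 0.66), minus any excluded-region labels."""
    gray_prob = np.asarray(gray_prob, dtype=float)
    if gray_prob.min() < 0 or gray_prob.max() > 1:
        raise FcsError("gray probabilities must lie in [0, 1]")
    mask = gray_prob > threshold
    if excluded is not None:
        mask &= np.asarray(excluded) == 0
    if not mask.any():
        raise FcsError("gray-matter mask is empty")
    return mask


def fcs_map(run: BoldRun, mask: np.ndarray, block_size: int = 2048) -> FcsMap:
    """Blocked FCS over retained frames.

    FCS_v = (1/(N-1)) * sum_{u != v} max(0, r_vu).  Zero-variance voxels
    are flagged; their correlations are defined as 0.
    """
    mask = np.asarray(mask, dtype=bool)
    N = int(mask.sum())
    if N < 2:
        raise FcsError("need at least 2 mask voxels")
    keep = run.keep if run.keep is not None else np.ones(run.n_frames, dtype=bool)
    T = int(keep.sum())
    if T < 3:
        raise FcsError(f"need at least 3 retained frames, have {T}")

    ts = run.data[mask][:, keep]  # (N, T)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    zero_var = norms == 0
    safe = np.where(zero_var, 1.0, norms)
    Z = ts / safe[:, None]
    Z[zero_var] = 0.0

    sums = np.empty(N)
    for start in range(0, N, block_size):
        stop = min(start + block_size, N)
        block = Z[start:stop] @ Z.T  # (b, N)
        np.clip(block, 0.0, None, out=block)
        # remove self-correlation (1 for normal voxels, 0 for zero-variance)
        block[np.arange(stop - start), np.arange(start, stop)] = 0.0
        sums[start:stop] = block.sum(axis=1)

    vals = sums / (N - 1)
    out = np.zeros(mask.shape)
    out[mask] = vals
    zv = np.zeros(mask.shape, dtype=bool)
    zv[mask] = zero_var
    return FcsMap(data=out, mask=mask, run_index=run.run_index, zero_variance=zv)


def fcs_per_run(runs: list, mask: np.ndarray, block_size: int = 2048) -> list:
    """One FCS map per valid run; no cross-run pooling."""
    if not runs:
        raise FcsError("no valid runs")
    return [fcs_map(run, mask, block_size=block_size) for run in runs]
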