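"""Mass-univariate GLMs over subject maps and cluster-extent inference.

T maps are converted to Z by the probability-preserving transform,
Gaussian-smoothed within the analysis mask (sigma = 4 mm by default),
and thresholded into connected clusters.  The cluster-extent threshold
is calibrated by Monte-Carlo simulation of stationary Gaussian null
fields at the smoothness estimated from the model residuals — under the
global null, the probability that a null map contains any suprathreshold
cluster of at least the chosen extent bounds the cluster-level
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sps


class StatsError(ValueError):
    pass


FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))  # 2.3548


# ---------------------------------------------------------------------------
# voxelwise GLM


@dataclass
class GlmResult:
    t: np.ndarray  # 3-D t volume (zero off-mask)
    residuals: np.ndarray  # (n_subjects,) + grid, zero off-mask
    df: int
    beta: np.ndarray  # contrast effect estimate per voxel
    mask: np.ndarray


def voxel_glm(
    maps: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    mask: np.ndarray,
    df_reduction: int = 0,
) -> GlmResult:
    """Ordinary-least-squares fit per voxel with a t statistic for the
    contrast; df = n - rank(design) - df_reduction.

    ``maps`` is (n_subjects,) + grid; ``design`` (n_subjects, p) should
    include its own intercept column.  A df reduction accounts for
    non-independent rows (repeat scans).
    """
    maps = np.asarray(maps, dtype=float)
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, p = X.shape
    if maps.shape[0] != n:
        raise StatsError("one map per design row required")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise StatsError("design matrix is rank-deficient")
    df = n - rank - int(df_reduction)
    if df <= 0:
        raise StatsError(f"non-positive degrees of freedom ({df})")

    Y = maps.reshape(n, -1)[:, mask.ravel()]  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var_c = float(c @ xtx_inv @ c)
    eff = c @ beta
    cap = 1e6  # perfect fits report a capped |t|
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sigma2 > 0, eff / np.sqrt(sigma2 * var_c), np.sign(eff) * cap)
    t = np.clip(t, -cap, cap)

    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t
    res_vol = np.zeros((n,) + mask.shape)
    res_vol[:, mask] = resid
    beta_vol = np.zeros(mask.shape)
    beta_vol[mask] = eff
    return GlmResult(t=t_vol, residuals=res_vol, df=df, beta=beta_vol, mask=mask)


def t_to_z(t_map: np.ndarray, df: int) -> np.ndarray:
    """Probability-preserving, sign-preserving t -> Z conversion with
    tail-safe evaluation: z = Phi^-1(F_t(t; df)) computed through the
    survival function on the matching tail."""
    if df < 1:
        raise StatsError("df must be >= 1")
    t = np.asarray(t_map, dtype=float)
    pos = t >= 0
    z = np.empty_like(t)
    # work on the upper tail for positive t, lower for negative
    sf = sps.t.sf(np.abs(t), df)
    z_mag = sps.norm.isf(sf)
    z_mag = np.where(np.isfinite(z_mag), z_mag, 40.0)
    z[pos] = z_mag[pos]
    z[~pos] = -z_mag[~pos]
    return z


# ---------------------------------------------------------------------------
# smoothing and smoothness


def smooth_z(z_map: np.ndarray, sigma_mm: float, mask: np.ndarray,
             voxel_mm: float = 3.0) -> np.ndarray:
    """Mask-normalized 3-D Gaussian smoothing (no bleed from outside the
    mask; a constant field maps to itself)."""
    if sigma_mm <= 0:
        raise StatsError("sigma must be positive")
    mask = np.asarray(mask, dtype=bool)
    sigma_vox = sigma_mm / voxel_mm
    num = ndimage.gaussian_filter(np.where(mask, z_map, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.zeros(z_map.shape)
    good = mask & (den > 0)
    out[good] = num[good] / den[good]
    return out


def estimate_smoothness(residual_maps: np.ndarray, mask: np.ndarray,
                        voxel_mm: float = 3.0) -> np.ndarray:
    """Per-axis spatial smoothness (FWHM, mm) of standardized residuals.

    The lag-1 spatial autocorrelation rho along each axis is inverted
    under a Gaussian autocorrelation model (white noise convolved with a
    Gaussian kernel of sd sigma gives rho = exp(-1/(4 sigma^2)) at one
    voxel lag), FWHM = 2.3548 sigma.  Fields whose rho falls at or below
    the value a one-voxel-FWHM field would produce report the one-voxel
    resolution floor.
    """
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[0] < 1:
        raise StatsError("need residual maps")
    mask = np.asarray(mask, dtype=bool)
    fwhm = np.empty(3)
    rho_floor = np.exp(-FWHM_PER_SIGMA**2 / 4.0)  # rho of a 1-voxel-FWHM field
    for axis in range(3):
        nums, dens = [], []
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if not pair_mask.any():
            raise StatsError("mask too thin to estimate smoothness")
        for m in maps:
            vals = m[mask]
            sd = vals.std()
            if sd == 0:
                raise StatsError("degenerate (constant) residual map")
            z = (m - vals.mean()) / sd
            a = z[tuple(sl_a)][pair_mask]
            b = z[tuple(sl_b)][pair_mask]
            nums.append(float((a * b).sum()))
            dens.append(float(np.sqrt((a**2).sum() * (b**2).sum())))
        rho = sum(nums) / max(sum(dens), 1e-300)
        if rho <= rho_floor:
            fwhm[axis] = voxel_mm
        else:
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
            fwhm[axis] = FWHM_PER_SIGMA * sigma_vox * voxel_mm
    return fwhm


# ---------------------------------------------------------------------------
# cluster extraction


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) indices
    size: int
    peak_z: float
    peak_ijk: tuple
    sign: int = 1


@dataclass
class ClusterSet:
    clusters: list
    z_thresh: float
    extent_min: int
    connectivity: int

    def __len__(self) -> int:
        return len(self.clusters)

    def label_volume(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=np.int32)
        for i, cl in enumerate(self.clusters, start=1):
            out[tuple(cl.voxels.T)] = i
        return out


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise StatsError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def extract_clusters(
    z_map: np.ndarray,
    z_thresh: float = 2.5,
    extent_min: int = 125,
    connectivity: int = 26,
    two_sided: bool = False,
) -> ClusterSet:
    """Connected components of {z > z_thresh} (strict), dropping
    components smaller than ``extent_min``.  With ``two_sided`` the
    negative tail is handled symmetrically on -z."""
    z_map = np.asarray(z_map, dtype=float)
    structure = _structure(connectivity)
    clusters: list = []
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        field = sign * z_map
        labeled, n = ndimage.label(field > z_thresh, structure=structure)
        for lab in range(1, n + 1):
            vox = np.argwhere(labeled == lab)
            if vox.shape[0] < extent_min:
                continue
            vals = field[tuple(vox.T)]
            peak = int(np.argmax(vals))
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=vox.shape[0],
                    peak_z=float(sign * vals[peak]),
                    peak_ijk=tuple(int(i) for i in vox[peak]),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters=clusters, z_thresh=z_thresh,
                      extent_min=extent_min, connectivity=connectivity)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster calibration


@dataclass
class CalibrationTable:
    extents: np.ndarray
    alpha: np.ndarray  # P(any null cluster >= extent)
    n_sims: int
    z_thresh: float
    max_sizes: np.ndarray

    def alpha_at(self, extent: int) -> float:
        return float(np.mean(self.max_sizes >= extent))

    def extent_for(self, alpha_target: float = 0.05) -> int:
        ok = self.extents[self.alpha <= alpha_target]
        if ok.size == 0:
            return int(self.extents[-1] + 1)
        return int(ok.min())


def calibrate_cluster_threshold(
    mask: np.ndarray,
    smoothness_fwhm_mm,
    z_thresh: float,
    n_sims: int = 200,
    seed: int = 0,
    extents: np.ndarray | None = None,
    exogenous_sigma_mm: float = 0.0,
    voxel_mm: float = 3.0,
    connectivity: int = 26,
) -> CalibrationTable:
    """Empirical null distribution of the maximum cluster size.

    White Gaussian noise is simulated on the grid, convolved to the
    target smoothness (intrinsic FWHM from the residuals combined in
    quadrature with any exogenous smoothing kernel), re-standardized to
    unit variance within the mask, thresholded at ``z_thresh``, and the
    maximum connected-component size recorded per simulation.  An
    intrinsic FWHM at the one-voxel resolution floor contributes no
    extra convolution.
    """
    if n_sims < 100:
        raise StatsError("n_sims must be >= 100")
    mask = np.asarray(mask, dtype=bool)
    fwhm = np.broadcast_to(np.asarray(smoothness_fwhm_mm, dtype=float), (3,)).copy()
    sigma_intr_mm = np.sqrt(
        np.maximum((fwhm / FWHM_PER_SIGMA) ** 2 - (voxel_mm / FWHM_PER_SIGMA) ** 2, 0.0)
    )
    sigma_vox = np.sqrt(sigma_intr_mm**2 + exogenous_sigma_mm**2) / voxel_mm
    if max(mask.shape) < 4 * max(float(np.max(sigma_vox)), 1.0):
        raise StatsError("mask grid too small for the requested smoothness")
    structure = _structure(connectivity)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1B]))
    max_sizes = np.zeros(n_sims, dtype=int)
    do_smooth = float(np.max(sigma_vox)) > 0
    for i in range(n_sims):
        field = rng.standard_normal(mask.shape)
        if do_smooth:
            field = ndimage.gaussian_filter(field, sigma=tuple(sigma_vox))
        vals = field[mask]
        field_z = np.zeros(mask.shape)
        field_z[mask] = (vals - vals.mean()) / vals.std()
        labeled, n = ndimage.label(field_z > z_thresh, structure=structure)
        if n > 0:
            sizes = ndimage.sum_labels(np.ones(mask.shape), labeled, np.arange(1, n + 1))
            max_sizes[i] = int(sizes.max())
    if extents is None:
        extents = np.unique(np.concatenate([[1], np.arange(5, 501, 5), [125, 200]]))
    extents = np.asarray(sorted(set(int(e) for e in extents)))
    alpha = np.array([(max_sizes >= e).mean() for e in extents])
    return CalibrationTable(extents=extents, alpha=alpha, n_sims=n_sims,
                            z_thresh=z_thresh, max_sizes=max_sizes)


def build_design(table, predictor: str, covariates: list) -> tuple:
    """Design matrix [1, predictor, covariates...] from a subject table;
    returns (X, contrast selecting the predictor)."""
    cols = [np.ones(len(table)), np.asarray(table[predictor], dtype=float)]
    for cov in covariates:
        cols.append(np.asarray(table[cov], dtype=float))
    X = np.column_stack(cols)
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    return X, c
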