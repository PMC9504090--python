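"""Three-variable mediation with bootstrap BCa inference.

The indirect effect is the product of path coefficients: a (exposure ->
mediator) times b (mediator -> outcome, adjusted for the exposure), with
covariates entering both regressions.  Inference resamples subjects as
whole rows with replacement and forms bias-corrected and accelerated
(BCa) confidence intervals; the two-sided p-value is the smallest level
at which the BCa interval excludes zero (grid resolution 0.001, floored
at 2/n_boot), and is converted to a signed Z for voxelwise maps.

For ordinary least squares with the same covariates in both models the
total effect decomposes exactly: c = c' + a*b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import ClusterSet, extract_clusters, smooth_z


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    a: float
    b: float
    c: float  # total effect
    c_prime: float  # direct effect
    indirect: float  # a * b
    ci_lower: float
    ci_upper: float
    level: float
    p: float
    z: float
    boot_estimates: np.ndarray
    z0: float
    acceleration: float
    p_tail_mass: float
    degenerate: bool


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(x.shape[0]), x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.shape[0]:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def _paths_vectorized(x: np.ndarray, M: np.ndarray, y: np.ndarray,
                      covariates: np.ndarray | None) -> tuple:
    """OLS paths for V mediator columns at once via Frisch-Waugh.

    a_v: coefficient of x in M_v ~ 1 + x + C.
    b_v: coefficient of M_v in y ~ 1 + M_v + x + C, equal to the
    regression of the (1, x, C)-residualized y on the residualized M_v.
    Returns (a, b, c_total) with c_total scalar.
    """
    A = _design(x, covariates)  # (n, p)
    pinv = np.linalg.pinv(A)
    coefs_M = pinv @ M  # (p, V)
    a = coefs_M[1]
    eM = M - A @ coefs_M
    coef_y = pinv @ y
    c_total = float(coef_y[1])
    ey = y - A @ coef_y
    den = (eM**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, (eM * ey[:, None]).sum(axis=0) / den, 0.0)
    return a, b, c_total


def bootstrap_indices(n: int, n_boot: int, seed: int) -> np.ndarray:
    """The (n_boot, n) resample-index matrix used for every voxel."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    return rng.integers(0, n, size=(n_boot, n))


def _bca_bounds(theta: np.ndarray, boots: np.ndarray, jack: np.ndarray,
                n_boot: int) -> tuple:
    """Bias-correction z0 and acceleration per column.

    ``theta`` (V,), ``boots`` (B, V), ``jack`` (n, V)."""
    frac = (boots < theta[None, :]).mean(axis=0)
    frac = np.clip(frac, 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0))
    z0 = sps.norm.ppf(frac)
    jm = jack.mean(axis=0)
    d = jm[None, :] - jack
    num = (d**3).sum(axis=0)
    den = 6.0 * ((d**2).sum(axis=0)) ** 1.5
    accel = np.where(den > 0, num / den, 0.0)
    return z0, accel


def _bca_interval(boots: np.ndarray, z0: np.ndarray, accel: np.ndarray,
                  level: float) -> tuple:
    """BCa interval endpoints per column at confidence ``level``."""
    alpha = 1.0 - level
    zlo = sps.norm.ppf(alpha / 2.0)
    zhi = sps.norm.ppf(1.0 - alpha / 2.0)

    def adj(zq):
        u = z0 + zq
        return sps.norm.cdf(z0 + u / (1.0 - accel * u))

    plo = adj(zlo)
    phi = adj(zhi)
    lower = np.array([np.quantile(boots[:, v], plo[v]) for v in range(boots.shape[1])])
    upper = np.array([np.quantile(boots[:, v], phi[v]) for v in range(boots.shape[1])])
    return lower, upper


def _bca_p(boots: np.ndarray, z0: np.ndarray, accel: np.ndarray,
           n_boot: int, grid_step: float = 0.001) -> np.ndarray:
    """Smallest alpha at which the BCa interval excludes 0 (two-sided).

    The interval excludes 0 at level 1-alpha iff the bootstrap CDF value
    of 0 lies outside the adjusted percentile pair; exclusion is
    monotone in alpha, so the grid scan reads off the p-value directly.
    """
    B, V = boots.shape
    F0 = (boots <= 0).mean(axis=0)  # (V,)
    alphas = np.arange(grid_step, 1.0, grid_step)
    zq = sps.norm.ppf(alphas / 2.0)  # (A,) lower-tail quantiles
    u_lo = z0[:, None] + zq[None, :]
    u_hi = z0[:, None] - zq[None, :]  # z_{1-alpha/2} = -zq
    with np.errstate(over="ignore", invalid="ignore"):
        p_lo = sps.norm.cdf(z0[:, None] + u_lo / (1.0 - accel[:, None] * u_lo))
        p_hi = sps.norm.cdf(z0[:, None] + u_hi / (1.0 - accel[:, None] * u_hi))
    excluded = (F0[:, None] < p_lo) | (F0[:, None] > p_hi)
    any_exc = excluded.any(axis=1)
    first = np.argmax(excluded, axis=1)
    p = np.where(any_exc, alphas[np.minimum(first, alphas.size - 1)], 1.0)
    return np.maximum(p, 2.0 / n_boot)


def _mediate_columns(
    x: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    boot_idx: np.ndarray,
    level: float,
    tail_mass: bool = False,
) -> dict:
    """Shared engine: mediation over V mediator columns with a common
    bootstrap index matrix."""
    n = x.shape[0]
    n_boot = boot_idx.shape[0]
    a, b, c_total = _paths_vectorized(x, M, y, covariates)
    theta = a * b

    boots = np.empty((n_boot, M.shape[1]))
    for i in range(n_boot):
        idx = boot_idx[i]
        cov_i = None if covariates is None else np.atleast_2d(
            np.asarray(covariates, dtype=float).reshape(n, -1)
        )[idx]
        ab, bb, _ = _paths_vectorized(x[idx], M[idx], y[idx], cov_i)
        boots[i] = ab * bb

    jack = np.empty((n, M.shape[1]))
    all_idx = np.arange(n)
    for i in range(n):
        idx = all_idx[all_idx != i]
        cov_i = None if covariates is None else np.atleast_2d(
            np.asarray(covariates, dtype=float).reshape(n, -1)
        )[idx]
        aj, bj, _ = _paths_vectorized(x[idx], M[idx], y[idx], cov_i)
        jack[i] = aj * bj

    z0, accel = _bca_bounds(theta, boots, jack, n_boot)
    lower, upper = _bca_interval(boots, z0, accel, level)
    p = _bca_p(boots, z0, accel, n_boot)
    if tail_mass:
        tm = 2.0 * np.minimum((boots <= 0).mean(axis=0), (boots >= 0).mean(axis=0))
        p_tail = np.maximum(tm, 2.0 / n_boot)
    else:
        p_tail = np.full(theta.shape, np.nan)
    degenerate = boots.std(axis=0) == 0
    z = np.sign(theta) * sps.norm.isf(np.minimum(p, 1.0) / 2.0)
    z[p >= 1.0] = 0.0
    return {
        "a": a, "b": b, "c": c_total, "indirect": theta,
        "lower": lower, "upper": upper, "p": p, "z": z,
        "boots": boots, "z0": z0, "accel": accel,
        "p_tail": p_tail, "degenerate": degenerate,
    }


def mediate(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    boot_idx: np.ndarray | None = None,
) -> MediationResult:
    """Mediation of x -> m -> y with bootstrap BCa inference.

    Fits m = a*x + covariates and y = b*m + c'*x + covariates by OLS,
    resamples subjects with replacement ``n_boot`` times (deterministic
    per ``seed``; an explicit ``boot_idx`` matrix overrides), and reports
    the indirect effect a*b with its BCa interval, two-sided p, and
    signed z.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise MediationError("need at least 10 observations")
    if boot_idx is None:
        if n_boot < 100:
            raise MediationError("n_boot must be >= 100")
        boot_idx = bootstrap_indices(n, n_boot, seed)
    if x.std() == 0 or m.std() == 0:
        raise MediationError("zero-variance exposure or mediator")
    res = _mediate_columns(x, m[:, None], y, covariates, boot_idx, level,
                           tail_mass=True)
    a = float(res["a"][0])
    b = float(res["b"][0])
    indirect = float(res["indirect"][0])
    return MediationResult(
        a=a, b=b, c=float(res["c"]), c_prime=float(res["c"]) - indirect,
        indirect=indirect,
        ci_lower=float(res["lower"][0]), ci_upper=float(res["upper"][0]),
        level=level, p=float(res["p"][0]), z=float(res["z"][0]),
        boot_estimates=res["boots"][:, 0],
        z0=float(res["z0"][0]), acceleration=float(res["accel"][0]),
        p_tail_mass=float(res["p_tail"][0]),
        degenerate=bool(res["degenerate"][0]),
    )


@dataclass
class VoxelMediationResult:
    z: np.ndarray  # signed Z volume (smoothed)
    z_raw: np.ndarray
    indirect: np.ndarray
    p: np.ndarray
    clusters: ClusterSet
    mask: np.ndarray


def voxelwise_mediation(
    x,
    maps: np.ndarray,
    other: np.ndarray,
    maps_role: str,
    mask: np.ndarray,
    covariates=None,
    n_boot: int = 1000,
    seed: int = 0,
    sigma_mm: float = 4.0,
    voxel_mm: float = 3.0,
    z_thresh: float = 2.5,
    extent_min: int = 125,
    connectivity: int = 26,
    two_sided: bool = True,
) -> VoxelMediationResult:
    """Voxelwise mediation with the map as mediator or outcome.

    role='mediator': x -> map_v -> other.  role='outcome': x -> other ->
    map_v.  The per-voxel signed z = sign(ab) * Phi^-1(1 - p/2) is
    Gaussian-smoothed (sigma 4 mm) and thresholded with the same cluster
    rule as the correlational analyses.  Subjects are resampled as whole
    rows with one bootstrap index matrix shared across voxels, so the
    result is bit-identical to running ``mediate`` per voxel with that
    matrix.
    """
    if maps_role not in ("mediator", "outcome"):
        raise MediationError("maps_role must be 'mediator' or 'outcome'")
    x = np.asarray(x, dtype=float)
    other = np.asarray(other, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    maps = np.asarray(maps, dtype=float)
    n = x.shape[0]
    M2 = maps.reshape(n, -1)[:, mask.ravel()]  # (n, V)
    boot_idx = bootstrap_indices(n, n_boot, seed)

    if maps_role == "mediator":
        res = _mediate_columns(x, M2, other, covariates, boot_idx, 0.95)
        z_vals, p_vals, ind = res["z"], res["p"], res["indirect"]
    else:
        # single mediator, many outcomes: bootstrap the (a, b_v) pair jointly
        res = _outcome_columns(x, other, M2, covariates, boot_idx)
        z_vals, p_vals, ind = res["z"], res["p"], res["indirect"]

    z_raw = np.zeros(mask.shape)
    z_raw[mask] = z_vals
    p_vol = np.ones(mask.shape)
    p_vol[mask] = p_vals
    ind_vol = np.zeros(mask.shape)
    ind_vol[mask] = ind
    z_smooth = smooth_z(z_raw, sigma_mm, mask, voxel_mm=voxel_mm)
    clusters = extract_clusters(z_smooth, z_thresh=z_thresh,
                                extent_min=extent_min,
                                connectivity=connectivity, two_sided=two_sided)
    return VoxelMediationResult(z=z_smooth, z_raw=z_raw, indirect=ind_vol,
                                p=p_vol, clusters=clusters, mask=mask)


def _outcome_columns(x: np.ndarray, m: np.ndarray, Y: np.ndarray,
                     covariates, boot_idx: np.ndarray) -> dict:
    """Mediation with a single mediator and V outcome columns."""
    n = x.shape[0]
    n_boot = boot_idx.shape[0]

    def paths(xi, mi, Yi, cov):
        A = _design(xi, cov)
        pinv = np.linalg.pinv(A)
        a = float((pinv @ mi)[1])
        em = mi - A @ (pinv @ mi)
        coefs_Y = pinv @ Yi
        eY = Yi - A @ coefs_Y
        den = float((em**2).sum())
        b = (em @ eY) / den if den > 0 else np.zeros(Yi.shape[1])
        return a * b

    cov_full = None if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    theta = paths(x, m, Y, cov_full)
    boots = np.empty((n_boot, Y.shape[1]))
    for i in range(n_boot):
        idx = boot_idx[i]
        boots[i] = paths(x[idx], m[idx], Y[idx],
                         None if cov_full is None else cov_full[idx])
    jack = np.empty((n, Y.shape[1]))
    all_idx = np.arange(n)
    for i in range(n):
        idx = all_idx[all_idx != i]
        jack[i] = paths(x[idx], m[idx], Y[idx],
                        None if cov_full is None else cov_full[idx])
    z0, accel = _bca_bounds(theta, boots, jack, n_boot)
    p = _bca_p(boots, z0, accel, n_boot)
    z = np.sign(theta) * sps.norm.isf(np.minimum(p, 1.0) / 2.0)
    z[p >= 1.0] = 0.0
    return {"z": z, "p": p, "indirect": theta}
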