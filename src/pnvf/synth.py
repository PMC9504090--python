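"""Synthetic study generator: phantom anatomy, BOLD runs, pCASL series
and a covariate table with planted ground truth.

The generator emulates the acquisition geometry of a pediatric
resting-state + ASL protocol — two 150-frame TR=2 s BOLD runs and one
45-pair pCASL series at TR=4.1 s per subject, on a shared 3 mm grid —
so every downstream estimator (FCS, CBF, the Pnvf ratio, voxelwise GLMs,
mediation) can be validated against known truth without any real data.

Signal model for a BOLD voxel v::

    s_v(t) = baseline_v * (1 + g_v c(t) + w_vk eta_k(t) + u xi_v(t) + eps)

where eta_k is the band-limited (0.01-0.08 Hz) shared time course of
network k, xi_v is a voxel-specific band-limited course, c(t) is a
low-frequency (0.02-0.04 Hz) global driver standing in for end-tidal CO2
fluctuations, and eps is thermal noise.  The shared/idiosyncratic
amplitude ratio fixes the within-network pairwise correlation at a
per-subject target r: w = u * sqrt(r / (1 - r)).

Motion enters twice: as a six-parameter trace (driving FD) and as a
multiplicative intensity disturbance on spike frames (driving DVARS), so
censoring can be validated on each criterion independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .asl import AslAcquisition, AslParams, forward_fractional_change
from .preproc import BoldRun, MotionTrace


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# anatomy


@dataclass
class PhantomAnatomy:
    """Tissue-probability phantom on a common grid.

    Gray/white/CSF probabilities sum to <= 1 per voxel; ``networks`` is an
    integer community label per voxel (0 = unassigned) and ``excluded`` an
    integer label volume standing in for regions removed from analysis
    (the study removed the cerebellum by template label)."""

    gray: np.ndarray
    white: np.ndarray
    csf: np.ndarray
    networks: np.ndarray
    excluded: np.ndarray
    voxel_mm: float = 3.0

    @property
    def dims(self) -> tuple:
        return self.gray.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.gray + self.white + self.csf) > 0.5

    @property
    def n_networks(self) -> int:
        return int(self.networks.max())

    def network_mask(self, k: int) -> np.ndarray:
        return self.networks == k

    def validate(self) -> None:
        total = self.gray + self.white + self.csf
        if total.max() > 1.0 + 1e-9:
            raise SyntheticError("tissue probabilities exceed 1")
        in_net = self.networks > 0
        if in_net.any() and not (self.gray[in_net] > 0.66).all():
            raise SyntheticError("network voxels must lie in gray matter (> 0.66)")


def make_phantom_anatomy(
    dims: tuple = (24, 24, 18),
    n_networks: int = 3,
    seed: int = 0,
    voxel_mm: float = 3.0,
    network_radius_vox: float = 3.5,
    min_separation_vox: float = 9.0,
) -> PhantomAnatomy:
    """Ellipsoidal brain phantom with disjoint network blobs in gray matter.

    The brain is an ellipsoid with a CSF rim, a gray-matter shell and a
    white-matter core.  Networks are spherical communities placed (given
    ``seed``) at random centers inside the deep gray shell, pairwise
    separated by at least ``min_separation_vox``.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 8 for d in dims):
        raise SyntheticError(f"dims {dims} too small; need >= 8 per axis")
    if n_networks < 1:
        raise SyntheticError("n_networks must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11A70]))

    nx, ny, nz = dims
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.46 * nx, 0.46 * ny, 0.46 * nz
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)

    # radial tissue profile: white core, thick gray shell, thin CSF rim
    gray = np.clip(1.0 - np.abs((r - 0.62) / 0.30) ** 2, 0.0, 1.0)
    white = np.clip(1.0 - (r / 0.45) ** 2, 0.0, 1.0)
    csf = np.clip(1.0 - np.abs((r - 0.97) / 0.08) ** 2, 0.0, 1.0)
    total = gray + white + csf
    over = total > 1.0
    for vol in (gray, white, csf):
        vol[over] /= total[over]
    outside = r > 1.0
    for vol in (gray, white, csf):
        vol[outside] = 0.0

    deep_gray = gray > 0.70
    candidates = np.argwhere(deep_gray)
    if candidates.shape[0] == 0:
        raise SyntheticError("phantom has no deep gray matter; enlarge dims")

    centers: list = []
    order = rng.permutation(candidates.shape[0])
    for idx in order:
        c = candidates[idx]
        if all(np.linalg.norm(c - np.asarray(p)) >= min_separation_vox for p in centers):
            centers.append(tuple(c))
        if len(centers) == n_networks:
            break
    if len(centers) < n_networks:
        raise SyntheticError(
            f"could not place {n_networks} disjoint networks at separation "
            f"{min_separation_vox} in dims {dims}"
        )

    networks = np.zeros(dims, dtype=np.int32)
    coords = np.stack([x, y, z], axis=-1).astype(float)
    for k, c in enumerate(centers, start=1):
        d = np.linalg.norm(coords - np.asarray(c), axis=-1)
        blob = (d <= network_radius_vox) & (gray > 0.66) & (networks == 0)
        networks[blob] = k

    # excluded region: a small inferior blob, standing in for cerebellum removal
    excluded = np.zeros(dims, dtype=np.int32)
    exc_center = np.array([cx, cy, 1.0])
    d = np.linalg.norm(coords - exc_center, axis=-1)
    excluded[(d <= 3.0) & ((gray + white) > 0.1)] = 1

    anat = PhantomAnatomy(
        gray=gray, white=white, csf=csf, networks=networks,
        excluded=excluded, voxel_mm=voxel_mm,
    )
    anat.validate()
    return anat


def gray_matter_like_mask(
    target_voxels: int = 45000, voxel_mm: float = 3.0
) -> tuple:
    """Deterministic cortical-shell mask with approximately
    ``target_voxels`` voxels, used for full-scale cluster calibration.

    Returns (mask, voxel_mm).  The shell lies between two concentric
    ellipsoids; the inner scale is bisected so the voxel count lands
    within ~1% of the target.
    """
    dims = (64, 76, 64)
    nx, ny, nz = dims
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.47 * nx, 0.47 * ny, 0.47 * nz
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)
    lo, hi = 0.0, 1.0

    def count(inner: float) -> int:
        return int(((r <= 1.0) & (r >= inner)).sum())

    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if count(mid) > target_voxels:
            lo = mid
        else:
            hi = mid
    inner = 0.5 * (lo + hi)
    mask = (r <= 1.0) & (r >= inner)
    return mask, voxel_mm


# ---------------------------------------------------------------------------
# cohort specification and ground truth


@dataclass
class CohortSpec:
    """Free parameters of the synthetic study.

    Defaults reproduce the study conditions where stated (group sizes
    24/64, 150-frame TR=2 s runs, 45-pair TR=4.1 s ASL) and otherwise use
    values a practitioner would call realistic for 3 T pediatric imaging
    (1% BOLD fluctuation amplitude, gray/white CBF of 60/20 mL/100 g/min).
    """

    n_chd: int = 24
    n_control: int = 64
    dims: tuple = (24, 24, 18)
    voxel_mm: float = 3.0
    n_networks: int = 3
    network_radius_vox: float = 4.5
    min_separation_vox: float = 10.0

    # connectivity: per-subject within-network correlation targets
    base_network_r: float = 0.72
    group_dr: tuple = (-0.03, 0.0, 0.0)  # direct CHD shift per network
    mediator_coupling: tuple = (0.5, 0.0, 0.0)  # r shift per mediator unit, net 1 carries the chain
    cbf_mediator_coupling: tuple = (-0.12, 0.0, 0.0)  # fractional CBF shift per mediator unit

    # BOLD signal amplitudes (fractional units)
    bold_fluct: float = 0.01  # idiosyncratic band-limited amplitude
    bold_noise_sd: float = 0.005  # thermal
    co2_gain_mean: float = 0.002  # global driver gain
    co2_gain_coupling: float = 0.001  # extra gain per unit zero-meaned true-Pnvf deviation

    # motion
    spike_frames: tuple = (40, 100)
    spike_mag_mm: tuple = (0.5, 0.8)
    spike_intensity_per_mm: float = 0.06  # multiplicative disturbance per mm of spike
    motion_walk_sd_mm: float = 0.01
    motion_walk_sd_rad: float = 1e-4

    # CBF truth (mL/100 g/min)
    cbf_gray: float = 60.0
    cbf_white: float = 20.0
    cbf_spatial_sd: float = 5.0
    asl_noise_sd: float = 1.2  # intensity units; yields ~7% gray-matter CBF error
    n_asl_pairs: int = 45

    # covariates: mediator = a*group + eps_m ; outcome = b*mediator + c_direct*group + eps_y
    med_a: float = -1.0
    med_b: float = 1.0
    med_c_direct: float = 0.0
    med_resid_sd: float = 0.35
    out_resid_sd: float = 0.25

    run_length: int = 150
    tr_bold: float = 2.0
    n_repeat_subjects: int = 3
    master_seed: int = 1234

    asl_params: AslParams = field(default_factory=AslParams)

    def validate(self) -> None:
        if self.n_chd <= 0 or self.n_control <= 0:
            raise SyntheticError("group counts must be positive")
        if self.run_length < 1:
            raise SyntheticError("run length must be >= 1")
        for name in ("bold_noise_sd", "asl_noise_sd", "med_resid_sd", "out_resid_sd",
                     "cbf_spatial_sd", "motion_walk_sd_mm"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_chd + self.n_control


@dataclass
class GroundTruth:
    """Everything the generator planted, reproducible bit-exactly from
    (CohortSpec, master seed)."""

    true_cbf: np.ndarray
    network_r: np.ndarray  # (n_subjects, n_networks) per-subject correlation targets
    mediator: np.ndarray  # standardized-scale mediator values
    outcome: np.ndarray
    spike_frames: tuple
    subject_seeds: list
    expected_fcs: np.ndarray | None = None
    true_pnvf_dev: np.ndarray | None = None
    cbf_scale: np.ndarray | None = None  # (n_subjects, n_networks) perfusion modulation


@dataclass
class SubjectData:
    subject_id: str
    group: int
    runs: list  # [(BoldRun, MotionTrace), ...]
    asl: AslAcquisition


# ---------------------------------------------------------------------------
# signal building blocks


def bandlimited_noise(
    rng: np.random.Generator, n: int, tr: float, f_lo: float, f_hi: float, size: int = 1
) -> np.ndarray:
    """(size, n) unit-variance Gaussian series band-limited to [f_lo, f_hi]."""
    white = rng.standard_normal((size, n))
    freqs = np.fft.rfftfreq(n, d=tr)
    H = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    H[0] = 0.0
    out = np.fft.irfft(np.fft.rfft(white, axis=1) * H, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def true_cbf_volume(anatomy: PhantomAnatomy, spec: CohortSpec, seed: int) -> np.ndarray:
    """Ground-truth perfusion: tissue-weighted means plus smooth variation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCBF]))
    base = spec.cbf_gray * anatomy.gray + spec.cbf_white * anatomy.white
    if spec.cbf_spatial_sd > 0:
        rough = rng.standard_normal(anatomy.dims)
        smooth = ndimage.gaussian_filter(rough, sigma=2.0)
        smooth /= max(smooth.std(), 1e-12)
        base = base + spec.cbf_spatial_sd * smooth * (base > 1)
    return np.clip(base, 0.0, None)


def expected_fcs_volume(anatomy: PhantomAnatomy, spec: CohortSpec) -> np.ndarray:
    """Population-level FCS implied by the signal model (clipped-positive
    mean correlation with all other gray voxels), ignoring sampling noise."""
    gm = anatomy.gray > 0.66
    N = int(gm.sum())
    fcs = np.zeros(anatomy.dims)
    r = spec.base_network_r
    for k in range(1, anatomy.n_networks + 1):
        net = anatomy.network_mask(k) & gm
        nk = int(net.sum())
        if nk >= 2:
            fcs[net] = (nk - 1) * r / max(N - 1, 1)
    return fcs


# ---------------------------------------------------------------------------
# BOLD simulation


def simulate_bold_run(
    anatomy: PhantomAnatomy,
    spec: CohortSpec,
    subject: int,
    run_index: int,
    seed: int,
    network_r: np.ndarray | None = None,
    co2_gain: np.ndarray | None = None,
    co2_driver: np.ndarray | None = None,
) -> tuple:
    """Simulate one BOLD run and its motion trace.

    ``network_r`` gives this subject's within-network correlation target
    per network (defaults to the control baseline).  ``co2_gain`` is the
    per-voxel fractional gain on the global driver; ``co2_driver`` allows
    injecting a known driver time course (band 0.02-0.04 Hz otherwise).
    """
    spec.validate()
    T = spec.run_length
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject), int(run_index), 0xB07D])
    )
    if network_r is None:
        network_r = np.full(anatomy.n_networks, spec.base_network_r)
    network_r = np.clip(np.asarray(network_r, dtype=float), 0.02, 0.95)

    brain = anatomy.brain_mask
    V = int(brain.sum())
    baseline = 900.0 * (0.7 * anatomy.gray + 0.6 * anatomy.white + 0.9 * anatomy.csf) + 30.0

    eta = bandlimited_noise(rng, T, spec.tr_bold, 0.01, 0.08, size=anatomy.n_networks)
    if co2_driver is None:
        co2_driver = bandlimited_noise(rng, T, spec.tr_bold, 0.02, 0.04, size=1)[0]
    xi = bandlimited_noise(rng, T, spec.tr_bold, 0.01, 0.08, size=V)

    u = spec.bold_fluct
    frac = u * xi  # (V, T) idiosyncratic component
    net_labels = anatomy.networks[brain]
    for k in range(1, anatomy.n_networks + 1):
        rk = network_r[k - 1]
        w = u * np.sqrt(rk / (1.0 - rk))
        members = net_labels == k
        if members.any():
            frac[members] += w * eta[k - 1]

    if co2_gain is None:
        gain = np.full(V, spec.co2_gain_mean)
        if spec.co2_gain_coupling != 0:
            # couple to the zero-meaned true-Pnvf deviation in gray matter
            dev = _pnvf_deviation(anatomy, spec)
            gain = gain + spec.co2_gain_coupling * dev[brain]
    else:
        gain = np.asarray(co2_gain, dtype=float)
        if gain.shape != (V,):
            gain = gain[brain]
    frac += gain[:, None] * co2_driver[None, :]
    if spec.bold_noise_sd > 0:
        frac += spec.bold_noise_sd * rng.standard_normal((V, T))

    data = np.tile(baseline[..., None], (1, 1, 1, T))
    data[brain] = baseline[brain][:, None] * (1.0 + frac)
    # out-of-brain thermal noise
    out = ~brain
    data[out] += 2.0 * rng.standard_normal((int(out.sum()), T))

    # motion: slow random walk plus scheduled spikes
    trans = np.cumsum(rng.normal(0.0, spec.motion_walk_sd_mm, size=(T, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, spec.motion_walk_sd_rad, size=(T, 3)), axis=0)
    for f, mag in zip(spec.spike_frames, spec.spike_mag_mm):
        if 0 <= f < T:
            trans[f, 2] += mag  # single-frame displacement
            data[..., f] *= 1.0 + spec.spike_intensity_per_mm * mag
    trace = MotionTrace(translations=trans, rotations=rot)
    run = BoldRun(data=data, tr=spec.tr_bold, run_index=run_index)
    return run, trace


def _pnvf_deviation(anatomy: PhantomAnatomy, spec: CohortSpec) -> np.ndarray:
    """Zero-meaned (over gray matter) true-Pnvf deviation volume, unit SD."""
    gm = anatomy.gray > 0.66
    fcs = expected_fcs_volume(anatomy, spec)
    cbf = spec.cbf_gray * anatomy.gray + spec.cbf_white * anatomy.white
    pnvf = -fcs / np.maximum(cbf, 20.0)
    dev = np.zeros(anatomy.dims)
    vals = pnvf[gm]
    sd = vals.std()
    dev[gm] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return dev


# ---------------------------------------------------------------------------
# ASL simulation


def simulate_asl_series(
    anatomy: PhantomAnatomy,
    true_cbf: np.ndarray,
    asl_params: AslParams,
    seed: int,
    n_pairs: int = 45,
    noise_sd: float = 1.2,
) -> AslAcquisition:
    """Interleaved control/label pCASL series from the forward kinetic model.

    control = M0 + noise; label = M0 * (1 - dM/M(CBF, slice)) + noise,
    with the slice-dependent post-labeling delay applied per acquisition
    order (slice index = z coordinate, ascending)."""
    true_cbf = np.asarray(true_cbf, dtype=float)
    if (true_cbf < 0).any():
        raise SyntheticError("true CBF must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA51]))
    dims = anatomy.dims
    m0 = 1000.0 * (0.75 * anatomy.gray + 0.65 * anatomy.white + 1.0 * anatomy.csf) + 20.0

    slice_idx = np.broadcast_to(np.arange(dims[2])[None, None, :], dims)
    dm_over_m = forward_fractional_change(true_cbf, asl_params, slice_idx)
    label_mean = m0 * (1.0 - dm_over_m)

    n_vols = 2 * n_pairs
    data = np.empty(dims + (n_vols,), dtype=float)
    is_label = np.zeros(n_vols, dtype=bool)
    is_label[1::2] = True
    for t in range(n_vols):
        mean = label_mean if is_label[t] else m0
        noise = noise_sd * rng.standard_normal(dims) if noise_sd > 0 else 0.0
        data[..., t] = mean + noise
    return AslAcquisition(
        data=data, is_label=is_label, params=asl_params, tr=asl_params.tr_ms / 1000.0
    )


# ---------------------------------------------------------------------------
# whole cohort


@dataclass
class Cohort:
    anatomy: PhantomAnatomy
    subjects: list  # of SubjectData
    table: pd.DataFrame
    truth: GroundTruth


def _covariate_table(spec: CohortSpec, rng: np.random.Generator) -> tuple:
    """Subject table with the planted group -> mediator -> outcome chain.

    mediator_std = a*group + eps_m ; outcome_std = b*mediator_std +
    c'*group + eps_y.  Natural-unit columns (nNO-like nL/min, NIH-Toolbox-
    like composite) are affine rescalings of the standardized values."""
    n = spec.n_subjects
    group = np.concatenate([np.ones(spec.n_chd, dtype=int), np.zeros(spec.n_control, dtype=int)])
    age = rng.uniform(6.0, 25.0, size=n)  # recruitment span 6-25 y
    gender = rng.integers(0, 2, size=n)
    eps_m = rng.normal(0.0, spec.med_resid_sd, size=n)
    eps_y = rng.normal(0.0, spec.out_resid_sd, size=n)
    mediator = spec.med_a * group + eps_m
    outcome = spec.med_b * mediator + spec.med_c_direct * group + eps_y
    age_at_med = age + rng.uniform(-0.5, 0.5, size=n)
    repeat = np.zeros(n, dtype=bool)
    repeat[: min(spec.n_repeat_subjects, n)] = True
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "gender": gender,
            "nno": 280.0 + 80.0 * mediator,
            "cognition": 110.0 + 15.0 * outcome,
            "mediator_std": mediator,
            "outcome_std": outcome,
            "age_at_nno": age_at_med,
            "repeat_scan": repeat,
        }
    )
    return table, mediator, outcome


def simulate_cohort(spec: CohortSpec, with_imaging: bool = True) -> Cohort:
    """Generate the full synthetic study, deterministic per master seed."""
    spec.validate()
    ss = np.random.SeedSequence(spec.master_seed)
    anat_seed, cov_seed, cbf_seed, *subj_seeds = ss.generate_state(3 + spec.n_subjects)
    anatomy = make_phantom_anatomy(
        dims=spec.dims, n_networks=spec.n_networks, seed=int(anat_seed),
        voxel_mm=spec.voxel_mm, network_radius_vox=spec.network_radius_vox,
        min_separation_vox=spec.min_separation_vox,
    )
    table, mediator, outcome = _covariate_table(
        spec, np.random.default_rng(np.random.SeedSequence([int(cov_seed), 0xC0F]))
    )
    true_cbf = true_cbf_volume(anatomy, spec, int(cbf_seed))

    group = table["group"].to_numpy()
    n = spec.n_subjects
    network_r = np.zeros((n, spec.n_networks))
    m_centered = mediator - mediator.mean()
    for k in range(spec.n_networks):
        network_r[:, k] = (
            spec.base_network_r
            + spec.group_dr[k] * group
            + spec.mediator_coupling[k] * m_centered
        )
    network_r = np.clip(network_r, 0.02, 0.95)

    # per-subject perfusion: the mediator modulates regional CBF inside
    # the coupled network(s), mirroring NO-dependent vascular tone
    cbf_scale = np.ones((n, spec.n_networks))
    for k in range(spec.n_networks):
        cbf_scale[:, k] = 1.0 + spec.cbf_mediator_coupling[k] * m_centered
    cbf_scale = np.clip(cbf_scale, 0.3, 2.0)

    subjects: list = []
    if with_imaging:
        for i in range(n):
            seed_i = int(subj_seeds[i])
            runs = []
            for run_index in (1, 2):
                run, trace = simulate_bold_run(
                    anatomy, spec, subject=i, run_index=run_index, seed=seed_i,
                    network_r=network_r[i],
                )
                runs.append((run, trace))
            cbf_i = true_cbf.copy()
            for k in range(spec.n_networks):
                net = anatomy.network_mask(k + 1)
                cbf_i[net] *= cbf_scale[i, k]
            asl = simulate_asl_series(
                anatomy, cbf_i, spec.asl_params, seed=seed_i,
                n_pairs=spec.n_asl_pairs, noise_sd=spec.asl_noise_sd,
            )
            subjects.append(
                SubjectData(
                    subject_id=table["subject_id"].iloc[i],
                    group=int(group[i]), runs=runs, asl=asl,
                )
            )

    truth = GroundTruth(
        true_cbf=true_cbf,
        cbf_scale=cbf_scale,
        network_r=network_r,
        mediator=mediator,
        outcome=outcome,
        spike_frames=spec.spike_frames,
        subject_seeds=[int(s) for s in subj_seeds],
        expected_fcs=expected_fcs_volume(anatomy, spec),
        true_pnvf_dev=_pnvf_deviation(anatomy, spec),
    )
    return Cohort(anatomy=anatomy, subjects=subjects, table=table, truth=truth)
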