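"""End-to-end orchestration: simulate (optional) -> preprocess -> FCS ->
CBF -> Pnvf -> group analyses, with per-stage QC reporting.

The stages mirror the study pipeline: BOLD runs are grand-mean
normalized, scrubbed (FD/DVARS), nuisance-regressed and band-passed;
FCS is computed per run on the subject gray mask; ASL series are fit by
GLM and inverted to CBF; Pnvf = -FCS / max(CBF, floor) is averaged over
runs, filled into the group gray mask, and fed to the voxelwise group
GLM (with Monte-Carlo cluster calibration), bootstrap mediation, CO2-
estimator agreement and test-retest reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, fcs as fcs_mod, petco2 as petco2_mod, preproc, stats as stats_mod
from .asl import asl_glm, quantify_cbf
from .config import PipelineConfig
from .mediation import voxelwise_mediation
from .synth import Cohort, CohortSpec, SubjectData, simulate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        super().__init__(f"stage '{stage}'"
                         + (f" subject {subject}" if subject else "")
                         + f" failed: {cause}")
        self.stage = stage
        self.subject = subject


@dataclass
class SubjectResult:
    subject_id: str
    group: int
    retention: preproc.RetentionReport
    valid: bool
    gray_mask: np.ndarray | None = None
    fcs_maps: list = field(default_factory=list)
    cbf: np.ndarray | None = None
    pnvf_runs: list = field(default_factory=list)
    pnvf_mean: core.PnvfMap | None = None
    runs_pp: list = field(default_factory=list)  # preprocessed BoldRun per valid run
    qc: dict = field(default_factory=dict)


@dataclass
class PipelineReport:
    config: PipelineConfig
    qc: pd.DataFrame
    group_clusters: stats_mod.ClusterSet | None = None
    group_z: np.ndarray | None = None
    mediation_clusters: stats_mod.ClusterSet | None = None
    retest: core.RetestSummary | None = None
    co2_group: petco2_mod.GroupTestResult | None = None
    calibration: stats_mod.CalibrationTable | None = None
    extent_used: int | None = None
    thresholds: dict = field(default_factory=dict)

    def summary_lines(self) -> list:
        lines = [
            "Pnvf pipeline report",
            f"subjects analyzed: {len(self.qc)} "
            f"(valid: {int(self.qc['subject_valid'].sum())})",
        ]
        for key, val in self.thresholds.items():
            lines.append(f"  threshold {key} = {val}")
        if self.group_clusters is not None:
            lines.append(f"group-contrast clusters: {len(self.group_clusters)} "
                         f"(extent >= {self.extent_used})")
        if self.mediation_clusters is not None:
            lines.append(f"mediation clusters: {len(self.mediation_clusters)}")
        if self.retest is not None:
            lines.append(
                f"test-retest: mean r = {self.retest.mean_r:.3f}, "
                f"{100 * self.retest.frac_above:.1f}% voxels r > {self.retest.threshold}"
            )
        if self.co2_group is not None:
            lines.append(
                f"CO2 estimator agreement: mean z = {self.co2_group.mean:.2f} "
                f"+/- {self.co2_group.sem:.2f} (p = {self.co2_group.p:.2g})"
            )
        return lines


def preprocess_run(run: preproc.BoldRun, trace: preproc.MotionTrace,
                   brain_mask: np.ndarray, cfg: PipelineConfig) -> tuple:
    """normalize -> FD/DVARS -> censor -> nuisance regression -> band-pass."""
    run_n = preproc.normalize_global(run, target=cfg.norm_target, mask=brain_mask)
    fd = preproc.framewise_displacement(trace, head_radius_mm=cfg.head_radius_mm)
    dv = preproc.dvars(run_n, brain_mask)
    censor = preproc.censor_frames(fd, dv, cfg.fd_thresh, cfg.dvars_thresh)
    run_r = preproc.nuisance_regress(run_n, trace, censor, drift_order=cfg.drift_order)
    run_f = preproc.bandpass(run_r, cfg.bold_band[0], cfg.bold_band[1], censor)
    return run_f, censor, fd, dv


def process_subject(subject: SubjectData, anatomy, cfg: PipelineConfig) -> SubjectResult:
    """Per-subject pipeline through the final averaged Pnvf map."""
    sid = subject.subject_id
    brain = anatomy.brain_mask
    try:
        processed = []
        censors = []
        for run, trace in subject.runs:
            run_f, censor, _, _ = preprocess_run(run, trace, brain, cfg)
            processed.append(run_f)
            censors.append(censor)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("preprocess", sid, exc) from exc

    retention = preproc.apply_retention_rules(
        censors, cfg.min_run_frames, cfg.min_total_frames
    )
    result = SubjectResult(subject_id=sid, group=subject.group,
                           retention=retention, valid=retention.subject_valid)
    result.qc = {
        "retained_per_run": retention.retained_per_run,
        "total_retained": retention.total_retained,
    }
    if not retention.subject_valid:
        return result

    try:
        gray = fcs_mod.subject_gray_mask(anatomy.gray, cfg.gray_threshold,
                                         excluded=anatomy.excluded)
        valid_runs = [r for r, ok in zip(processed, retention.run_valid) if ok]
        result.runs_pp = valid_runs
        result.gray_mask = gray
        result.fcs_maps = fcs_mod.fcs_per_run(valid_runs, gray)
        result.qc["gray_mask_voxels"] = int(gray.sum())
    except Exception as exc:
        raise PipelineError("fcs", sid, exc) from exc

    try:
        frac = asl_glm(subject.asl)
        cbf_map = quantify_cbf(frac, subject.asl.params)
        result.cbf = cbf_map.data
    except Exception as exc:
        raise PipelineError("cbf", sid, exc) from exc

    try:
        pnvf_runs = [
            core.pnvf_map(fm.data, result.cbf, mask=gray,
                          cbf_floor=cfg.cbf_floor, run_index=fm.run_index)
            for fm in result.fcs_maps
        ]
        result.pnvf_runs = pnvf_runs
        result.pnvf_mean = core.average_runs(*pnvf_runs)
    except Exception as exc:
        raise PipelineError("pnvf", sid, exc) from exc
    return result


def run_pipeline(
    spec: CohortSpec | None = None,
    cohort: Cohort | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    run_mediation: bool = True,
    run_co2: bool = True,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Execute the full study on a synthetic (or pre-built) cohort.

    Either ``spec`` (simulated here) or a ready ``cohort`` must be given.
    Emits a structured report; with ``out_dir`` the QC table, cluster
    tables and summary text are also written as CSV/TXT.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if cohort is None:
        if spec is None:
            raise ValueError("need a CohortSpec or a Cohort")
        cohort = simulate_cohort(spec)
    anatomy = cohort.anatomy
    table = cohort.table

    results = [process_subject(s, anatomy, cfg) for s in cohort.subjects]
    qc_rows = []
    for res in results:
        qc_rows.append(
            {
                "subject_id": res.subject_id,
                "group": res.group,
                "subject_valid": res.valid,
                "total_retained": res.retention.total_retained,
                "runs_retained": ";".join(str(r) for r in res.retention.retained_per_run),
                "gray_mask_voxels": res.qc.get("gray_mask_voxels", 0),
            }
        )
    qc = pd.DataFrame(qc_rows)
    report = PipelineReport(config=cfg, qc=qc)
    report.thresholds = {
        "fd_thresh": cfg.fd_thresh,
        "dvars_thresh": cfg.dvars_thresh,
        "gray_threshold": cfg.gray_threshold,
        "group_gray_threshold": cfg.group_gray_threshold,
        "cbf_floor": cfg.cbf_floor,
        "bold_band": cfg.bold_band,
        "co2_band": cfg.co2_band,
        "smooth_sigma_mm": cfg.smooth_sigma_mm,
        "cluster_rule": (cfg.cluster_z, cfg.cluster_extent),
        "relaxed_cluster_rule": (cfg.relaxed_cluster_z, cfg.relaxed_cluster_extent),
        "n_boot": cfg.n_boot,
    }

    valid = [r for r in results if r.valid]
    if len(valid) < 3:
        return report
    valid_ids = {r.subject_id for r in valid}
    sub_table = table[table["subject_id"].isin(valid_ids)].reset_index(drop=True)
    order = {sid: i for i, sid in enumerate(sub_table["subject_id"])}
    valid.sort(key=lambda r: order[r.subject_id])

    try:
        group_mask = core.group_gray_mask(
            [anatomy.gray for _ in valid], threshold=cfg.group_gray_threshold
        )
        filled = [core.fill_missing(r.pnvf_mean, group_mask) for r in valid]
        maps = np.stack([m.data for m in filled])
    except Exception as exc:
        raise PipelineError("group-mask", None, exc) from exc

    # group GLM with cluster calibration
    try:
        X, contrast = stats_mod.build_design(sub_table, "group", ["age", "gender"])
        glm = stats_mod.voxel_glm(maps, X, contrast, group_mask)
        z = stats_mod.t_to_z(glm.t, glm.df)
        z_s = stats_mod.smooth_z(z, cfg.smooth_sigma_mm, group_mask, cfg.voxel_mm)
        fwhm = stats_mod.estimate_smoothness(glm.residuals, group_mask, cfg.voxel_mm)
        calib = stats_mod.calibrate_cluster_threshold(
            group_mask, fwhm, cfg.cluster_z, n_sims=cfg.calibration_sims,
            seed=seed, exogenous_sigma_mm=cfg.smooth_sigma_mm,
            voxel_mm=cfg.voxel_mm, connectivity=cfg.connectivity,
        )
        extent = max(calib.extent_for(cfg.calibration_alpha), 2)
        report.calibration = calib
        report.extent_used = extent
        report.group_z = z_s
        report.group_clusters = stats_mod.extract_clusters(
            z_s, cfg.cluster_z, extent, cfg.connectivity, two_sided=True
        )
    except Exception as exc:
        raise PipelineError("group-glm", None, exc) from exc

    if run_mediation:
        try:
            med = voxelwise_mediation(
                x=sub_table["group"].to_numpy(float),
                maps=maps,
                other=sub_table["cognition"].to_numpy(float),
                maps_role="mediator",
                mask=group_mask,
                covariates=np.column_stack(
                    [sub_table["age"].to_numpy(float), sub_table["gender"].to_numpy(float)]
                ),
                n_boot=cfg.n_boot,
                seed=seed + 1,
                sigma_mm=cfg.smooth_sigma_mm,
                voxel_mm=cfg.voxel_mm,
                z_thresh=cfg.cluster_z,
                extent_min=report.extent_used,
                connectivity=cfg.connectivity,
            )
            report.mediation_clusters = med.clusters
        except Exception as exc:
            raise PipelineError("mediation", None, exc) from exc

    # test-retest over subjects with two valid runs
    try:
        both = [r for r in valid if len(r.pnvf_runs) == 2]
        if len(both) >= 3:
            r1 = np.stack([r.pnvf_runs[0].data for r in both])
            r2 = np.stack([r.pnvf_runs[1].data for r in both])
            gray = both[0].gray_mask
            _, report.retest = core.test_retest_map(
                r1, r2, mask=gray, r_threshold=cfg.retest_r_threshold
            )
    except Exception as exc:
        raise PipelineError("retest", None, exc) from exc

    if run_co2:
        try:
            zs = []
            for r in valid:
                if len(r.runs_pp) != 2 or len(r.pnvf_runs) != 2:
                    continue
                agr = petco2_mod.cross_run_agreement(
                    r.runs_pp[0], r.runs_pp[1],
                    r.pnvf_runs[0].data, r.pnvf_runs[1].data,
                    r.gray_mask, cfg.co2_band[0], cfg.co2_band[1],
                )
                zs.append(agr.fisher_z)
            if len(zs) >= 3:
                report.co2_group = petco2_mod.group_test(zs)
        except Exception as exc:
            raise PipelineError("petco2", None, exc) from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc.to_csv(out / "qc.csv", index=False)
        if report.group_clusters is not None:
            _cluster_frame(report.group_clusters).to_csv(
                out / "group_clusters.csv", index=False
            )
        if report.mediation_clusters is not None:
            _cluster_frame(report.mediation_clusters).to_csv(
                out / "mediation_clusters.csv", index=False
            )
        (out / "summary.txt").write_text("\n".join(report.summary_lines()) + "\n")
    return report


def _cluster_frame(cs: stats_mod.ClusterSet) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": i + 1,
            "size": c.size,
            "peak_z": c.peak_z,
            "peak_i": c.peak_ijk[0],
            "peak_j": c.peak_ijk[1],
            "peak_k": c.peak_ijk[2],
            "sign": c.sign,
        }
        for i, c in enumerate(cs.clusters)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "size", "peak_z",
                                       "peak_i", "peak_j", "peak_k", "sign"])
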