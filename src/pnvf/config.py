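"""Pipeline configuration: every analysis threshold is a config default,
never a hard-coded constant inside a stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .asl import AslParams


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable thresholds of the Pnvf pipeline with their defaults.

    The defaults mirror the acquisition/analysis protocol: gray-matter
    cut > 0.66 (subject) and >= 0.5 (group average); CBF floor
    20 mL/100 g/min; scrubbing at FD > 0.2 mm or DVARS > 25 (mode-1000
    units) with run/subject retention minima of 50/150 frames; BOLD
    passband 0.009-0.08 Hz and CO2-estimator passband 0.02-0.04 Hz;
    z-map smoothing sigma = 4 mm; cluster rules 125 voxels @ Z > 2.5
    (relaxed: 200 @ Z > 2.0 for reduced-n analyses); 1000 bootstrap
    repetitions for mediation.
    """

    gray_threshold: float = 0.66  # strict >
    group_gray_threshold: float = 0.5  # inclusive >=
    cbf_floor: float = 20.0  # mL/100 g/min
    fd_thresh: float = 0.2  # mm
    dvars_thresh: float = 25.0  # mode-1000 units
    min_run_frames: int = 50
    min_total_frames: int = 150
    norm_target: float = 1000.0
    head_radius_mm: float = 50.0
    drift_order: int = 2
    bold_band: tuple = (0.009, 0.08)  # Hz
    co2_band: tuple = (0.02, 0.04)  # Hz
    smooth_sigma_mm: float = 4.0
    cluster_z: float = 2.5
    cluster_extent: int = 125
    relaxed_cluster_z: float = 2.0
    relaxed_cluster_extent: int = 200
    connectivity: int = 26
    n_boot: int = 1000
    calibration_sims: int = 200
    calibration_alpha: float = 0.05
    retest_r_threshold: float = 0.7
    voxel_mm: float = 3.0
    asl: AslParams = field(default_factory=AslParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "asl" in d and isinstance(d["asl"], dict):
            d["asl"] = AslParams(**d["asl"])
        for key in ("bold_band", "co2_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def validate(self) -> None:
        if not (0 < self.gray_threshold < 1):
            raise ConfigError("gray_threshold must be in (0, 1)")
        if self.cbf_floor <= 0:
            raise ConfigError("cbf_floor must be positive")
        lo, hi = self.bold_band
        if not (0 < lo < hi):
            raise ConfigError("invalid BOLD band")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
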