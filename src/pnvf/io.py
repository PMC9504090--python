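"""Volume, trace and table io: NIfTI-1 for volumes, TSV for motion
traces and censor masks, CSV for covariates/manifests/cluster tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preproc import MotionTrace


class IoError(ValueError):
    pass


def save_volume(path, data: np.ndarray, voxel_mm: float = 3.0) -> None:
    """Write a 3-D or 4-D volume as NIfTI-1 with an isotropic affine."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise IoError(f"expected 3-D or 4-D volume, got shape {data.shape}")
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    nib.save(img, str(path))


def load_volume(path, expect_shape: tuple | None = None) -> tuple:
    """Load a NIfTI volume; returns (data, affine).  Round trip preserves
    data to float32 precision and the affine bit-exactly."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise IoError(f"expected 3-D or 4-D volume, got shape {data.shape}")
    if expect_shape is not None and tuple(data.shape[:3]) != tuple(expect_shape):
        raise IoError(
            f"grid mismatch: file has {tuple(data.shape[:3])}, pipeline expects "
            f"{tuple(expect_shape)}"
        )
    return data, img.affine


def save_trace(path, trace: MotionTrace) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    df = pd.DataFrame(
        np.hstack([trace.translations, trace.rotations]), columns=cols
    )
    df.to_csv(path, sep="\t", index=False)


def load_trace(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    return MotionTrace(
        translations=df[["trans_x", "trans_y", "trans_z"]].to_numpy(),
        rotations=df[["rot_x", "rot_y", "rot_z"]].to_numpy(),
    )


def save_censor(path, keep: np.ndarray) -> None:
    pd.DataFrame({"keep": np.asarray(keep, dtype=int)}).to_csv(path, sep="\t", index=False)


def load_censor(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["keep"].to_numpy().astype(bool)


@dataclass
class ManifestEntry:
    subject_id: str
    scan_id: str
    group: int
    run_paths: list
    asl_path: str | None
    run_valid: list
    repeat_scan: bool


@dataclass
class Manifest:
    """Subject -> file mapping with validity flags.

    Repeat scans share a subject id but carry distinct scan ids; ids must
    be unique per scan and every referenced path must exist at load.
    """

    entries: list

    def validate(self, root: Path | None = None) -> None:
        seen = set()
        for e in self.entries:
            if e.scan_id in seen:
                raise IoError(f"duplicate scan id {e.scan_id}")
            seen.add(e.scan_id)
            for p in list(e.run_paths) + ([e.asl_path] if e.asl_path else []):
                full = Path(root) / p if root else Path(p)
                if not full.exists():
                    raise IoError(f"manifest references missing path {full}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "subject_id": e.subject_id,
                    "scan_id": e.scan_id,
                    "group": e.group,
                    "run_paths": ";".join(e.run_paths),
                    "asl_path": e.asl_path or "",
                    "run_valid": ";".join(str(int(v)) for v in e.run_valid),
                    "repeat_scan": int(e.repeat_scan),
                }
            )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, root: Path | None = None) -> "Manifest":
        df = pd.read_csv(path, keep_default_na=False)
        entries = []
        for _, row in df.iterrows():
            entries.append(
                ManifestEntry(
                    subject_id=str(row["subject_id"]),
                    scan_id=str(row["scan_id"]),
                    group=int(row["group"]),
                    run_paths=[p for p in str(row["run_paths"]).split(";") if p],
                    asl_path=str(row["asl_path"]) or None,
                    run_valid=[bool(int(v)) for v in str(row["run_valid"]).split(";") if v != ""],
                    repeat_scan=bool(int(row["repeat_scan"])),
                )
            )
        manifest = cls(entries=entries)
        manifest.validate(root=root)
        return manifest
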