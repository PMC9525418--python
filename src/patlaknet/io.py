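"""File formats: NIfTI image series with JSON sidecars, VOIs, configs.

Each dynamic series is one 4-D NIfTI file plus a JSON sidecar carrying
frame timing, units and subject metadata.  All writes are atomic
(write to a temporary file in the destination directory, then rename).
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .simulate import DynamicSeries

__all__ = [
    "read_series",
    "write_series",
    "atomic_write_json",
    "read_json",
    "RunConfig",
]


def _atomic(path: Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(obj, path) -> None:
    _atomic(Path(path), lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=1)))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_series(series: DynamicSeries, nifti_path, sidecar_path) -> None:
    """Write a series as 4-D NIfTI (x, y, z, t) plus a JSON timing sidecar."""
    # internal (T, S, H, W) -> NIfTI (W, H, S, T)
    data = np.transpose(series.frames, (3, 2, 1, 0))
    affine = np.diag([series.voxel_size_mm, series.voxel_size_mm,
                      series.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    _atomic(Path(nifti_path), lambda tmp: nib.save(img, tmp))
    sidecar = {
        "frames": [{"start_s": s, "duration_s": d} for s, d in series.timing],
        "units": series.units,
        "weight_kg": series.weight_kg,
        "injected_MBq": series.injected_mbq,
        "voxel_size_mm": series.voxel_size_mm,
        "slice_thickness_mm": series.slice_thickness_mm,
    }
    atomic_write_json(sidecar, sidecar_path)


def read_series(nifti_path, sidecar_path) -> DynamicSeries:
    """Load a series written by :func:`write_series`.

    A 3-D NIfTI with a 1-frame sidecar loads as a single-frame series.
    The sidecar frame count must match the NIfTI 4th dimension and the
    units tag must be present.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected 3-D or 4-D NIfTI, got shape {data.shape}")
    sidecar = read_json(sidecar_path)
    if "units" not in sidecar:
        raise ValueError("sidecar is missing the units tag")
    frames_meta = sidecar["frames"]
    if len(frames_meta) != data.shape[3]:
        raise ValueError(
            f"sidecar lists {len(frames_meta)} frames but the NIfTI has "
            f"{data.shape[3]} frames")
    frames = np.transpose(data, (3, 2, 1, 0))  # back to (T, S, H, W)
    return DynamicSeries(
        frames=frames,
        timing=[(f["start_s"], f["duration_s"]) for f in frames_meta],
        voxel_size_mm=float(sidecar.get("voxel_size_mm", abs(img.affine[0, 0]))),
        slice_thickness_mm=float(sidecar.get("slice_thickness_mm", abs(img.affine[2, 2]))),
        units=sidecar["units"],
        weight_kg=sidecar.get("weight_kg"),
        injected_mbq=sidecar.get("injected_MBq"),
    )


def write_volume(volume: np.ndarray, path, voxel_size_mm: float = 4.0,
                 slice_thickness_mm: float = 40.0) -> None:
    """Write a single (S, H, W) volume (e.g. a Ki map) as 3-D NIfTI."""
    data = np.transpose(np.asarray(volume), (2, 1, 0))
    affine = np.diag([voxel_size_mm, voxel_size_mm, slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    _atomic(Path(path), lambda tmp: nib.save(img, tmp))


def read_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.transpose(np.asarray(img.dataobj, dtype=np.float64), (2, 1, 0))


@dataclass
class RunConfig:
    """Fully serializable end-to-end run configuration."""

    seed: int = 0
    n_subjects: int = 19
    matrix: int = 64
    n_slices: int = 120
    slice_thickness_mm: float = 6.4
    voxel_size_mm: float = 4.0
    variability: float = 0.1
    n_lesions_per_subject: int = 3
    noise_scale: float = 1.0
    psf_fwhm_mm: float = 2.0
    config_names: tuple = ("p13-11",)
    t_star_s: float | None = None
    eval_threshold: float = 5e-5
    tbr_threshold: float = 1.5
    n_folds: int = 9
    eval_fold: int = 0
    crop_target: tuple | None = None
    epochs: int = 10
    batch_size: int = 20
    widths: tuple = (8, 16, 24)
    window_size: int | None = 32
    holdout_fraction: float = 0.05
    global_norm: bool = False
    persist_images: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("config_names", "widths", "crop_target"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path) -> None:
        _atomic(Path(path), lambda tmp: Path(tmp).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)))
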