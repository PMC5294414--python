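"""Voxel-volume and annotation I/O with explicit physical calibration.

Every volume carries its isotropic voxel side length in micrometres so that
all downstream morphometry (volumes, areas, diameters) is expressed in
physical units rather than voxels.  Conventions used throughout the package:

* axis order is ``(z, y, x)`` — ``z`` is the scan/stack axis, one TIFF page
  (or one file) per slice;
* all physical coordinates are μm, all index boxes are 0-based half-open;
* the authoritative voxel size comes from a small YAML/JSON sidecar
  (``{"voxel_size_um": <float>}``), never from TIFF resolution tags, which
  vary between scanner export dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "PointAnnotationSet",
    "CalibrationError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "crop_roi",
    "read_points",
    "write_points",
]

POINT_LABELS = ("capillary", "fiber")


class CalibrationError(ValueError):
    """Missing or non-positive physical calibration."""


class VolumeFormatError(ValueError):
    """Malformed volume on disk (missing slices, unequal shapes, ...)."""


def _check_voxel_size(voxel_size_um: float) -> float:
    if not np.isfinite(voxel_size_um) or voxel_size_um <= 0:
        raise CalibrationError(
            f"voxel_size_um must be a positive finite number, got {voxel_size_um!r}"
        )
    return float(voxel_size_um)


@dataclass
class VoxelVolume:
    """A 3D scalar field with isotropic voxel calibration.

    Parameters
    ----------
    data
        3D array in ``(z, y, x)`` order; values must be finite.
    voxel_size_um
        Isotropic voxel side length in μm (> 0).
    name
        Free-text identifier carried through reports.
    """

    data: np.ndarray
    voxel_size_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"volume must be 3D with all dimensions >= 1, got shape {self.data.shape}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise VolumeFormatError("volume contains non-finite values")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_um**3


@dataclass
class BinaryMask:
    """Boolean voxel grid congruent with its source :class:`VoxelVolume`."""

    data: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"mask must be 3D, got shape {self.data.shape}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def volume_um3(self) -> float:
        """Foreground volume in μm³."""
        return self.count() * self.voxel_size_um**3


@dataclass
class PointAnnotationSet:
    """2D point annotations (capillary / fiber centroids) on a section.

    ``points`` is a DataFrame with columns ``x_um``, ``y_um``, ``label``;
    ``extent_um`` is the ``(width, height)`` of the section in μm.
    """

    points: pd.DataFrame
    extent_um: tuple[float, float]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.points, columns=["x_um", "y_um", "label"]).copy()
        w, h = float(self.extent_um[0]), float(self.extent_um[1])
        if w <= 0 or h <= 0:
            raise ValueError(f"extent_um must be strictly positive, got {(w, h)}")
        bad = ~df["label"].isin(POINT_LABELS)
        if bad.any():
            raise ValueError(f"unknown labels: {sorted(df.loc[bad, 'label'].unique())}")
        x = df["x_um"].to_numpy(float)
        y = df["y_um"].to_numpy(float)
        if len(df) and ((x < 0) | (x >= w) | (y < 0) | (y >= h)).any():
            raise ValueError("points must satisfy 0 <= x < width, 0 <= y < height")
        self.points = df
        self.extent_um = (w, h)

    def coords(self, label: str) -> np.ndarray:
        """(n, 2) array of (x_um, y_um) for one label."""
        sel = self.points[self.points["label"] == label]
        return sel[["x_um", "y_um"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# volume I/O


def _read_sidecar(metadata_path: Path) -> float:
    if not metadata_path.exists():
        raise CalibrationError(f"metadata sidecar not found: {metadata_path}")
    text = metadata_path.read_text()
    meta = (
        json.loads(text) if metadata_path.suffix == ".json" else yaml.safe_load(text)
    )
    if not isinstance(meta, dict) or "voxel_size_um" not in meta:
        raise CalibrationError(f"sidecar {metadata_path} lacks 'voxel_size_um'")
    return _check_voxel_size(float(meta["voxel_size_um"]))


def _default_sidecar(path: Path) -> Path:
    if path.is_dir():
        return path / "metadata.yaml"
    return path.with_suffix(".yaml")


def read_volume(path, metadata_path=None) -> VoxelVolume:
    """Read a TIFF stack (multi-page file or directory of per-slice files).

    Slices in a directory are stacked in lexicographic filename order along
    ``z``.  The voxel size comes from the metadata sidecar (YAML or JSON with
    key ``voxel_size_um``); TIFF resolution tags are ignored.
    """
    path = Path(path)
    metadata_path = (
        Path(metadata_path) if metadata_path is not None else _default_sidecar(path)
    )
    voxel_size_um = _read_sidecar(metadata_path)

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix in (".tif", ".tiff"))
        if not files:
            raise VolumeFormatError(f"no TIFF slices in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or any(s.ndim != 2 for s in slices):
            raise VolumeFormatError(f"slice shapes differ or are not 2D: {shapes}")
        data = np.stack(slices, axis=0)
    else:
        if not path.exists():
            raise VolumeFormatError(f"volume not found: {path}")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeFormatError(f"expected 2D/3D TIFF, got ndim={data.ndim}")
    return VoxelVolume(data=data, voxel_size_um=voxel_size_um, name=path.stem)


def write_volume(vol: VoxelVolume, path, metadata_path=None) -> Path:
    """Write a volume as a multi-page TIFF plus a YAML sidecar.

    Inverse of :func:`read_volume`: a write/read roundtrip is bit-identical
    in data and calibration.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    metadata_path = (
        Path(metadata_path) if metadata_path is not None else _default_sidecar(path)
    )
    metadata_path.write_text(yaml.safe_dump({"voxel_size_um": vol.voxel_size_um}))
    return path


def crop_roi(vol: VoxelVolume, bounds: Sequence[Sequence[int]]) -> VoxelVolume:
    """Crop a half-open index box ``[(z0, z1), (y0, y1), (x0, x1))``.

    The result has shape ``hi - lo`` per axis and preserves calibration.
    Nested crops compose: cropping twice equals cropping once with the
    composed box.
    """
    bounds = [(int(lo), int(hi)) for lo, hi in bounds]
    if len(bounds) != 3:
        raise ValueError("bounds must give (lo, hi) for each of the three axes")
    for ax, ((lo, hi), n) in enumerate(zip(bounds, vol.shape)):
        if not (0 <= lo < hi <= n):
            raise IndexError(
                f"axis {ax}: bounds [{lo}, {hi}) invalid for length {n} "
                "(need 0 <= lo < hi <= length)"
            )
    (z0, z1), (y0, y1), (x0, x1) = bounds
    return VoxelVolume(
        data=vol.data[z0:z1, y0:y1, x0:x1].copy(),
        voxel_size_um=vol.voxel_size_um,
        name=vol.name,
    )


# ---------------------------------------------------------------------------
# point-annotation I/O (CSV with header x_um,y_um,label)


def write_points(points: PointAnnotationSet, path) -> Path:
    path = Path(path)
    points.points.to_csv(path, index=False)
    meta = Path(str(path) + ".meta.json")
    meta.write_text(
        json.dumps({"width_um": points.extent_um[0], "height_um": points.extent_um[1]})
    )
    return path


def read_points(path, extent_um=None) -> PointAnnotationSet:
    path = Path(path)
    df = pd.read_csv(path)
    if extent_um is None:
        meta = Path(str(path) + ".meta.json")
        if not meta.exists():
            raise ValueError("extent_um not given and no .meta.json sidecar found")
        m = json.loads(meta.read_text())
        extent_um = (m["width_um"], m["height_um"])
    return PointAnnotationSet(points=df, extent_um=tuple(extent_um))
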