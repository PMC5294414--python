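"""Kernel-based density maps over 2D section annotations.

A square kernel of side ``kernel_size_um`` slides over the section with a
step of ``stride_um``; each map cell holds either the number of capillaries
in the kernel divided by the kernel's in-bounds area (capillary density,
count/μm²) or the capillary-to-fiber ratio.  Point-in-kernel assignment is
half-open (a point exactly on a kernel's upper/right edge belongs to the
next kernel), boundary kernels are normalized by their clipped in-bounds
area, and cf-ratio cells containing no fiber are flagged undefined — 0/0 is
not zero density.  With ``stride == kernel`` (tiling) the density map
conserves counts exactly: Σ cells (value × cell area) equals the number of
capillary points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import PointAnnotationSet

__all__ = ["DensityMap", "capillary_density_map", "cf_ratio_map", "render_density_map"]


@dataclass
class DensityMap:
    """2D grid of per-kernel values.

    ``grid[j, i]`` covers ``x ∈ [i·stride, i·stride + kernel)`` and
    ``y ∈ [j·stride, j·stride + kernel)``, clipped to the section.
    ``defined[j, i]`` is False where the value is undefined (cf ratio with
    zero fibers); undefined cells hold NaN, never a numeric sentinel.
    """

    grid: np.ndarray
    defined: np.ndarray
    kernel_size_um: float
    stride_um: float
    extent_um: tuple[float, float]
    value_kind: str  # "count_per_um2" | "cf_ratio"

    def __post_init__(self) -> None:
        if self.value_kind not in ("count_per_um2", "cf_ratio"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if not (self.kernel_size_um >= self.stride_um > 0):
            raise ValueError("need kernel_size_um >= stride_um > 0")
        self.grid = np.asarray(self.grid, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        vals = self.grid[self.defined]
        if vals.size and (vals < 0).any():
            raise ValueError("defined map values must be >= 0")

    @property
    def is_tiled(self) -> bool:
        return self.stride_um == self.kernel_size_um

    def cell_bounds_um(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the clipped kernel at column i, row j."""
        w, h = self.extent_um
        x0, y0 = i * self.stride_um, j * self.stride_um
        return (x0, min(x0 + self.kernel_size_um, w), y0, min(y0 + self.kernel_size_um, h))

    def cell_area_um2(self, i: int, j: int) -> float:
        x0, x1, y0, y1 = self.cell_bounds_um(i, j)
        return (x1 - x0) * (y1 - y0)

    def write(self, path_prefix) -> dict[str, Path]:
        """Write the grid as CSV plus a JSON metadata sidecar."""
        prefix = Path(path_prefix)
        csv_path = prefix.with_suffix(".csv")
        np.savetxt(csv_path, self.grid, delimiter=",", fmt="%.10g")
        meta_path = prefix.with_suffix(".json")
        meta_path.write_text(
            json.dumps(
                {
                    "kernel_size_um": self.kernel_size_um,
                    "stride_um": self.stride_um,
                    "extent_um": list(self.extent_um),
                    "value_kind": self.value_kind,
                    "units": "1/um^2" if self.value_kind == "count_per_um2" else "ratio",
                    "shape": list(self.grid.shape),
                    "n_undefined": int((~self.defined).sum()),
                },
                indent=2,
            )
        )
        return {"csv": csv_path, "meta": meta_path}


def _grid_counts(
    coords: np.ndarray,
    extent_um: tuple[float, float],
    kernel_size_um: float,
    stride_um: float,
) -> np.ndarray:
    """Per-cell point counts for half-open kernels clipped to the extent."""
    w, h = extent_um
    nx = max(int(np.ceil((w - 1e-12) / stride_um)), 1)
    ny = max(int(np.ceil((h - 1e-12) / stride_um)), 1)
    counts = np.zeros((ny, nx), dtype=int)
    if len(coords) == 0:
        return counts
    x, y = coords[:, 0], coords[:, 1]
    for j in range(ny):
        y0 = j * stride_um
        y1 = min(y0 + kernel_size_um, h)
        in_y = (y >= y0) & (y < y1)
        for i in range(nx):
            x0 = i * stride_um
            x1 = min(x0 + kernel_size_um, w)
            counts[j, i] = int(np.count_nonzero(in_y & (x >= x0) & (x < x1)))
    return counts


def _check_params(points: PointAnnotationSet, kernel_size_um: float, stride_um: float):
    if kernel_size_um <= 0 or stride_um <= 0:
        raise ValueError("kernel_size_um and stride_um must be > 0")
    if stride_um > kernel_size_um:
        raise ValueError("stride_um must not exceed kernel_size_um")
    if kernel_size_um > max(points.extent_um):
        raise ValueError("kernel must not exceed the section extent")


def capillary_density_map(
    points: PointAnnotationSet,
    kernel_size_um: float,
    stride_um: float | None = None,
) -> DensityMap:
    """Capillary density (count per μm²) per kernel.

    Default stride is ``kernel/2`` (sliding mode, smoother maps); pass
    ``stride_um = kernel_size_um`` for the tiled mode with exact count
    conservation.
    """
    if stride_um is None:
        stride_um = kernel_size_um / 2.0
    _check_params(points, kernel_size_um, stride_um)
    caps = _grid_counts(points.coords("capillary"), points.extent_um,
                        kernel_size_um, stride_um)
    grid = np.empty(caps.shape, dtype=float)
    for j in range(caps.shape[0]):
        for i in range(caps.shape[1]):
            x0 = i * stride_um
            y0 = j * stride_um
            area = (min(x0 + kernel_size_um, points.extent_um[0]) - x0) * (
                min(y0 + kernel_size_um, points.extent_um[1]) - y0
            )
            grid[j, i] = caps[j, i] / area
    return DensityMap(
        grid=grid,
        defined=np.ones(caps.shape, dtype=bool),
        kernel_size_um=kernel_size_um,
        stride_um=stride_um,
        extent_um=points.extent_um,
        value_kind="count_per_um2",
    )


def cf_ratio_map(
    points: PointAnnotationSet,
    kernel_size_um: float,
    stride_um: float | None = None,
) -> DensityMap:
    """Capillary-to-fiber ratio per kernel; fiber-free kernels are undefined."""
    if stride_um is None:
        stride_um = kernel_size_um / 2.0
    _check_params(points, kernel_size_um, stride_um)
    caps = _grid_counts(points.coords("capillary"), points.extent_um,
                        kernel_size_um, stride_um)
    fibs = _grid_counts(points.coords("fiber"), points.extent_um,
                        kernel_size_um, stride_um)
    defined = fibs > 0
    grid = np.full(caps.shape, np.nan)
    np.divide(caps, fibs, out=grid, where=defined)
    return DensityMap(
        grid=grid,
        defined=defined,
        kernel_size_um=kernel_size_um,
        stride_um=stride_um,
        extent_um=points.extent_um,
        value_kind="cf_ratio",
    )


def render_density_map(dmap: DensityMap, path, cmap: str = "viridis") -> Path:
    """Render the map as a heat map PNG.

    Uses a perceptually uniform colormap with the value range stated in the
    colorbar label; undefined cells render grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.6")
    masked = np.ma.masked_invalid(dmap.grid)
    im = ax.imshow(
        masked,
        origin="lower",
        cmap=cm,
        extent=(0, dmap.extent_um[0], 0, dmap.extent_um[1]),
    )
    unit = "capillaries / μm²" if dmap.value_kind == "count_per_um2" else "capillary : fiber"
    vmin, vmax = (float(masked.min()), float(masked.max())) if masked.count() else (0, 0)
    fig.colorbar(im, ax=ax, label=f"{unit}  (range {vmin:.3g}–{vmax:.3g})")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(
        f"{dmap.value_kind}  kernel {dmap.kernel_size_um:g} μm, stride {dmap.stride_um:g} μm"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
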