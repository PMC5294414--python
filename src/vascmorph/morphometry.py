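"""3D vascular morphometry: volume fraction, vessel-size distributions on
equidistant virtual sections, and multi-stage shrinkage estimation.

The size estimator is the equivalent-circle diameter ``d = 2 sqrt(A / π)``
of each 8-connected vessel profile on transverse virtual sections — the
simplest fully specified estimator for a section-based protocol.  Profiles
touching the section border are censored from size statistics by default
(truncated profiles bias diameters downward) but still count toward volume
fractions.  Shrinkage between preparation stages is reported under both the
retained-percent and shrinkage-percent conventions simultaneously, since
published figures mix the two readings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .volume_io import BinaryMask

__all__ = [
    "VesselCrossSection",
    "DiameterDistribution",
    "ShrinkageReport",
    "vascular_volume_fraction",
    "extract_equidistant_sections",
    "measure_cross_sections",
    "diameter_distribution",
    "compare_size_distributions",
    "shrinkage_report",
    "DEFAULT_BIN_WIDTH_UM",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_UM = 5.0


@dataclass
class VesselCrossSection:
    """One vessel profile on a virtual section."""

    section_index: int
    area_um2: float
    equiv_diameter_um: float
    centroid_um: tuple[float, float]

    def __post_init__(self) -> None:
        expected = 2.0 * math.sqrt(self.area_um2 / math.pi)
        if not math.isclose(self.equiv_diameter_um, expected, rel_tol=1e-12):
            raise ValueError("equiv_diameter_um must equal 2*sqrt(area/pi)")


@dataclass
class DiameterDistribution:
    """Binned relative proportions of vessel diameters plus the median.

    Bins are half-open ``[lo, hi)``.  ``n == 0`` marks an empty
    distribution whose median is undefined (NaN).
    """

    bin_edges_um: np.ndarray
    proportions: np.ndarray
    n: int
    median_um: float
    diameters_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.n > 0 and abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1 for n > 0")

    @property
    def is_empty(self) -> bool:
        return self.n == 0


def vascular_volume_fraction(vessel: BinaryMask, tissue: BinaryMask) -> float:
    """Vascular volume fraction vv/tv = |vessel ∧ tissue| / |tissue|.

    Vessel voxels outside the tissue mask are excluded from the numerator
    and their count is logged.  Both masks must be congruent in shape and
    calibration.
    """
    if vessel.shape != tissue.shape:
        raise ValueError(
            f"mask shapes differ: {vessel.shape} vs {tissue.shape}"
        )
    if not math.isclose(vessel.voxel_size_um, tissue.voxel_size_um):
        raise ValueError("masks must share the same voxel size")
    tv = int(tissue.data.sum())
    if tv == 0:
        raise ZeroDivisionError("tissue mask is empty")
    vv = int((vessel.data & tissue.data).sum())
    outside = int(vessel.data.sum()) - vv
    if outside:
        logger.info("vascular_volume_fraction: %d vessel voxels outside tissue", outside)
    return vv / tv


def extract_equidistant_sections(
    mask: BinaryMask, n_sections: int, axis: int = 0
) -> list[np.ndarray]:
    """Extract ``n`` equidistant 2D sections along an axis.

    Section indices follow the midpoint rule ``i_k = round((k + 0.5) L / n)``
    with exact halves rounding down (so ``n == L`` selects every slice); any
    rounding collision is resolved by shifting the later index forward by
    one, keeping the list strictly increasing.
    """
    L = mask.shape[axis]
    if not (1 <= n_sections <= L):
        raise ValueError(f"n_sections must be in [1, {L}], got {n_sections}")
    indices: list[int] = []
    for k in range(n_sections):
        i = min(int(math.ceil((k + 0.5) * L / n_sections - 0.5)), L - 1)
        while indices and i <= indices[-1]:
            i += 1
        if i >= L:
            raise ValueError("section indices exceed axis length after collision fix")
        indices.append(i)
    return [np.take(mask.data, i, axis=axis) for i in indices]


def section_indices(length: int, n_sections: int) -> list[int]:
    """The index list used by :func:`extract_equidistant_sections`."""
    if not (1 <= n_sections <= length):
        raise ValueError(f"n_sections must be in [1, {length}]")
    indices: list[int] = []
    for k in range(n_sections):
        i = min(int(math.ceil((k + 0.5) * length / n_sections - 0.5)), length - 1)
        while indices and i <= indices[-1]:
            i += 1
        indices.append(i)
    return indices


def measure_cross_sections(
    section: np.ndarray,
    voxel_size_um: float,
    min_area_px: int = 1,
    border_policy: str = "exclude",
    section_index: int = 0,
) -> list[VesselCrossSection]:
    """Measure vessel profiles on one binary section.

    8-connected foreground components become cross-sections with
    ``area = pixels × voxel_size²`` and equivalent-circle diameter
    ``2 sqrt(A/π)``.  Components smaller than ``min_area_px`` are dropped;
    ``border_policy`` ("include"/"exclude") governs components touching the
    section edge.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if border_policy not in ("include", "exclude"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    section = np.asarray(section).astype(bool)
    labeled = label(section, connectivity=2)
    out: list[VesselCrossSection] = []
    h, w = section.shape
    for rp in regionprops(labeled):
        if rp.area < min_area_px:
            continue
        if border_policy == "exclude":
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        area_um2 = float(rp.area) * voxel_size_um**2
        out.append(
            VesselCrossSection(
                section_index=section_index,
                area_um2=area_um2,
                equiv_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
                centroid_um=(
                    float(rp.centroid[1]) * voxel_size_um,
                    float(rp.centroid[0]) * voxel_size_um,
                ),
            )
        )
    return out


def diameter_distribution(
    cross_sections: list[VesselCrossSection],
    bin_edges_um: np.ndarray | None = None,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> DiameterDistribution:
    """Bin per-profile equivalent diameters into relative proportions.

    Bins are half-open ``[lo, hi)``; if the given edges do not cover the
    observed diameters an overflow bin is appended (and a leading bin
    prepended for undershoot).  The median is the empirical median of the
    pooled per-cross-section diameters — each profile counts once,
    regardless of which section it came from.  Without explicit edges,
    uniform bins of ``bin_width_um`` from 0 to the observed maximum are
    used.
    """
    d = np.asarray([cs.equiv_diameter_um for cs in cross_sections], dtype=float)
    n = len(d)
    if bin_edges_um is None:
        top = float(d.max()) if n else bin_width_um
        n_bins = max(int(math.ceil(top / bin_width_um)), 1)
        if n and top >= n_bins * bin_width_um:  # max exactly on an edge
            n_bins += 1
        bin_edges_um = np.arange(n_bins + 1) * bin_width_um
    edges = np.asarray(bin_edges_um, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if n:
        if d.max() >= edges[-1]:
            edges = np.append(edges, max(d.max() * (1 + 1e-12), edges[-1] + 1e-9))
        if d.min() < edges[0]:
            edges = np.insert(edges, 0, d.min())
    if n == 0:
        return DiameterDistribution(
            bin_edges_um=edges,
            proportions=np.zeros(len(edges) - 1),
            n=0,
            median_um=float("nan"),
        )
    # np.digitize with right=False gives half-open [lo, hi) assignment
    which = np.digitize(d, edges, right=False) - 1
    counts = np.bincount(which, minlength=len(edges) - 1)
    return DiameterDistribution(
        bin_edges_um=edges,
        proportions=counts / n,
        n=n,
        median_um=float(np.median(d)),
        diameters_um=np.sort(d),
    )


def compare_size_distributions(
    a: DiameterDistribution, b: DiameterDistribution
) -> dict:
    """Per-bin proportion ratios a/b and the median shift a − b (μm).

    Bins where ``b`` has zero proportion are flagged (ratio NaN), never
    divided.  Requires identical bin edges and non-empty distributions.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("cannot compare empty distributions")
    if len(a.bin_edges_um) != len(b.bin_edges_um) or not np.allclose(
        a.bin_edges_um, b.bin_edges_um
    ):
        raise ValueError("distributions must share identical bin edges")
    undefined = b.proportions == 0
    ratio = np.full_like(a.proportions, np.nan)
    np.divide(a.proportions, b.proportions, out=ratio, where=~undefined)
    return {
        "bin_edges_um": a.bin_edges_um.copy(),
        "ratio": ratio,
        "undefined": undefined,
        "median_shift_um": a.median_um - b.median_um,
    }


@dataclass
class ShrinkageReport:
    """Stage-to-stage retained and shrinkage percentages.

    For each consecutive stage pair, ``retained_percent = 100 · later /
    earlier`` and ``shrinkage_percent = 100 − retained_percent``.  Both are
    reported because published shrinkage figures mix the two conventions
    (a "109%" can mean retained volume, a "63%" volume lost).
    """

    labels: list[str]
    measurements: list[float]
    retained_percent: list[float]
    shrinkage_percent: list[float]

    def pairs(self) -> list[dict]:
        return [
            {
                "from": self.labels[i],
                "to": self.labels[i + 1],
                "retained_percent": self.retained_percent[i],
                "shrinkage_percent": self.shrinkage_percent[i],
            }
            for i in range(len(self.retained_percent))
        ]

    def cumulative_scale_factor(self) -> float:
        """Isotropic linear scale factor from first to last stage
        (cube root of the retained volume fraction)."""
        return (self.measurements[-1] / self.measurements[0]) ** (1.0 / 3.0)


def shrinkage_report(stage_measurements: list[tuple[str, float]]) -> ShrinkageReport:
    """Compute stage-to-stage shrinkage from ordered (label, measurement).

    Measurements are volumes (μm³) or areas (μm²); only ratios are used, so
    the unit must merely be consistent across stages.
    """
    if len(stage_measurements) < 2:
        raise ValueError("need at least two stages")
    labels = [str(lab) for lab, _ in stage_measurements]
    values = [float(v) for _, v in stage_measurements]
    if any(v <= 0 for v in values):
        raise ValueError("stage measurements must be positive")
    retained = [100.0 * values[i + 1] / values[i] for i in range(len(values) - 1)]
    return ShrinkageReport(
        labels=labels,
        measurements=values,
        retained_percent=retained,
        shrinkage_percent=[100.0 - r for r in retained],
    )
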