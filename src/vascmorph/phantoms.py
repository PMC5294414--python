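"""Ground-truthed synthetic phantoms for vascular morphometry.

Three generators emulate the statistical structure the analysis pipeline
assumes, each fully seeded and reproducible:

* hierarchical branching vessel trees obeying Murray's law
  (``parent_r^m = sum(child_r^m)`` exactly at every bifurcation, default
  ``m = 3``), with optional tortuosity, rasterized into noisy grayscale
  volumes with exact binary truth masks;
* 2D muscle cross-section scenes — fibers on a jittered hexagonal lattice
  with capillaries placed around fiber boundaries at a spatially varying
  expected capillary-to-fiber ratio;
* hierarchical dual-label capillary classification counts (animal →
  section → field of view) drawn from stated true proportions.

Geometry convention: all 3D points are ``(z, y, x)`` in μm, matching the
volume axis order, so voxel index ``(k, j, i)`` has its center at
``origin_um + (index + 0.5) * voxel_size_um`` componentwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .volume_io import BinaryMask, PointAnnotationSet, VoxelVolume

__all__ = [
    "VesselSegment",
    "VesselTree",
    "ClassificationCounts",
    "generate_vessel_tree",
    "rasterize_tree",
    "generate_histology_scene",
    "generate_classification_counts",
    "murray_residuals",
]

logger = logging.getLogger(__name__)

# Terminal capillary radii of the default tree land at ~3.2 μm (6.3 μm
# diameter), inside the physiological 2.5–4 μm capillary band, so phantoms
# contain vessels both above and below the 10 μm visibility scale of
# overview-resolution scans.
DEFAULT_ROOT_RADIUS_UM = 8.0
DEFAULT_DEPTH = 4
DEFAULT_BRANCH_ANGLE_DEG = 37.0
DEFAULT_LENGTH_RADIUS_RATIO = 8.0


@dataclass
class VesselSegment:
    """One vessel segment: a polyline with a constant radius.

    ``p0``/``p1`` are the endpoints in μm, ``(z, y, x)`` order; ``points``
    is the full polyline (straight segments have just the two endpoints;
    tortuous ones carry interior points).  ``parent`` is the index of the
    parent segment in the owning tree (-1 for the root).
    """

    p0: np.ndarray
    p1: np.ndarray
    radius_um: float
    generation: int = 0
    parent: int = -1
    points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.radius_um <= 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")
        if np.allclose(self.p0, self.p1):
            raise ValueError("segment endpoints must differ")
        if self.points is None:
            self.points = np.stack([self.p0, self.p1])
        self.points = np.asarray(self.points, dtype=float)

    @property
    def length_um(self) -> float:
        """Arc length of the polyline (tortuous length, not the chord)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_um(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def volume_um3(self) -> float:
        """Cylinder volume π r² L along the polyline."""
        return math.pi * self.radius_um**2 * self.length_um


@dataclass
class VesselTree:
    """A connected binary tree of vessel segments."""

    segments: list[VesselSegment]
    murray_exponent: float = 3.0
    tortuosity_amplitude_um: float = 0.0
    seed: int = 0

    def children_of(self, index: int) -> list[int]:
        return [i for i, s in enumerate(self.segments) if s.parent == index]

    def total_volume_um3(self) -> float:
        """Analytic Σ π r² L over all segments (no cap/junction correction)."""
        return sum(s.volume_um3 for s in self.segments)

    def bounding_box_um(self, margin_um: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners in μm enclosing all polylines dilated by radius."""
        los, his = [], []
        for s in self.segments:
            los.append(s.points.min(axis=0) - s.radius_um - margin_um)
            his.append(s.points.max(axis=0) + s.radius_um + margin_um)
        return np.min(los, axis=0), np.max(his, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Truth table: one row per segment (endpoints, radius, generation)."""
        rows = []
        for i, s in enumerate(self.segments):
            rows.append(
                {
                    "segment": i,
                    "parent": s.parent,
                    "generation": s.generation,
                    "z0_um": s.p0[0], "y0_um": s.p0[1], "x0_um": s.p0[2],
                    "z1_um": s.p1[0], "y1_um": s.p1[1], "x1_um": s.p1[2],
                    "radius_um": s.radius_um,
                    "length_um": s.length_um,
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def murray_residuals(tree: VesselTree) -> np.ndarray:
    """Relative Murray-law residual |r_p^m − Σ r_c^m| / r_p^m per bifurcation."""
    m = tree.murray_exponent
    res = []
    for i, seg in enumerate(tree.segments):
        kids = tree.children_of(i)
        if kids:
            rp = seg.radius_um**m
            rc = sum(tree.segments[k].radius_um**m for k in kids)
            res.append(abs(rp - rc) / rp)
    return np.asarray(res)


# ---------------------------------------------------------------------------
# tree generation


def _perpendicular_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane perpendicular to d."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _tortuous_polyline(
    p0: np.ndarray,
    p1: np.ndarray,
    amplitude_um: float,
    rng: np.random.Generator,
    step_um: float = 4.0,
) -> np.ndarray:
    """Smooth seeded perturbation of a straight segment.

    Interior points are displaced perpendicular to the chord by a sum of two
    sine harmonics with random phase/direction; endpoints stay fixed so tree
    connectivity is preserved.  The resulting path length exceeds the chord
    (tortuosity index > 1) by an amount controlled by ``amplitude_um``.
    """
    chord = p1 - p0
    length = np.linalg.norm(chord)
    n = max(int(math.ceil(length / step_um)), 2)
    t = np.linspace(0.0, 1.0, n + 1)
    base = p0[None, :] + t[:, None] * chord[None, :]
    if amplitude_um <= 0:
        return np.stack([p0, p1])
    d = chord / length
    u, v = _perpendicular_basis(d)
    phases = rng.uniform(0, 2 * math.pi, size=2)
    angles = rng.uniform(0, 2 * math.pi, size=2)
    disp = np.zeros_like(base)
    for h, (phase, ang, amp) in enumerate(
        zip(phases, angles, (amplitude_um, amplitude_um / 2.0)), start=1
    ):
        direction = math.cos(ang) * u + math.sin(ang) * v
        profile = amp * np.sin(math.pi * h * t + phase) * np.sin(math.pi * t)
        disp += profile[:, None] * direction[None, :]
    out = base + disp
    out[0], out[-1] = p0, p1  # endpoints exact, so child segments connect
    return out


def _rotate_about(d: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of d about a unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return d * c + np.cross(axis, d) * s + axis * np.dot(axis, d) * (1 - c)


def generate_vessel_tree(
    root_radius_um: float = DEFAULT_ROOT_RADIUS_UM,
    depth: int = DEFAULT_DEPTH,
    branch_angle_deg: float = DEFAULT_BRANCH_ANGLE_DEG,
    tortuosity_amplitude_um: float = 0.0,
    murray_exponent: float = 3.0,
    seed: int = 0,
    *,
    length_radius_ratio: float = DEFAULT_LENGTH_RADIUS_RATIO,
    split_fraction: float = 0.5,
    root_point_um: Sequence[float] = (0.0, 0.0, 0.0),
    root_direction: Sequence[float] = (1.0, 0.0, 0.0),
) -> VesselTree:
    """Grow a binary branching tree satisfying Murray's law exactly.

    Each segment has length ``length_radius_ratio * radius``; at every
    bifurcation the flow split ``split_fraction : 1 - split_fraction``
    determines child radii as ``r_child = r_parent * fraction**(1/m)``, which
    conserves ``r^m`` exactly.  With the default symmetric split both
    children get ``r_parent * 2**(-1/m)``.  Child directions deviate from
    the parent by ``branch_angle_deg`` at a seeded random azimuth; segments
    are optionally made tortuous (see ``_tortuous_polyline``).

    ``depth`` counts bifurcation levels: depth 0 is a single straight (or
    tortuous) root segment.
    """
    if root_radius_um <= 0:
        raise ValueError(f"root_radius_um must be > 0, got {root_radius_um}")
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if not (0 < split_fraction < 1):
        raise ValueError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = float(murray_exponent)
    angle = math.radians(branch_angle_deg)

    segments: list[VesselSegment] = []
    # stack of (parent_index, start_point, direction, radius, generation)
    stack = [
        (
            -1,
            np.asarray(root_point_um, dtype=float),
            np.asarray(root_direction, dtype=float)
            / np.linalg.norm(root_direction),
            float(root_radius_um),
            0,
        )
    ]
    while stack:
        parent, p0, d, r, gen = stack.pop(0)
        p1 = p0 + d * (length_radius_ratio * r)
        pts = _tortuous_polyline(p0, p1, tortuosity_amplitude_um, rng)
        seg = VesselSegment(
            p0=p0, p1=p1, radius_um=r, generation=gen, parent=parent, points=pts
        )
        segments.append(seg)
        idx = len(segments) - 1
        if gen < depth:
            fracs = (split_fraction, 1.0 - split_fraction)
            azim = rng.uniform(0.0, 2.0 * math.pi)
            u, v = _perpendicular_basis(d)
            for k, frac in enumerate(fracs):
                r_child = r * frac ** (1.0 / m)
                axis = math.cos(azim) * u + math.sin(azim) * v
                sign = 1.0 if k == 0 else -1.0
                d_child = _rotate_about(d, axis, sign * angle)
                d_child /= np.linalg.norm(d_child)
                stack.append((idx, p1.copy(), d_child, r_child, gen + 1))
    return VesselTree(
        segments=segments,
        murray_exponent=m,
        tortuosity_amplitude_um=tortuosity_amplitude_um,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rasterization


def _paint_edge(
    inside: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    radius_um: float,
    voxel_size_um: float,
    origin_um: np.ndarray,
) -> None:
    """Mark voxels whose center lies within ``radius`` of edge [a, b]."""
    shape = np.asarray(inside.shape)
    lo_um = np.minimum(a, b) - radius_um
    hi_um = np.maximum(a, b) + radius_um
    lo = np.maximum(np.floor((lo_um - origin_um) / voxel_size_um).astype(int), 0)
    hi = np.minimum(
        np.ceil((hi_um - origin_um) / voxel_size_um).astype(int) + 1, shape
    )
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *(
            origin_um[ax] + (np.arange(lo[ax], hi[ax]) + 0.5) * voxel_size_um
            for ax in range(3)
        ),
        indexing="ij",
    )
    centers = np.stack(grids, axis=-1)
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0.0:
        dist2 = ((centers - a) ** 2).sum(axis=-1)
    else:
        t = np.clip(((centers - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        dist2 = ((centers - proj) ** 2).sum(axis=-1)
    sub = inside[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= dist2 <= radius_um**2


def rasterize_tree(
    tree: VesselTree,
    voxel_size_um: float,
    volume_shape: tuple[int, int, int] | None = None,
    fg_intensity: float = 200.0,
    bg_intensity: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    origin_um: Sequence[float] | None = None,
    margin_um: float = 5.0,
) -> tuple[VoxelVolume, BinaryMask]:
    """Rasterize a tree into a noisy grayscale volume plus exact truth mask.

    The truth mask marks every voxel whose center lies within the segment
    radius of any polyline (point-to-polyline Euclidean distance, membership
    decided at the voxel center).  The grayscale volume takes ``fg`` inside
    and ``bg`` outside with seeded additive Gaussian noise, emulating the
    homogeneous bright signal of a polymerizing contrast agent against
    tissue background.

    If ``volume_shape`` is omitted the volume is sized to the tree's
    bounding box plus ``margin_um``.  Segments extending beyond the volume
    are clipped and logged.  A voxel size exceeding the smallest radius
    triggers a warning (sub-voxel vessels can vanish), not an error.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be > 0")
    if fg_intensity == bg_intensity:
        raise ValueError("fg and bg intensities must be distinct")
    if origin_um is None or volume_shape is None:
        if tree.segments:
            lo, hi = tree.bounding_box_um(margin_um)
        else:
            lo, hi = np.zeros(3), np.full(3, max(margin_um, voxel_size_um))
        if origin_um is None:
            origin_um = lo
        if volume_shape is None:
            volume_shape = tuple(
                int(math.ceil(v / voxel_size_um)) for v in (hi - np.asarray(origin_um))
            )
    origin = np.asarray(origin_um, dtype=float)
    shape = tuple(int(s) for s in volume_shape)

    if tree.segments:
        r_min = min(s.radius_um for s in tree.segments)
        if voxel_size_um > r_min:
            logger.warning(
                "voxel size %.3g μm exceeds smallest vessel radius %.3g μm; "
                "sub-voxel vessels may vanish",
                voxel_size_um,
                r_min,
            )

    inside = np.zeros(shape, dtype=bool)
    hi_um = origin + np.asarray(shape) * voxel_size_um
    for i, seg in enumerate(tree.segments):
        if np.any(seg.points.min(axis=0) - seg.radius_um < origin) or np.any(
            seg.points.max(axis=0) + seg.radius_um > hi_um
        ):
            logger.info("segment %d extends beyond the volume; clipping", i)
        for a, b in zip(seg.points[:-1], seg.points[1:]):
            _paint_edge(inside, a, b, seg.radius_um, voxel_size_um, origin)

    rng = np.random.default_rng(seed)
    data = np.where(inside, float(fg_intensity), float(bg_intensity))
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=shape)
    vol = VoxelVolume(data=data.astype(np.float32), voxel_size_um=voxel_size_um,
                      name="phantom")
    mask = BinaryMask(data=inside, voxel_size_um=voxel_size_um)
    return vol, mask


# ---------------------------------------------------------------------------
# 2D histology scenes


def generate_histology_scene(
    extent_um: tuple[float, float],
    fiber_pitch_um: float = 50.0,
    capillary_per_fiber_profile: float | Callable[[float, float], float] = 1.5,
    seed: int = 0,
    *,
    jitter_frac: float = 0.08,
) -> PointAnnotationSet:
    """Synthesize a muscle cross-section point scene.

    Fibers sit on a jittered hexagonal lattice with the given pitch (the
    default 50 μm matches typical murine fiber diameters).  Around each
    fiber, a Poisson-distributed number of capillaries with mean
    ``profile(x, y)`` is placed at the fiber boundary (radius ≈ pitch / 2),
    so the expected capillary-to-fiber ratio at position (x, y) equals the
    profile there.  Capillary positions are clipped into the section extent
    so counts are conserved.  The profile may be a constant or a callable
    ``(x_um, y_um) -> expected capillaries per fiber``, allowing the
    deep-vs-superficial density gradients seen in real muscle.
    """
    w, h = float(extent_um[0]), float(extent_um[1])
    if w <= 0 or h <= 0:
        raise ValueError("extent_um must be strictly positive")
    if fiber_pitch_um >= min(w, h):
        raise ValueError("fiber_pitch_um must be smaller than the section extent")
    if callable(capillary_per_fiber_profile):
        profile = capillary_per_fiber_profile
    else:
        c = float(capillary_per_fiber_profile)
        profile = lambda x, y: c  # noqa: E731

    rng = np.random.default_rng(seed)
    eps = 1e-9
    row_pitch = fiber_pitch_um * math.sqrt(3.0) / 2.0
    rows = []
    j = 0
    y = fiber_pitch_um / 2.0
    while y < h:
        x0 = fiber_pitch_um / 2.0 + (fiber_pitch_um / 2.0 if j % 2 else 0.0)
        x = x0
        while x < w:
            rows.append((x, y))
            x += fiber_pitch_um
        y += row_pitch
        j += 1
    fibers = np.asarray(rows, dtype=float)
    if len(fibers):
        fibers += rng.normal(0.0, jitter_frac * fiber_pitch_um, size=fibers.shape)
        fibers[:, 0] = np.clip(fibers[:, 0], 0.0, w - eps)
        fibers[:, 1] = np.clip(fibers[:, 1], 0.0, h - eps)

    records = [
        {"x_um": fx, "y_um": fy, "label": "fiber"} for fx, fy in fibers
    ]
    for fx, fy in fibers:
        lam = max(float(profile(fx, fy)), 0.0)
        k = rng.poisson(lam)
        if k == 0:
            continue
        ang = rng.uniform(0.0, 2.0 * math.pi, size=k)
        rad = fiber_pitch_um / 2.0 * rng.uniform(0.85, 1.05, size=k)
        cx = np.clip(fx + rad * np.cos(ang), 0.0, w - eps)
        cy = np.clip(fy + rad * np.sin(ang), 0.0, h - eps)
        records.extend(
            {"x_um": float(a), "y_um": float(b), "label": "capillary"}
            for a, b in zip(cx, cy)
        )
    df = pd.DataFrame(records, columns=["x_um", "y_um", "label"])
    return PointAnnotationSet(points=df, extent_um=(w, h))


# ---------------------------------------------------------------------------
# dual-label classification counts


@dataclass
class ClassificationCounts:
    """Hierarchical dual-label capillary counts.

    One row per field of view with columns ``animal``, ``section``, ``fov``,
    ``n_pp`` (μAF+/L+), ``n_pm`` (μAF+/L−), ``n_mp`` (μAF−/L+).  A
    doubly-negative category does not exist: a capillary must be detected by
    at least one label to be counted at all.
    """

    table: pd.DataFrame
    design: dict = field(default_factory=dict)

    COLUMNS = ("animal", "section", "fov", "n_pp", "n_pm", "n_mp")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        for c in ("n_pp", "n_pm", "n_mp"):
            if (df[c] < 0).any():
                raise ValueError(f"negative counts in column {c}")
        self.table = df[list(self.COLUMNS)].reset_index(drop=True)

    def total(self) -> int:
        return int(self.table[["n_pp", "n_pm", "n_mp"]].to_numpy().sum())

    def per_animal(self) -> pd.DataFrame:
        return self.table.groupby("animal")[["n_pp", "n_pm", "n_mp"]].sum()

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path) -> "ClassificationCounts":
        return cls(table=pd.read_csv(path))


def generate_classification_counts(
    true_props: tuple[float, float, float],
    n_animals: int = 3,
    sections_per_animal: int = 3,
    fovs_per_section: int = 4,
    capillaries_per_fov: int = 105,
    seed: int = 0,
) -> ClassificationCounts:
    """Draw per-FOV dual-label counts from true category proportions.

    ``true_props = (p_pp, p_pm, p_mp)`` must sum to 1 (tolerance 1e-9).
    Per-FOV totals are Poisson-distributed around ``capillaries_per_fov``
    (emulating the natural variation in capillaries per field) and each
    total is split by a multinomial draw with the true proportions.  The
    defaults mirror a stereological design of 3 sections per muscle with 4
    systematically sampled fields per section and roughly 1250 capillaries
    evaluated per animal.
    """
    props = np.asarray(true_props, dtype=float)
    if props.shape != (3,) or (props < 0).any():
        raise ValueError("true_props must be three non-negative numbers")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"true_props must sum to 1, got {props.sum()!r}")
    if min(n_animals, sections_per_animal, fovs_per_section, capillaries_per_fov) < 1:
        raise ValueError("design integers must all be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for s in range(sections_per_animal):
            for f in range(fovs_per_section):
                n = int(rng.poisson(capillaries_per_fov))
                n_pp, n_pm, n_mp = rng.multinomial(n, props)
                rows.append(
                    {
                        "animal": a,
                        "section": s,
                        "fov": f,
                        "n_pp": int(n_pp),
                        "n_pm": int(n_pm),
                        "n_mp": int(n_mp),
                    }
                )
    design = {
        "true_props": props.tolist(),
        "n_animals": n_animals,
        "sections_per_animal": sections_per_animal,
        "fovs_per_section": fovs_per_section,
        "capillaries_per_fov": capillaries_per_fov,
        "seed": seed,
    }
    return ClassificationCounts(table=pd.DataFrame(rows), design=design)
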