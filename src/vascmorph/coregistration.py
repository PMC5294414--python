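"""Locate the virtual microCT section matching a 2D histological image.

Because the solidified contrast agent is autofluorescent, a histological
section and its corresponding virtual microCT section share the same vessel
geometry even though their intensities are unrelated.  The match is found
by exhaustive grid search over (z slice, in-plane rotation, isotropic
scale), scoring each candidate with zero-mean normalized cross-correlation
(NCC) on binarized vessel/non-vessel images by default.  Exhaustive search
keeps the result deterministic; ties are broken by smallest z, then
smallest absolute rotation.

The isotropic scale candidates exist because tissue processing shrinks the
specimen isotropically between the scan and the sectioned state; pass the
``cumulative_scale_factor`` of a :class:`~vascmorph.morphometry.ShrinkageReport`
to account for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import VoxelVolume

__all__ = ["SectionMatch", "match_section", "ncc_score"]

# central square inscribed in the rotated field of view for any angle,
# so rotation fill values never enter the score
_CROP_SHRINK = 1.0 / math.sqrt(2.0)


@dataclass
class SectionMatch:
    """Best (z, rotation, scale) triple and its NCC score."""

    z_index: int
    in_plane_rotation_deg: float
    scale_factor: float
    score: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError(f"NCC score out of [-1, 1]: {self.score}")

    def to_dict(self) -> dict:
        return {
            "z_index": self.z_index,
            "in_plane_rotation_deg": self.in_plane_rotation_deg,
            "scale_factor": self.scale_factor,
            "score": self.score,
        }


def _central_crop(img: np.ndarray, side: int) -> np.ndarray:
    h, w = img.shape
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return img[r0 : r0 + side, c0 : c0 + side]


def ncc_score(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two same-shape images.

    Equals the Pearson correlation of the flattened pixels, hence invariant
    to affine intensity rescaling of either image.  Raises on constant
    input, where the correlation is undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.dot(a, b) / (na * nb))


def _binarize(img: np.ndarray) -> np.ndarray:
    if img.dtype == bool:
        return img.astype(float)
    if np.ptp(img) == 0:
        raise ValueError("cannot binarize a constant image")
    return (img >= threshold_otsu(img, nbins=256)).astype(float)


def _resample_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center-crop or zero-pad to the target shape."""
    out = np.zeros(shape, dtype=float)
    h, w = img.shape
    th, tw = shape
    src_r = slice(max((h - th) // 2, 0), max((h - th) // 2, 0) + min(h, th))
    src_c = slice(max((w - tw) // 2, 0), max((w - tw) // 2, 0) + min(w, tw))
    dst_r = slice(max((th - h) // 2, 0), max((th - h) // 2, 0) + min(h, th))
    dst_c = slice(max((tw - w) // 2, 0), max((tw - w) // 2, 0) + min(w, tw))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def match_section(
    histo: np.ndarray,
    vol: VoxelVolume,
    z_range: tuple[int, int] | None = None,
    rotations_deg: Sequence[float] = (0.0,),
    scale_candidates: Sequence[float] = (1.0,),
    binarize: bool = True,
    smooth_sigma_px: float = 1.0,
) -> SectionMatch:
    """Find the virtual section best matching a 2D query image.

    ``in_plane_rotation_deg`` in the result is the rotation applied to the
    query to align it with the volume slice (a query that was physically
    rotated by +θ relative to its section is recovered with rotation ≈ −θ).
    The search is exhaustive over ``z_range`` (half-open, default the whole
    stack) × ``rotations_deg`` × ``scale_candidates``; the score is NCC on
    a central square crop small enough that rotation fill never enters it.

    Both images are Gaussian-smoothed by ``smooth_sigma_px`` after
    binarization, so the NCC of thin binary vessel profiles degrades
    gracefully under sub-pixel resampling error instead of collapsing; the
    same filter is applied to query and slice, so an exact self-match still
    scores 1.  Slices on which the correlation is undefined (constant
    content) are skipped; if every candidate is skipped an error is raised.
    """
    histo = np.asarray(histo)
    nz = vol.shape[0]
    if z_range is None:
        z_range = (0, nz)
    z0, z1 = int(z_range[0]), int(z_range[1])
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-range z_range {z_range} for {nz} slices")
    if len(rotations_deg) == 0 or len(scale_candidates) == 0:
        raise ValueError("rotation and scale candidate lists must be non-empty")

    query = _binarize(histo) if binarize else np.asarray(histo, dtype=float)
    if np.ptp(query) == 0:
        raise ValueError("query image is constant; correlation undefined")

    target_shape = vol.shape[1:]
    side = int(min(target_shape) * _CROP_SHRINK)
    if side < 2:
        raise ValueError("volume slices too small to correlate")

    # candidate transforms ordered so that strict improvement implements the
    # tie-break: smallest z, then smallest |rotation|
    rotations = sorted((float(r) for r in rotations_deg), key=lambda r: (abs(r), r))
    transformed: list[tuple[float, float, np.ndarray]] = []
    for rot in rotations:
        for scale in scale_candidates:
            img = query
            if scale != 1.0:
                img = ndimage.zoom(img, float(scale), order=1)
            if rot != 0.0:
                img = ndimage.rotate(img, rot, reshape=False, order=1, mode="constant")
            img = _resample_to(img, target_shape)
            if smooth_sigma_px > 0:
                img = ndimage.gaussian_filter(img, smooth_sigma_px)
            transformed.append((rot, float(scale), _central_crop(img, side)))

    best: SectionMatch | None = None
    for z in range(z0, z1):
        sl = vol.data[z]
        sl = _binarize(sl) if binarize else np.asarray(sl, dtype=float)
        if smooth_sigma_px > 0:
            sl = ndimage.gaussian_filter(sl, smooth_sigma_px)
        sl = _central_crop(sl, side)
        if np.ptp(sl) == 0:
            continue
        for rot, scale, img in transformed:
            if np.ptp(img) == 0:
                continue
            s = ncc_score(img, sl)
            if best is None or s > best.score:
                best = SectionMatch(
                    z_index=z, in_plane_rotation_deg=rot, scale_factor=scale, score=s
                )
    if best is None:
        raise ValueError("correlation undefined for every candidate in the search grid")
    return best
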