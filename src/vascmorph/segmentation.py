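"""Vessel and tissue segmentation of grayscale microCT volumes.

The original analyses of this kind were run through closed commercial
software whose threshold and despeckle settings are opaque; this module
re-specifies the step openly: a global threshold (Otsu on 256 histogram
bins, or a fixed value for auditability), removal of small speckle
components, and a per-slice convex-hull tissue mask providing the
denominator for vascular volume fraction.  Connectivity is 26-connected in
3D (8-connected in 2D) throughout the package.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image, remove_small_objects

from .volume_io import BinaryMask, VoxelVolume

__all__ = ["threshold_volume", "despeckle", "tissue_mask", "DEFAULT_MIN_VOXELS"]

logger = logging.getLogger(__name__)

# below two voxels across per axis is unresolvable structure
DEFAULT_MIN_VOXELS = 8


def threshold_volume(
    vol: VoxelVolume, method: str = "otsu", fixed_value: float | None = None
) -> BinaryMask:
    """Binarize a volume: ``mask = data >= threshold``.

    ``method="otsu"`` maximizes between-class variance on a 256-bin
    histogram over the observed data range; ``method="fixed"`` uses
    ``fixed_value``.  The chosen threshold is logged and recorded in
    ``mask.meta["threshold"]``.
    """
    data = vol.data
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        t = float(fixed_value)
    elif method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError(
                "otsu thresholding undefined on a constant-valued volume"
            )
        t = float(threshold_otsu(data, nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info("threshold_volume: method=%s threshold=%g", method, t)
    return BinaryMask(
        data=data >= t,
        voxel_size_um=vol.voxel_size_um,
        meta={"threshold": t, "method": method},
    )


def despeckle(mask: BinaryMask, min_voxels: int = DEFAULT_MIN_VOXELS) -> BinaryMask:
    """Drop 26-connected foreground components smaller than ``min_voxels``.

    Monotone (output ⊆ input) and idempotent at fixed ``min_voxels``.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    # max_size removes components of size <= value, so keep size >= min_voxels
    cleaned = remove_small_objects(
        mask.data, max_size=int(min_voxels) - 1, connectivity=mask.data.ndim
    )
    return BinaryMask(
        data=cleaned,
        voxel_size_um=mask.voxel_size_um,
        meta={**mask.meta, "despeckle_min_voxels": int(min_voxels)},
    )


def tissue_mask(
    vol_or_mask: BinaryMask,
    method: str = "bounding_hull",
    provided: BinaryMask | None = None,
) -> BinaryMask:
    """Build the tissue region used as the vv/tv denominator.

    ``bounding_hull`` fills, slice by slice along z, the 2D convex hull of
    the foreground (so the vessel mask is contained in the tissue mask by
    construction); ``provided`` passes a user-supplied mask through after a
    shape check.
    """
    if method == "provided":
        if provided is None:
            raise ValueError("method='provided' requires a mask")
        if provided.shape != vol_or_mask.shape:
            raise ValueError(
                f"provided mask shape {provided.shape} does not match "
                f"source shape {vol_or_mask.shape}"
            )
        return provided
    if method != "bounding_hull":
        raise ValueError(f"unknown tissue_mask method {method!r}")
    fg = vol_or_mask.data
    if not fg.any():
        raise ValueError("cannot build a bounding hull of an empty foreground")
    hull = np.zeros_like(fg)
    for k in range(fg.shape[0]):
        if fg[k].any():
            hull[k] = convex_hull_image(fg[k])
    return BinaryMask(
        data=hull,
        voxel_size_um=vol_or_mask.voxel_size_um,
        meta={"method": "bounding_hull"},
    )
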