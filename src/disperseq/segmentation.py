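"""Mask-level utilities: ROI-constrained thresholding, centroids, erosion splits.

These are the primitives the quantification procedures rest on: refining a
coarse manual ROI into a cell mask by automatic thresholding, computing the
cluster centroid as the unweighted mean of segmented voxel coordinates, and
partitioning a cell mask into a cortical membrane rim and a cytoplasmic core
by repeated erosion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .containers import LabelMask, Spacing
from .errors import DegenerateHistogramError, DisperseqError, TooThinObjectError


def _as_bool(mask) -> np.ndarray:
    m = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    return m.astype(bool)


def refine_roi_threshold(
    image: np.ndarray,
    roi: np.ndarray,
    spacing: Spacing = (1.0, 1.0, 1.0),
) -> LabelMask:
    """Refine a coarse ROI into a mask by Otsu thresholding within the ROI.

    The threshold minimizes intra-class intensity variance over the ROI voxels
    (256-bin Otsu criterion); the largest connected above-threshold component
    inside the ROI is returned. The result is always a subset of the ROI.

    Raises
    ------
    DegenerateHistogramError
        If the ROI holds fewer than two distinct intensity values.
    """
    image = np.asarray(image)
    roi = _as_bool(roi)
    if not roi.any():
        raise DisperseqError("roi is empty")
    vals = image[roi]
    if np.unique(vals).size < 2:
        raise DegenerateHistogramError(
            "ROI contains fewer than two distinct intensity values"
        )
    thr = threshold_otsu(vals, nbins=256)
    above = roi & (image > thr)
    if not above.any():
        raise DegenerateHistogramError("no ROI voxel exceeds the Otsu threshold")
    lab, n = ndi.label(above)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # ties -> smallest label (raster order)
    return LabelMask((lab == keep).astype(np.int32), spacing)


def cluster_centroid(mask, spacing: Spacing | None = None) -> np.ndarray:
    """Unweighted mean of labeled voxel coordinates, scaled to µm.

    Accepts a :class:`LabelMask` or a plain array (then ``spacing`` applies,
    default isotropic 1 µm). Returns a ``(z, y, x)`` µm point (``(y, x)`` for
    2D input).
    """
    if isinstance(mask, LabelMask):
        arr, sp = mask.labels, mask.spacing
    else:
        arr = np.asarray(mask)
        sp = spacing if spacing is not None else (1.0,) * 3
    fg = arr > 0
    if not fg.any():
        raise DisperseqError("mask is empty; centroid undefined")
    coords = np.argwhere(fg).mean(axis=0)
    sp_used = np.asarray(sp, dtype=float)[-coords.size :]
    return coords * sp_used


def _erode(mask: np.ndarray, radius: int, footprint: str = "auto") -> np.ndarray:
    """Erode ``radius`` times with a 3x3 square (2D) or 1-voxel ball (3D)."""
    if radius < 1:
        raise DisperseqError("erosion radius must be >= 1 pixel")
    if footprint == "auto":
        footprint = "square" if mask.ndim == 2 else "ball"
    if footprint == "square":
        structure = np.ones((3,) * mask.ndim, dtype=bool)
    elif footprint == "ball":
        structure = ball(1) if mask.ndim == 3 else np.ones((3, 3), dtype=bool)
    else:
        raise DisperseqError(f"unknown footprint {footprint!r}")
    return ndi.binary_erosion(mask, structure=structure, iterations=radius)


def membrane_cytoplasm_split(
    cell_mask,
    erosion_radius_px: int = 2,
    footprint: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a cell mask into a membrane rim and a cytoplasmic core.

    The cytoplasm is the mask eroded ``erosion_radius_px`` times; the membrane
    is the original mask minus the eroded mask. The two regions are disjoint
    and together exhaust the input mask.

    Raises
    ------
    TooThinObjectError
        If erosion annihilates the mask (no cytoplasm would remain).
    """
    mask = _as_bool(cell_mask)
    if not mask.any():
        raise DisperseqError("cell mask is empty")
    cyto = _erode(mask, erosion_radius_px, footprint)
    if not cyto.any():
        raise TooThinObjectError(
            f"erosion radius {erosion_radius_px} px annihilates the cell mask"
        )
    membrane = mask & ~cyto
    return membrane, cyto


def periphery_mask(cell_mask, erosion_radius_px: int = 2, footprint: str = "auto") -> np.ndarray:
    """The membrane rim only (first element of :func:`membrane_cytoplasm_split`)."""
    membrane, _ = membrane_cytoplasm_split(cell_mask, erosion_radius_px, footprint)
    return membrane
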