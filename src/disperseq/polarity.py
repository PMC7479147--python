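"""Cortical polarity: detection, intensity ratio, orientation, stability.

A polarized cortical region is a connected set of bright peripheral pixels:
the cell periphery (mask minus its erosion) is screened for pixels more than
``sd_threshold`` standard deviations above the whole-cell mean, and connected
components larger than ``min_region_px`` qualify. The polarity orientation is
the angle between the vector from the cell centroid to the region centroid
and the vector from the cell centroid to a reference point (the surrounding
tissue's centre). Reorientation events are frame-to-frame shifts of that
angle beyond ``reorientation_deg``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import rotate as _sk_rotate

from .errors import DisperseqError, UndefinedOrientationError
from .segmentation import membrane_cytoplasm_split, periphery_mask


@dataclass
class PolarityParams:
    """Cut-offs of the polarity analysis.

    ``ratio_threshold`` (fold over cytoplasm) defines a polarized cell;
    ``sd_threshold`` and ``min_region_px`` define an automatic polarized
    region; ``reorientation_deg`` is the angular shift scored as a
    reorientation event; ``posterior_fraction`` is the fraction of segmented
    rows defining the posterior after rotation.
    """

    ratio_threshold: float = 1.2
    sd_threshold: float = 1.5
    min_region_px: int = 10
    reorientation_deg: float = 60.0
    posterior_fraction: float = 0.20
    erosion_radius_px: int = 2

    def validate(self) -> None:
        for name in ("ratio_threshold", "sd_threshold", "min_region_px",
                     "reorientation_deg", "erosion_radius_px"):
            if getattr(self, name) <= 0:
                raise DisperseqError(f"{name} must be strictly positive")
        if not (0.0 < self.posterior_fraction < 1.0):
            raise DisperseqError("posterior_fraction must lie in (0, 1)")


@dataclass
class PolarityRecord:
    """One cell's polarity readout at one frame."""

    cell: int
    frame: int
    detected: bool
    region_centroid: tuple[float, ...] | None = None  # µm (y, x)
    polarized_intensity: float | None = None  # fold over cytoplasm
    orientation_deg: float | None = None  # in [0, 180]


def polarity_ratio(
    image: np.ndarray,
    polarized_roi: np.ndarray,
    cytoplasm_roi: np.ndarray,
    params: PolarityParams | None = None,
) -> tuple[float, bool]:
    """Mean intensity ratio of a polarized region over the cytoplasm.

    Returns the fold ratio and whether it meets the polarity criterion
    (>= ``ratio_threshold``, default 1.2-fold).
    """
    params = params or PolarityParams()
    image = np.asarray(image, dtype=float)
    pol = np.asarray(polarized_roi).astype(bool)
    cyt = np.asarray(cytoplasm_roi).astype(bool)
    if not pol.any() or not cyt.any():
        raise DisperseqError("both ROIs must be non-empty")
    cyt_mean = image[cyt].mean()
    if cyt_mean == 0:
        raise DisperseqError("cytoplasm mean intensity is zero")
    ratio = float(image[pol].mean() / cyt_mean)
    return ratio, ratio >= params.ratio_threshold


def detect_polarized_region(
    image: np.ndarray,
    cell_mask: np.ndarray,
    params: PolarityParams | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Automatic polarized-region detection on a 2D slice or projection.

    Candidate pixels are periphery pixels brighter than the whole-cell mean
    plus ``sd_threshold`` standard deviations (statistics over all cell-mask
    pixels, sample SD). Connected components (8-connectivity) larger than
    ``min_region_px`` qualify; if several qualify the one with the greatest
    total intensity wins, with ties broken by lowest centroid row then column.
    Returns ``(region_mask, centroid_px)`` or None when nothing qualifies —
    an undetected frame is a valid outcome, not an error.
    """
    params = params or PolarityParams()
    params.validate()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(cell_mask).astype(bool)
    if image.ndim != 2 or mask.shape != image.shape:
        raise DisperseqError("detection expects a 2D image with a matching mask")
    periphery = periphery_mask(mask, params.erosion_radius_px)
    vals = image[mask]
    mu = vals.mean()
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    candidates = periphery & (image > mu + params.sd_threshold * sd)
    if not candidates.any():
        return None
    lab, n = ndi.label(candidates, structure=np.ones((3, 3), dtype=bool))
    best = None
    for comp in range(1, n + 1):
        sel = lab == comp
        size = int(sel.sum())
        if size <= params.min_region_px:
            continue
        total = image[sel].sum()
        centroid = np.argwhere(sel).mean(axis=0)
        key = (-total, centroid[0], centroid[1])
        if best is None or key < best[0]:
            best = (key, sel, centroid)
    if best is None:
        return None
    return best[1], best[2]


def orientation_angle(
    cell_point: Sequence[float],
    region_centroid: Sequence[float],
    reference_point: Sequence[float],
) -> float:
    """Angle (degrees, in [0, 180]) between cell->region and cell->reference."""
    a = np.asarray(region_centroid, dtype=float) - np.asarray(cell_point, dtype=float)
    b = np.asarray(reference_point, dtype=float) - np.asarray(cell_point, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedOrientationError("zero-length vector; orientation undefined")
    cosang = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def reorientation_events(
    angles: Sequence[float | None],
    threshold_deg: float = 60.0,
    across_gaps: bool = True,
) -> int:
    """Count polarity shifts exceeding ``threshold_deg`` along an angle series.

    ``angles`` may contain None/NaN for undetected frames. One event is scored
    per consecutive pair of detected values whose absolute change exceeds the
    threshold; with ``across_gaps`` (default) the first detected value after a
    gap is compared with the last before it, otherwise gap-spanning pairs are
    skipped.
    """
    arr = np.array(
        [np.nan if a is None else float(a) for a in angles], dtype=float
    )
    detected_idx = np.flatnonzero(np.isfinite(arr))
    if detected_idx.size < 2:
        raise DisperseqError("need at least 2 detected frames to count events")
    events = 0
    for i, j in zip(detected_idx[:-1], detected_idx[1:]):
        if not across_gaps and j != i + 1:
            continue
        if abs(arr[j] - arr[i]) > threshold_deg:
            events += 1
    return events


def _rotation_angle_for_down(direction: Sequence[float]) -> float:
    """Rotation (deg, for skimage.transform.rotate) mapping ``(dy, dx)`` to down."""
    dy, dx = float(direction[0]), float(direction[1])
    if dy == 0 and dx == 0:
        raise UndefinedOrientationError("posterior direction is a zero vector")
    return -math.degrees(math.atan2(dx, dy))


def posterior_intensity_timecourse(
    images: np.ndarray,
    masks: np.ndarray,
    posterior_direction: np.ndarray,
    params: PolarityParams | None = None,
) -> np.ndarray:
    """Mean posterior intensity per frame after rotating the posterior down.

    For each frame the image (bilinear) and mask (nearest-neighbour) are
    rotated in-plane so that ``posterior_direction`` (an in-plane ``(dy, dx)``
    unit vector per frame) points toward the bottom. The posterior is the
    lowest ``ceil(posterior_fraction x rows)`` of the rows containing mask
    pixels; the mean image intensity over posterior mask pixels is returned.

    A mask spanning fewer than 5 rows triggers a too-small-cell warning and
    the single lowest row is used.
    """
    params = params or PolarityParams()
    images = np.asarray(images, dtype=float)
    masks = np.asarray(masks).astype(bool)
    dirs = np.asarray(posterior_direction, dtype=float)
    if images.ndim != 3 or masks.shape != images.shape or dirs.shape != (len(images), 2):
        raise DisperseqError(
            "expect images (T, Y, X), masks (T, Y, X) and directions (T, 2)"
        )
    out = np.empty(len(images))
    for t in range(len(images)):
        if not masks[t].any():
            raise DisperseqError(f"frame {t}: empty mask")
        ang = _rotation_angle_for_down(dirs[t])
        img = _sk_rotate(images[t], ang, resize=True, order=1, preserve_range=True)
        msk = (
            _sk_rotate(
                masks[t].astype(float), ang, resize=True, order=0, preserve_range=True
            )
            > 0.5
        )
        rows = np.flatnonzero(msk.any(axis=1))
        if rows.size < 5:
            warnings.warn(
                f"frame {t}: mask spans only {rows.size} rows; using the lowest row",
                stacklevel=2,
            )
            post_rows = rows[-1:]
        else:
            n_post = math.ceil(params.posterior_fraction * rows.size)
            post_rows = rows[-n_post:]
        sel = np.zeros_like(msk)
        sel[post_rows] = True
        sel &= msk
        out[t] = img[sel].mean()
    return out


def polarity_timecourse(
    images: np.ndarray,
    cell_labels: np.ndarray,
    reference_point: Sequence[float],
    spacing_yx: tuple[float, float] = (1.0, 1.0),
    params: PolarityParams | None = None,
) -> list[PolarityRecord]:
    """Per-cell, per-frame polarity records from 2D frames.

    Parameters
    ----------
    images:
        Reporter channel as ``(T, Y, X)`` 2D frames (slices or projections).
    cell_labels:
        Integer ``(T, Y, X)`` stack; label k marks cell k at each frame.
    reference_point:
        The orientation reference (tissue centre) in µm ``(y, x)``.
    """
    params = params or PolarityParams()
    images = np.asarray(images, dtype=float)
    cell_labels = np.asarray(cell_labels)
    if images.shape != cell_labels.shape or images.ndim != 3:
        raise DisperseqError("images and cell_labels must both be (T, Y, X)")
    sp = np.asarray(spacing_yx, dtype=float)
    ref = np.asarray(reference_point, dtype=float)

    records: list[PolarityRecord] = []
    for cell in np.unique(cell_labels):
        if cell == 0:
            continue
        for t in range(len(images)):
            mask = cell_labels[t] == cell
            if not mask.any():
                continue
            det = detect_polarized_region(images[t], mask, params)
            if det is None:
                records.append(PolarityRecord(int(cell), t, False))
                continue
            region, centroid_px = det
            cell_centroid = np.argwhere(mask).mean(axis=0) * sp
            region_um = centroid_px * sp
            _, cyto = membrane_cytoplasm_split(mask, params.erosion_radius_px)
            ratio, _ = polarity_ratio(images[t], region, cyto, params)
            try:
                angle = orientation_angle(cell_centroid, region_um, ref)
            except UndefinedOrientationError:
                angle = None
            records.append(
                PolarityRecord(
                    int(cell), t, True, tuple(region_um), ratio, angle
                )
            )
    return records
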