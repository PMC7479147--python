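"""Reading and writing movies, label stacks and ground truth.

Movies are canonicalized to ``T x C x Z x Y x X`` on read: axes are taken
from the TIFF series metadata (or an explicit override), missing axes are
promoted to length 1, and voxel spacing comes from OME metadata or an
override. Writing uses OME-TIFF with physical sizes embedded so a
write-then-read round trip restores voxels and spacing exactly.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .containers import LabelMovie, Movie, Spacing
from .errors import DisperseqError

_CANONICAL = "TCZYX"


def read_movie(
    path,
    spacing: Spacing | None = None,
    frame_interval_s: float | None = None,
    axes: str | None = None,
    channel_names: tuple[str, ...] = (),
) -> Movie:
    """Read a TIFF / OME-TIFF as a canonical ``(T, C, Z, Y, X)`` movie.

    ``axes`` overrides the axis string when the file's metadata is ambiguous;
    an unresolvable axis raises an error naming the offending letter.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes if axes is not None else series.axes
        meta_spacing, meta_dt = _ome_spacing(tif)

    file_axes = file_axes.upper().replace("S", "C").replace("I", "T").replace("Q", "")
    if len(file_axes) != data.ndim:
        if axes is None:
            raise DisperseqError(
                f"cannot resolve axes {series.axes!r} for shape {data.shape}; "
                "pass axes= explicitly"
            )
        raise DisperseqError(f"axes override {axes!r} does not match shape {data.shape}")
    for ax in file_axes:
        if ax not in _CANONICAL:
            raise DisperseqError(
                f"ambiguous axis {ax!r} in {file_axes!r}; pass axes= to override"
            )
    if len(set(file_axes)) != len(file_axes):
        raise DisperseqError(f"duplicate axis in {file_axes!r}")

    order = [file_axes.index(ax) for ax in _CANONICAL if ax in file_axes]
    data = np.transpose(data, order)
    for pos, ax in enumerate(_CANONICAL):
        if ax not in file_axes:
            data = np.expand_dims(data, pos)

    final_spacing = spacing or meta_spacing or (1.0, 1.0, 1.0)
    dt = frame_interval_s or meta_dt or 30.0
    return Movie(data, final_spacing, frame_interval_s=dt, channel_names=channel_names)


def _ome_spacing(tif: tifffile.TiffFile):
    """Best-effort (spacing, frame interval) from OME metadata."""
    if not tif.is_ome or not tif.ome_metadata:
        return None, None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        spacing = (
            float(pixels.get("PhysicalSizeZ", 1.0)),
            float(pixels.get("PhysicalSizeY", 1.0)),
            float(pixels.get("PhysicalSizeX", 1.0)),
        )
        dt = pixels.get("TimeIncrement")
        return spacing, float(dt) if dt is not None else None
    except (KeyError, TypeError, ValueError):
        return None, None


def write_movie(path, movie: Movie) -> None:
    """Write a movie as OME-TIFF with spacing and frame interval embedded."""
    dz, dy, dx = movie.spacing
    tifffile.imwrite(
        path,
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": _CANONICAL,
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "TimeIncrement": movie.frame_interval_s,
            "TimeIncrementUnit": "s",
        },
    )


def write_label_movie(path, labels: LabelMovie) -> None:
    tifffile.imwrite(
        path,
        labels.labels.astype(np.uint16),
        metadata={"axes": "TZYX"},
    )


def read_label_movie(path, spacing: Spacing = (1.0, 1.0, 1.0)) -> LabelMovie:
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    return LabelMovie(data.astype(np.int32), spacing)
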