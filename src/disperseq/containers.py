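"""Core in-memory containers.

Conventions used throughout the package:

* image arrays are ordered ``T x C x Z x Y x X`` (movies), ``T x Z x Y x X``
  (label movies) or ``Z x Y x X`` (single volumes);
* ``spacing`` is the physical voxel size in micrometres, ordered ``(z, y, x)``;
* physical points are micrometre ``(z, y, x)`` vectors unless a function
  documents otherwise (track tables use the field-standard ``x, y, z`` columns);
* coordinates are 0-based and refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DisperseqError

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DisperseqError(f"spacing must be three positive lengths, got {spacing}")
    return spacing


@dataclass
class Movie:
    """A multi-channel 4D voxel image with physical spacing.

    Parameters
    ----------
    data:
        Array of shape ``(T, C, Z, Y, X)``.
    spacing:
        Voxel size in µm, ``(z, y, x)``.
    frame_interval_s:
        Time between frames in seconds.
    channel_names:
        Optional channel labels, e.g. ``("membrane", "reporter")``.
    """

    data: np.ndarray
    spacing: Spacing
    frame_interval_s: float = 30.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise DisperseqError(
                f"Movie data must be 5D (T, C, Z, Y, X), got shape {self.data.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise DisperseqError("channel_names length must match the C axis")
        if self.frame_interval_s <= 0:
            raise DisperseqError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a ``(T, Z, Y, X)`` array."""
        if isinstance(which, str):
            if which not in self.channel_names:
                raise DisperseqError(
                    f"unknown channel {which!r}; have {self.channel_names}"
                )
            which = self.channel_names.index(which)
        return self.data[:, which]


@dataclass
class LabelMask:
    """Integer label volume (0 = background) with physical spacing."""

    labels: np.ndarray
    spacing: Spacing
    frame: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.int32)
            else:
                raise DisperseqError("labels must be an integer (or boolean) array")
        if self.labels.min() < 0:
            raise DisperseqError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class LabelMovie:
    """Per-frame integer label masks, shape ``(T, Z, Y, X)``."""

    labels: np.ndarray
    spacing: Spacing
    frame_interval_s: float = 30.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise DisperseqError(
                f"LabelMovie labels must be 4D (T, Z, Y, X), got {self.labels.shape}"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame(self, t: int) -> LabelMask:
        return LabelMask(self.labels[t], self.spacing, frame=t)


@dataclass
class Region:
    """A named voxel region anchored to an optional frame/slice.

    ``role`` tags the region's use in the analysis (cell, posterior,
    cytoplasm, polarized, background, boundary).
    """

    mask: np.ndarray
    role: str = "cell"
    name: str = ""
    frame: int | None = None
    z: int | None = None

    ROLES = ("cell", "posterior", "cytoplasm", "polarized", "background", "boundary")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise DisperseqError(f"region {self.name!r} is empty")
        if self.role not in self.ROLES:
            raise DisperseqError(f"unknown region role {self.role!r}")


@dataclass
class RoiSet:
    """A collection of named regions."""

    regions: dict[str, Region] = field(default_factory=dict)

    def add(self, region: Region) -> None:
        if not region.name:
            raise DisperseqError("region must be named to join a RoiSet")
        self.regions[region.name] = region

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def by_role(self, role: str) -> list[Region]:
        return [r for r in self.regions.values() if r.role == role]


@dataclass
class Track:
    """One cell's ordered positions: times in minutes, positions in µm (x, y, z)."""

    track_id: int
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.t.size, 3):
            raise DisperseqError("xyz must be (n, 3) matching t")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise DisperseqError(f"track {self.track_id}: t must strictly increase")

    def __len__(self) -> int:
        return self.t.size


class TrackSet:
    """A set of 3D tracks backed by a tidy DataFrame.

    Columns: ``track_id, t, x, y, z`` with t in minutes and positions in µm.
    """

    COLUMNS = ["track_id", "t", "x", "y", "z"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DisperseqError(f"track table missing columns {missing}")
        self.df = (
            df[self.COLUMNS]
            .sort_values(["track_id", "t"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_tracks(cls, tracks: Sequence[Track]) -> "TrackSet":
        frames = [
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "t": tr.t,
                    "x": tr.xyz[:, 0],
                    "y": tr.xyz[:, 1],
                    "z": tr.xyz[:, 2],
                }
            )
            for tr in tracks
        ]
        return cls(pd.concat(frames, ignore_index=True))

    @classmethod
    def read_csv(cls, path) -> "TrackSet":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, index=False)

    def track_ids(self) -> list[int]:
        return sorted(self.df["track_id"].unique().tolist())

    def __len__(self) -> int:
        return len(self.track_ids())

    def __iter__(self) -> Iterator[Track]:
        for tid, sub in self.df.groupby("track_id", sort=True):
            yield Track(int(tid), sub["t"].to_numpy(), sub[["x", "y", "z"]].to_numpy())

    def get(self, track_id: int) -> Track:
        sub = self.df[self.df["track_id"] == track_id]
        if sub.empty:
            raise DisperseqError(f"no track with id {track_id}")
        return Track(track_id, sub["t"].to_numpy(), sub[["x", "y", "z"]].to_numpy())
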