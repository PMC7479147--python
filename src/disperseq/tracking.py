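"""3D track construction and motility metrics.

Speed is total path length over total elapsed time (µm/min) and straightness
is net displacement over path length — the standard definitions of commercial
tracking software. Linking is greedy nearest-neighbour with a maximum
displacement gate and no gap closing: a missing frame splits a track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import LabelMovie, Track, TrackSet
from .errors import DisperseqError, TrackError


@dataclass
class TrackMetrics:
    track_id: int
    speed_um_per_min: float
    straightness: float


@dataclass(frozen=True)
class BoxRoi:
    """Axis-aligned box in µm (x, y, z) used for containment tests."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xyz, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass(frozen=True)
class SphereRoi:
    """Sphere in µm (x, y, z); the boundary radius of a cluster cavity."""

    center: tuple[float, float, float]
    radius: float

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xyz, dtype=float))
        return np.linalg.norm(p - np.asarray(self.center), axis=1) <= self.radius


def link_centroids(
    label_movie: LabelMovie | np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    frame_interval_min: float = 0.5,
    max_displacement_um: float | None = None,
    cell_radius_um: float = 2.5,
) -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame label centroids.

    Pairs are assigned in order of increasing distance (ties by smallest
    label), gated at ``max_displacement_um`` (default 2 x ``cell_radius_um``).
    Unmatched objects start new tracks; tracks with no match end.
    """
    if isinstance(label_movie, LabelMovie):
        labels = label_movie.labels
        spacing = label_movie.spacing
        frame_interval_min = label_movie.frame_interval_s / 60.0
    else:
        labels = np.asarray(label_movie)
    if labels.ndim != 4 or labels.shape[0] < 2:
        raise DisperseqError("need a (T, Z, Y, X) label movie with >= 2 frames")
    gate = max_displacement_um if max_displacement_um is not None else 2.0 * cell_radius_um
    sp = np.asarray(spacing, dtype=float)

    def frame_centroids(frame: np.ndarray) -> dict[int, np.ndarray]:
        ids = np.unique(frame)
        ids = ids[ids > 0]
        if ids.size == 0:
            return {}
        coms = ndi.center_of_mass(np.ones_like(frame), frame, index=ids)
        # zyx voxel -> xyz µm
        return {
            int(i): np.array([c[2] * sp[2], c[1] * sp[1], c[0] * sp[0]])
            for i, c in zip(ids, coms)
        }

    next_track = 1
    rows: list[dict] = []
    active: dict[int, np.ndarray] = {}  # track_id -> last position
    prev = frame_centroids(labels[0])
    track_of: dict[int, int] = {}
    for lab in sorted(prev):
        track_of[lab] = next_track
        active[next_track] = prev[lab]
        rows.append(
            {"track_id": next_track, "t": 0.0, "x": prev[lab][0], "y": prev[lab][1], "z": prev[lab][2]}
        )
        next_track += 1

    for f in range(1, labels.shape[0]):
        cur = frame_centroids(labels[f])
        pairs = []
        for tid, pos in active.items():
            for lab, cpos in cur.items():
                d = float(np.linalg.norm(cpos - pos))
                if d <= gate:
                    pairs.append((d, tid, lab))
        pairs.sort()
        used_t: set[int] = set()
        used_l: set[int] = set()
        new_active: dict[int, np.ndarray] = {}
        assign: dict[int, int] = {}
        for d, tid, lab in pairs:
            if tid in used_t or lab in used_l:
                continue
            used_t.add(tid)
            used_l.add(lab)
            assign[lab] = tid
        t_min = f * frame_interval_min
        for lab in sorted(cur):
            tid = assign.get(lab)
            if tid is None:
                tid = next_track
                next_track += 1
            new_active[tid] = cur[lab]
            rows.append(
                {"track_id": tid, "t": t_min, "x": cur[lab][0], "y": cur[lab][1], "z": cur[lab][2]}
            )
        active = new_active

    return TrackSet(pd.DataFrame(rows))


def _track_arrays(track: Track) -> tuple[np.ndarray, np.ndarray]:
    if len(track) < 2:
        raise TrackError(f"track {track.track_id}: need >= 2 samples")
    return track.t, track.xyz


def track_speed(track: Track) -> float:
    """Total path length / total elapsed time, in µm/min."""
    t, xyz = _track_arrays(track)
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise TrackError(f"track {track.track_id}: zero elapsed time")
    path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
    return path / float(elapsed)


def track_straightness(track: Track) -> float:
    """Net displacement (first to last) / total path length, in [0, 1]."""
    _, xyz = _track_arrays(track)
    path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
    if path == 0:
        raise TrackError(f"track {track.track_id}: zero path length")
    return float(np.linalg.norm(xyz[-1] - xyz[0]) / path)


def track_metrics(tracks: TrackSet) -> pd.DataFrame:
    """Speed and straightness for every track."""
    rows = [
        {
            "track_id": tr.track_id,
            "speed_um_per_min": track_speed(tr),
            "straightness": track_straightness(tr),
        }
        for tr in tracks
    ]
    return pd.DataFrame(rows)


def distance_from_point_timecourse(
    tracks: TrackSet,
    reference: Sequence[float],
    relative: bool = False,
) -> pd.DataFrame:
    """Mean ± SEM distance to a fixed reference point per frame.

    In relative mode each track's distance series is divided by its initial
    distance before aggregation (a zero initial distance is an error).
    Returns columns ``t, mean, sem, n``.
    """
    ref = np.asarray(reference, dtype=float)
    per_track = []
    for tr in tracks:
        d = np.linalg.norm(tr.xyz - ref, axis=1)
        if relative:
            if d[0] == 0:
                raise TrackError(
                    f"track {tr.track_id}: zero initial distance in relative mode"
                )
            d = d / d[0]
        per_track.append(pd.DataFrame({"t": tr.t, "d": d}))
    stacked = pd.concat(per_track, ignore_index=True)
    g = stacked.groupby("t")["d"]
    out = g.agg(mean="mean", n="count")
    sd = g.std(ddof=1)
    out["sem"] = sd / np.sqrt(out["n"])
    return out.reset_index()[["t", "mean", "sem", "n"]]


def classify_reversal(track: Track, activation_roi, t_pulse: float, window: float) -> bool:
    """True iff the cell exits the activation ROI within ``window`` after the pulse."""
    if track.t[0] > t_pulse or track.t[-1] < t_pulse + window:
        raise TrackError(
            f"track {track.track_id} does not cover [{t_pulse}, {t_pulse + window}]"
        )
    sel = (track.t > t_pulse) & (track.t <= t_pulse + window)
    inside = activation_roi.contains(track.xyz[sel])
    return bool(np.any(~inside))


def count_transmigrated(tracks: TrackSet, boundary) -> pd.DataFrame:
    """Cumulative count of tracks that have crossed a boundary, per frame.

    ``boundary`` is any object with a ``contains(xyz) -> bool array`` method
    (e.g. :class:`SphereRoi` for a radius around the tissue centre). A track
    counts from its first frame outside the boundary onward; the series is
    monotone non-decreasing. Returns columns ``t, count``.
    """
    times = np.array(sorted(tracks.df["t"].unique()))
    exit_t = []
    for tr in tracks:
        outside = ~boundary.contains(tr.xyz)
        idx = np.flatnonzero(outside)
        if idx.size:
            exit_t.append(tr.t[idx[0]])
    exit_t = np.asarray(exit_t)
    counts = [(exit_t <= t).sum() for t in times]
    return pd.DataFrame({"t": times, "count": counts})
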