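"""Synthetic 4D fluorescence-microscopy data with known ground truth.

This module generates the study conditions every downstream quantification is
tested against: spherical cell clusters in a rosette configuration with a
membrane channel and a cortical-reporter channel carrying an angular cap of
enrichment. The cap is oriented either radially toward the cluster centroid
(the wild-type-like, guided condition) or drifts and randomly reorients (the
receptor-mutant-like condition). Depth-dependent signal decay and a
Poisson-plus-Gaussian noise model emulate two-photon imaging of an embryo.

All generators are pure functions of their parameter records: identical
parameters (including the seed) produce bit-identical output.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

from .containers import LabelMovie, Movie, Spacing, Track, TrackSet
from .errors import DisperseqError, PackingError

# --------------------------------------------------------------------------
# cluster movies
# --------------------------------------------------------------------------


@dataclass
class ClusterSimParams:
    """Parameters of a simulated cell-cluster movie.

    The defaults describe a ~30-cell rosette of 2.5-µm-radius cells imaged at
    30-s intervals with anisotropic voxels (0.5 x 0.2 x 0.2 µm), a cortical
    reporter cap of half-angle 45° enriched 2-fold over the cortex baseline,
    and moderate depth attenuation.
    """

    n_cells: int = 30
    cell_radius_um: float = 2.5
    cluster_radius_um: float = 12.5
    cortex_thickness_um: float = 0.6
    cap_half_angle_deg: float = 45.0
    cap_enrichment: float = 2.0
    orientation_mode: Literal["radial_inward", "random"] = "radial_inward"
    reorientation_rate_per_min: float = 0.5
    frame_interval_s: float = 30.0
    n_frames: int = 1
    voxel_spacing_um: Spacing = (0.5, 0.2, 0.2)
    cortex_intensity: float = 200.0
    background_level: float = 20.0
    depth_attenuation_um: float = math.inf
    noise: Literal["none", "poisson_gaussian"] = "none"
    gaussian_sd: float = 5.0
    axis_drift_deg_per_frame: float = 5.0
    margin_um: float = 1.5
    seed: int = 0
    noise_seed: int | None = None  # vary noise only, keeping geometry fixed

    def validate(self) -> None:
        if self.n_cells < 1:
            raise DisperseqError("n_cells must be >= 1")
        if not (0 < self.cap_half_angle_deg < 180):
            raise DisperseqError("cap_half_angle_deg must lie in (0, 180)")
        if self.cap_enrichment < 1:
            raise DisperseqError("cap_enrichment must be >= 1")
        for name in ("cell_radius_um", "cluster_radius_um", "cortex_thickness_um",
                     "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise DisperseqError(f"{name} must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise DisperseqError("voxel spacing must be strictly positive on every axis")
        if self.n_frames < 1:
            raise DisperseqError("n_frames must be >= 1")
        if self.noise not in ("none", "poisson_gaussian"):
            raise DisperseqError(f"unknown noise model {self.noise!r}")
        if self.orientation_mode not in ("radial_inward", "random"):
            raise DisperseqError(f"unknown orientation_mode {self.orientation_mode!r}")


@dataclass
class GroundTruth:
    """Per-frame ground truth accompanying a simulated movie.

    ``cap_axes`` and ``positions`` are indexed ``[frame, cell]`` with cell i
    carrying label ``i + 1`` in ``label_movie``. All vectors are µm-space
    ``(z, y, x)``; cap axes are unit-norm.
    """

    label_movie: LabelMovie
    cap_axes: np.ndarray
    positions: np.ndarray
    cluster_centroid: np.ndarray
    detachment_times: np.ndarray | None = None

    def n_cells(self) -> int:
        return self.positions.shape[1]

    def save(self, out_dir: str) -> None:
        """Serialize as a label TIFF plus an inspectable JSON record."""
        os.makedirs(out_dir, exist_ok=True)
        tifffile.imwrite(
            os.path.join(out_dir, "labels.tif"),
            self.label_movie.labels.astype(np.uint16),
        )
        record = {
            "spacing_um_zyx": list(self.label_movie.spacing),
            "frame_interval_s": self.label_movie.frame_interval_s,
            "cap_axes_zyx": self.cap_axes.tolist(),
            "positions_um_zyx": self.positions.tolist(),
            "cluster_centroid_um_zyx": self.cluster_centroid.tolist(),
            "detachment_times": None
            if self.detachment_times is None
            else self.detachment_times.tolist(),
        }
        with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
            json.dump(record, fh)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (z, y, x) on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([z, r * np.cos(phi), r * np.sin(phi)], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _shell_capacity(shell_radius: float, cell_radius: float) -> int:
    """Conservative count of non-overlapping cells on a spherical shell.

    The spherical-cap area bound gives at most 2 / (1 - cos θ) caps of angular
    radius θ = arcsin(r/s); a 0.6 efficiency factor leaves headroom for the
    near-uniform (not optimal) Fibonacci lattice.
    """
    half_angle = math.asin(min(1.0, cell_radius / shell_radius))
    return max(1, int(0.6 * 2.0 / (1.0 - math.cos(half_angle))))


def _pack_cells(params: ClusterSimParams, rng: np.random.Generator) -> np.ndarray:
    """Deterministic Fibonacci-lattice shell packing, jittered by the seed.

    Returns cell centres in µm (z, y, x) relative to the cluster centre.
    Shells sit at radii 2 r k (k = 1, 2, ...) so radial neighbours are exactly
    one diameter apart; each shell's lattice is rotated by a seeded random
    rotation. Raises :class:`PackingError` when the requested count cannot fit
    inside ``cluster_radius_um``.
    """
    r = params.cell_radius_um
    centers: list[np.ndarray] = []
    remaining = params.n_cells
    k = 1
    while remaining > 0:
        shell_r = 2.0 * r * k
        if shell_r + r > params.cluster_radius_um:
            raise PackingError(
                f"cannot pack n_cells={params.n_cells} of radius "
                f"{params.cell_radius_um} µm inside cluster_radius_um="
                f"{params.cluster_radius_um}: shell {k} at {shell_r} µm "
                f"would exceed the cluster"
            )
        cap = _shell_capacity(shell_r, r)
        take = min(cap, remaining)
        pts = _fibonacci_sphere(take) @ _random_rotation(rng).T
        centers.append(pts * shell_r)
        remaining -= take
        k += 1
    out = np.concatenate(centers, axis=0)
    if len(out) > 1:
        d = np.linalg.norm(out[:, None, :] - out[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2.0 * r * 0.98:
            raise PackingError(
                f"packing produced overlapping cells (min centre distance "
                f"{d.min():.3f} µm < diameter {2 * r} µm) for n_cells="
                f"{params.n_cells}, cell_radius_um={r}"
            )
    return out


def _rotate_about(axis: np.ndarray, unit: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``axis`` about ``unit`` by ``angle_rad``."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return (
        axis * c
        + np.cross(unit, axis) * s
        + unit * np.dot(unit, axis) * (1.0 - c)
    )


def _evolve_axes(
    params: ClusterSimParams,
    centers: np.ndarray,
    centroid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cap axis per cell per frame, shape (T, n, 3), unit (z, y, x)."""
    n = len(centers)
    axes = np.empty((params.n_frames, n, 3))
    if params.orientation_mode == "radial_inward":
        inward = centroid[None, :] - centers
        norms = np.linalg.norm(inward, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise DisperseqError("a cell sits exactly at the cluster centroid")
        axes[:] = (inward / norms)[None, :, :]
        return axes
    # random mode: uniform init, small-step spherical diffusion, Poisson-timed
    # uniform resampling at reorientation_rate_per_min
    dt_min = params.frame_interval_s / 60.0
    p_resample = 1.0 - math.exp(-params.reorientation_rate_per_min * dt_min)
    sigma = math.radians(params.axis_drift_deg_per_frame)
    for i in range(n):
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        for t in range(params.n_frames):
            axes[t, i] = ax
            if rng.uniform() < p_resample:
                ax = rng.normal(size=3)
                ax /= np.linalg.norm(ax)
            else:
                perp = np.cross(ax, rng.normal(size=3))
                perp /= np.linalg.norm(perp)
                ax = _rotate_about(ax, perp, rng.normal(0.0, sigma))
                ax /= np.linalg.norm(ax)
    return axes


def generate_cluster_movie(params: ClusterSimParams) -> tuple[Movie, GroundTruth]:
    """Render a two-channel rosette movie and its ground truth.

    Channel 0 ("membrane") carries uniform cortical signal; channel 1
    ("reporter") carries the cortical baseline with a cap of
    ``cap_enrichment``-fold signal on the side facing each cell's cap axis.
    Pre-noise expected values decay with depth as ``exp(-z/λ)``; the flat
    background decays identically so per-plane background normalization
    cancels the attenuation exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    centers_rel = _pack_cells(params, rng)
    n = params.n_cells
    dz, dy, dx = params.voxel_spacing_um

    half = params.cluster_radius_um + params.margin_um
    shape = tuple(int(math.ceil(2 * half / d)) + 1 for d in (dz, dy, dx))
    centroid = np.array([(s - 1) / 2.0 * d for s, d in zip(shape, (dz, dy, dx))])
    centers = centroid[None, :] + centers_rel

    axes = _evolve_axes(params, centers, centroid, rng)

    cos_cap = math.cos(math.radians(params.cap_half_angle_deg))
    r = params.cell_radius_um
    r_in = r - params.cortex_thickness_um

    mem = np.zeros((params.n_frames,) + shape)
    rep = np.zeros_like(mem)
    labels = np.zeros((params.n_frames,) + shape, dtype=np.int32)

    # per-cell bounding boxes (cells are static; geometry reused every frame)
    boxes = []
    for i in range(n):
        cz, cy, cx = centers[i]
        lo = [max(0, int((c - r) / d) - 1) for c, d in zip((cz, cy, cx), (dz, dy, dx))]
        hi = [
            min(s, int((c + r) / d) + 2)
            for c, d, s in zip((cz, cy, cx), (dz, dy, dx), shape)
        ]
        zz = (np.arange(lo[0], hi[0]) * dz - cz)[:, None, None]
        yy = (np.arange(lo[1], hi[1]) * dy - cy)[None, :, None]
        xx = (np.arange(lo[2], hi[2]) * dx - cx)[None, None, :]
        dist = np.sqrt(zz**2 + yy**2 + xx**2)
        inside = dist <= r
        cortex = inside & (dist >= r_in)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.stack(
                [np.broadcast_to(a, dist.shape) / np.where(dist > 0, dist, np.inf)
                 for a in (zz, yy, xx)],
                axis=0,
            )
        boxes.append((tuple(slice(a, b) for a, b in zip(lo, hi)), inside, cortex, unit))

    for t in range(params.n_frames):
        for i in range(n):
            sl, inside, cortex, unit = boxes[i]
            az, ay, ax_ = axes[t, i]
            cosang = az * unit[0] + ay * unit[1] + ax_ * unit[2]
            cap = cortex & (cosang >= cos_cap)
            mem[t][sl][cortex] = params.cortex_intensity
            rep[t][sl][cortex] = params.cortex_intensity
            rep[t][sl][cap] = params.cortex_intensity * params.cap_enrichment
            labels[t][sl][inside] = i + 1

    if math.isfinite(params.depth_attenuation_um):
        z_um = np.arange(shape[0]) * dz
        depth = np.exp(-z_um / params.depth_attenuation_um)[None, :, None, None]
    else:
        depth = 1.0
    mem = mem * depth + params.background_level * depth
    rep = rep * depth + params.background_level * depth

    data = np.stack([mem, rep], axis=1)
    if params.noise == "poisson_gaussian":
        # a separate noise_seed lets replicates share one geometry and cap
        # history while only the noise realization varies
        noise_rng = (
            rng
            if params.noise_seed is None
            else np.random.default_rng(params.noise_seed)
        )
        data = noise_rng.poisson(np.clip(data, 0.0, None)).astype(float)
        data += noise_rng.normal(0.0, params.gaussian_sd, size=data.shape)

    movie = Movie(
        data,
        spacing=params.voxel_spacing_um,
        frame_interval_s=params.frame_interval_s,
        channel_names=("membrane", "reporter"),
    )
    truth = GroundTruth(
        label_movie=LabelMovie(
            labels, params.voxel_spacing_um, frame_interval_s=params.frame_interval_s
        ),
        cap_axes=axes,
        positions=np.broadcast_to(centers, (params.n_frames, n, 3)).copy(),
        cluster_centroid=np.broadcast_to(centroid, (params.n_frames, 3)).copy(),
    )
    return movie, truth


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------


@dataclass
class WalkParams:
    """Parameters of a simulated 3D walk ensemble.

    ``persistent`` is a persistent random walk with directional correlation
    ``persistence``; ``directed`` additionally biases steps toward
    ``bias_target`` (or radially outward from the origin when the target is
    None); ``stationary`` cells do not move. Step length is exactly
    ``step_um`` per frame in the moving modes unless ``step_sd_um`` adds
    per-frame variability.
    """

    mode: Literal["persistent", "directed", "stationary"] = "persistent"
    step_um: float = 1.0
    step_sd_um: float = 0.0  # per-frame step-length variability (0 = exact)
    persistence: float = 0.8
    bias_target: tuple[float, float, float] | None = None
    bias_strength: float = 0.5
    n_tracks: int = 25
    n_frames: int = 40
    frame_interval_min: float = 0.5
    start_radius_um: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.step_um < 0 or self.step_sd_um < 0:
            raise DisperseqError("step_um and step_sd_um must be >= 0")
        for name in ("persistence", "bias_strength"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise DisperseqError(f"{name} must lie in [0, 1]")
        if self.n_frames < 2:
            raise DisperseqError("n_frames must be >= 2 (no displacement otherwise)")
        if self.n_tracks < 1:
            raise DisperseqError("n_tracks must be >= 1")
        if self.mode not in ("persistent", "directed", "stationary"):
            raise DisperseqError(f"unknown walk mode {self.mode!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def generate_tracks(params: WalkParams) -> tuple[TrackSet, dict]:
    """Simulate a walk ensemble; returns the tracks and a truth summary."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) * params.frame_interval_min

    # uniform starts inside a sphere of radius start_radius_um
    starts = rng.normal(size=(params.n_tracks, 3))
    starts /= np.linalg.norm(starts, axis=1, keepdims=True)
    starts *= (
        rng.uniform(0.0, 1.0, size=(params.n_tracks, 1)) ** (1.0 / 3.0)
        * params.start_radius_um
    )

    tracks = []
    for i in range(params.n_tracks):
        pos = np.empty((params.n_frames, 3))
        pos[0] = starts[i]
        if params.mode == "stationary":
            pos[1:] = pos[0]
        else:
            d = _unit(rng.normal(size=3))
            for f in range(1, params.n_frames):
                u = _unit(rng.normal(size=3))
                d_new = params.persistence * d + (1.0 - params.persistence) * u
                if params.mode == "directed":
                    if params.bias_target is None:
                        target_dir = _unit(pos[f - 1])  # radially outward
                    else:
                        target_dir = _unit(np.asarray(params.bias_target) - pos[f - 1])
                    d_new = (1.0 - params.bias_strength) * _unit(d_new) \
                        + params.bias_strength * target_dir
                d = _unit(d_new)
                step = params.step_um
                if params.step_sd_um > 0:
                    step = max(0.0, rng.normal(step, params.step_sd_um))
                pos[f] = pos[f - 1] + step * d
        tracks.append(Track(i + 1, t, pos))

    summary = {
        "mode": params.mode,
        "step_um": params.step_um,
        "persistence": params.persistence,
        "n_tracks": params.n_tracks,
        "start_positions_xyz": starts.tolist(),
    }
    return TrackSet.from_tracks(tracks), summary


# --------------------------------------------------------------------------
# shape masks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Disk:
    radius: float


@dataclass(frozen=True)
class Square:
    side: int


@dataclass(frozen=True)
class Ellipse:
    a: float  # semi-axis along columns
    b: float  # semi-axis along rows


@dataclass(frozen=True)
class Ring:
    r_in: float
    r_out: float


ShapeSpec = Disk | Square | Ellipse | Ring


def generate_shape_mask(spec: ShapeSpec) -> np.ndarray:
    """Exact rasterization of a 2D shape on the integer lattice.

    A pixel is labeled iff its centre satisfies the analytic inclusion test
    (distance <= radius for disks, boundary inclusive). The result carries a
    one-pixel background border.
    """
    if isinstance(spec, Disk):
        if spec.radius < 0:
            raise DisperseqError("disk radius must be >= 0")
        r = spec.radius
        c = int(math.ceil(r))
        n = 2 * c + 1
        ii, jj = np.mgrid[0:n, 0:n]
        mask = (ii - c) ** 2 + (jj - c) ** 2 <= r * r
    elif isinstance(spec, Square):
        if spec.side < 1:
            raise DisperseqError("square side must be >= 1 pixel")
        mask = np.ones((spec.side, spec.side), dtype=bool)
    elif isinstance(spec, Ellipse):
        if spec.a <= 0 or spec.b <= 0:
            raise DisperseqError("ellipse semi-axes must be positive")
        cb, ca = int(math.ceil(spec.b)), int(math.ceil(spec.a))
        ii, jj = np.mgrid[0 : 2 * cb + 1, 0 : 2 * ca + 1]
        mask = ((jj - ca) / spec.a) ** 2 + ((ii - cb) / spec.b) ** 2 <= 1.0
    elif isinstance(spec, Ring):
        if not (0 <= spec.r_in < spec.r_out):
            raise DisperseqError(
                f"ring requires 0 <= r_in < r_out, got ({spec.r_in}, {spec.r_out})"
            )
        c = int(math.ceil(spec.r_out))
        n = 2 * c + 1
        ii, jj = np.mgrid[0:n, 0:n]
        d2 = (ii - c) ** 2 + (jj - c) ** 2
        mask = (d2 <= spec.r_out**2) & (d2 > spec.r_in**2)
    else:  # pragma: no cover - type guard
        raise DisperseqError(f"unknown shape spec {spec!r}")
    if not mask.any():
        raise DisperseqError(f"shape spec {spec!r} rasterizes to zero area")
    return np.pad(mask, 1).astype(np.int32)


# --------------------------------------------------------------------------
# scripted posterior-contraction fixture
# --------------------------------------------------------------------------


def generate_contracting_posterior_series(
    n_frames: int = 10,
    width: int = 40,
    rows0: int = 24,
    shrink_rows_per_frame: int = 2,
    intensity0: float = 100.0,
    brighten_per_frame: float = 25.0,
    background: float = 10.0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """A scripted contracting, brightening posterior region.

    Frame t carries a rectangular posterior ROI of ``rows0 - t*shrink`` rows by
    ``width`` columns at uniform intensity ``intensity0 + t*brighten`` on a flat
    background. Returns per-frame ``(image, roi_mask)`` pairs and the exact
    schedule (area in px, mean intensity) the measurements must reproduce.
    """
    if rows0 - (n_frames - 1) * shrink_rows_per_frame < 1:
        raise DisperseqError("schedule shrinks the posterior to zero rows")
    h = rows0 + 8
    frames = []
    sched = []
    for t in range(n_frames):
        rows = rows0 - t * shrink_rows_per_frame
        val = intensity0 + t * brighten_per_frame
        img = np.full((h, width + 8), background)
        roi = np.zeros_like(img, dtype=bool)
        roi[h - rows - 2 : h - 2, 4 : 4 + width] = True
        img[roi] = val
        frames.append((img, roi))
        sched.append({"frame": t, "area_px": rows * width, "mean_intensity": val})
    return frames, pd.DataFrame(sched)
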