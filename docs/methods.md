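# Methods

## Scope and data model

All computations use the conventions: image axes `T x C x Z x Y x X`; voxel
spacing in µm ordered `(z, y, x)` and honoured in every physical distance
(anisotropy is never ignored); coordinates are 0-based voxel centres; track
tables carry `track_id, t, x, y, z` with t in minutes and positions in µm.

## Synthetic movies

The generator emulates the study conditions the quantifications assume: a
cluster of spherical cells in a rosette, each with a cortical shell and a
reporter cap of angular half-width `cap_half_angle_deg` enriched
`cap_enrichment`-fold over the cortical baseline. Defaults describe a
30-cell cluster of 2.5-µm cells inside a 12.5-µm rosette, imaged every 30 s
at 0.5 x 0.2 x 0.2 µm voxels. The 30-s interval is the one imaging cadence
the source experiments state; the voxel sizes are conventional two-photon
values chosen once, not measured facts. The baseline cortical amplitude
(`cortex_intensity`, default 200 counts over a background of 20) sets the
photon scale for the noise model.

**Packing.** Cells sit on concentric shells of radius `2 r k`
(k = 1, 2, ...), each shell holding a golden-angle (Fibonacci) lattice
rotated by a seeded random rotation. Shell capacity is bounded by the
spherical-cap area argument (≤ 2/(1 − cos θ), θ = arcsin(r/s)) with a 0.6
efficiency factor; after placement all pairwise centre distances are
verified against the cell diameter and a violation (or a shell exceeding
`cluster_radius_um`) raises a packing error naming the offending
parameters. There is no cell at the exact centre, so the inward cap axis is
defined for every cell.

**Cap dynamics.** `radial_inward` caps point from each cell centre to the
cluster centroid at every frame (orientation error exactly 0 by
construction). `random` caps start uniform on the sphere and follow
small-step spherical diffusion (5°/frame Gaussian steps by default) plus
Poisson-timed uniform resampling at `reorientation_rate_per_min` — this
produces both slow drift and the > 60° jumps the event counter is designed
to catch.

**Signal and noise.** Pre-noise expectation: cortex voxels carry the
baseline, cap-side cortex voxels (angle to the cap axis ≤ half-angle) carry
baseline x enrichment, everything is attenuated by `exp(-z/λ)` and a flat
background (attenuated identically) is added. Attenuating the background
with the same λ is deliberate: per-plane background normalization then
cancels depth decay exactly, which is the behaviour that normalization
exists to deliver. Noise is Poisson on the expected counts followed by
additive Gaussian read noise (`gaussian_sd`). A separate optional
`noise_seed` re-draws only the noise while keeping geometry and cap history
fixed, which replicate studies require; with it unset, everything derives
from the single `seed`. Identical parameter records give bit-identical
movies.

**What the generator does not emulate.** No optical PSF (edges are voxel
sharp), no photobleaching, no cell movement or shape change within cluster
movies, no partial-volume effects, and membranes of touching cells do not
fuse into shared interfaces. Passing tests therefore demonstrate
correctness of the measurement code under the stated statistical structure,
not robustness to segmentation error or optical blur in real movies.

**Walks.** Persistent random walks update the direction as
`d' = normalize(p d + (1 − p) u)` with u uniform on the sphere; directed
walks blend in a bias toward a target (or radially outward when no target
is given) with weight `bias_strength`. Step length is exactly `step_um`
per frame unless `step_sd_um` adds Gaussian variability — the default is
exact steps, but comparisons of *speed distributions* between conditions
need `step_sd_um > 0`, since rank statistics on bit-identical speeds are
meaningless.

## Quantification choices

* **ROI refinement** minimizes intra-class intensity variance over the ROI
  voxels (256-bin Otsu) and keeps the largest connected above-threshold
  component inside the ROI; the result is always a subset of the ROI. A
  near-uniform ROI (< 2 distinct values) is a degenerate-histogram error,
  not a silent empty mask.
* **Erosion partitions** use a full 3 x 3 structuring element in 2D and the
  1-voxel ball in 3D, applied `erosion_radius_px` times (default 2). 2D
  per-slice erosion is the default because the cell outlines these
  procedures start from are drawn per slice. Membrane = mask minus eroded
  mask, cytoplasm = eroded mask; the split is exhaustive and disjoint, and
  erosion that annihilates the mask raises rather than returning an empty
  cytoplasm.
* **Radial bins** are half-open `[lo, hi)` with the last bin closed, so
  every voxel is counted exactly once; empty bins report `n = 0` with NaN
  mean rather than 0, avoiding fake dips. Per-bin SEM is over voxel
  intensities (the pooled-voxel convention); per-cluster aggregation is done
  by computing one profile per cluster and comparing summary statistics
  (centre-to-mid contrast) across clusters. The time-resolved surface is
  bilinear on the (frame-time, bin-centre) grid; source nodes are preserved
  and a single frame returns the static profile untouched.
* **Polarity detection** computes the mean and sample SD (n − 1) over *all*
  cell-mask pixels — not periphery pixels only — because the whole-cell
  statistic is the stabler estimator; this is configurable in principle via
  the params record. Components must exceed `min_region_px` strictly
  (> 10 px). Among several qualifying components the brightest total
  intensity wins, with ties broken by lowest centroid row then column, so
  detection is deterministic. An undetected frame is a valid outcome.
* **Reorientation counting** compares consecutive detected frames and, by
  default, bridges undetected gaps (first detected value after a gap vs the
  last before it), because polarity time series routinely contain short
  detection gaps within otherwise-scored stretches; `across_gaps=False`
  restricts to adjacent frames.
* **Posterior extraction** rotates the image bilinearly and the mask by
  nearest-neighbour so the posterior direction maps to "down", counts the
  rows containing mask pixels, and takes the lowest `ceil(0.20 x rows)`.
  Masks spanning < 5 rows trigger a warning and use the single lowest row.
  The posterior direction may come from the detected polarity axis (default
  in the per-cell workflow) or from the cluster-centre direction.
* **Circularity** is `4πA/P²` with A the pixel count. The perimeter
  estimator defaults to the 4-direction Crofton formula: on rasterized
  disks of r ≥ 20 it is accurate to ~1–3% (circularity 0.97–0.98), whereas
  the marching-squares contour length over-measures staircase boundaries by
  ~7% and naive boundary-pixel counting is worse still. The contour
  estimator remains available (`perimeter_method="contour"`) and its length
  on rectilinear shapes has the closed form `4(s − 1) + 2√2` for an
  s x s square, used as a cross-check.
* **Track linking** is greedy nearest-neighbour with a displacement gate of
  2 x cell radius per frame, deterministic tie-breaking by label, and no
  gap closing (a missing frame starts a new track) — matching a workflow
  where gaps were corrected manually. Speed = path/time and
  straightness = net/path are the standard tracking-software definitions;
  the source names the metrics but not formulas, so the choice is stated
  here prominently.
* **Relative distance** time courses divide each track by its own initial
  distance (first-frame normalization); posterior area/intensity time
  courses normalize to the first frame by default, to the maximum on
  request.
* **Statistics.** Rank-sum: U with midrank ties; exact enumeration when the
  pooled sample is tie-free and `n1 x n2 ≤ 400`, otherwise the normal
  approximation with tie and continuity corrections (the switchover is a
  package policy, stated here because the original analyses ran in
  commercial software whose internals are not documented). Fisher's exact
  two-sided p uses the probability-mass criterion (sum of tables with mass
  ≤ the observed), the most common convention.

## Problem sizes

Default analysis scale (pipeline and acceptance script): two 10-cell
clusters (guided vs random caps) of 2-µm cells at 0.5 x 0.25 x 0.25 µm
voxels, 16 frames, Poisson + Gaussian noise with λ = 30 µm attenuation; two
25-track walk ensembles of 40 frames; 50 noise replicates for the
cap-enrichment recovery; a 30-cell, 2-frame cluster for orientation
recovery. These sizes give the comparisons stable power (reorientation
rank-sum p < 0.02 across seeds) while a full run completes in seconds.

## Known limitations

* Detection on a single slice misses caps pointing along the optical axis;
  such cell-frames are reported undetected, which mirrors practice but
  means orientation statistics are conditioned on detection.
* The synthetic cluster is static; linking is validated on static and
  constructed moving objects, not on crowded motion with identity switches.
* The kymograph propagates NaN from empty bins through interpolated
  neighbourhoods rather than inventing values.
* Circularity of rasterized shapes carries discretization bias that depends
  on the perimeter estimator; comparisons should fix one estimator, and
  absolute values within ~5% of 1 should not be over-interpreted.
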