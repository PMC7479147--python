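# disperseq

Quantification of **cell-cluster dispersal** from multi-channel 4D
fluorescence microscopy, built around the developmental migration of
*Drosophila* primordial germ cells (PGCs): ~30 cells clustered in a rosette
inside the embryonic endoderm that polarize their contractile machinery
(myosin II, active RhoA) toward the cluster centre, pull on cell–cell
contacts, and disperse as single cells. The same measurements distinguish
guided cells from receptor-mutant (*tre1*-like) cells, whose cortical
polarity reorients randomly and which fail to separate.

The package is for microscopists and quantitative biologists who have
time-lapse Z-stacks, label masks and cell tracks and want reproducible,
scriptable versions of the standard cluster-dispersal readouts — plus a
synthetic movie generator with known ground truth so every stage can be
validated without imaging data.

## What it measures

* **Radial intensity profile** — every segmented voxel's intensity is
  normalized to the mean background at its own Z plane (cancelling
  depth-dependent attenuation), assigned a physical distance to the cluster
  centroid `c = mean(voxel positions)`, and binned into 50 equally spaced
  bins. Centre-enriched reporters (active RhoA at posterior membranes)
  produce a profile that decays with distance; a time-resolved variant
  yields a bilinearly interpolated (distance, time) surface.
* **Cortical polarity** — a polarized region is a connected set (> 10 px) of
  cell-periphery pixels brighter than the cell mean + 1.5 SD, the periphery
  being the mask minus its erosion. Its intensity over the cytoplasm defines
  the polarity fold (polarized at ≥ 1.2-fold); the angle θ between
  (cell → region) and (cell → tissue centre) defines the orientation; a
  frame-to-frame shift |Δθ| > 60° is a **reorientation event**.
* **Posterior dynamics** — cells are rotated so the posterior points down;
  the lowest 20% of mask rows define the posterior, whose area and mean
  intensity are tracked over time (contraction = shrinking, brightening
  posterior).
* **Shape and adhesion** — circularity `4πA/P²`, and the
  membrane/cytoplasm intensity ratio from the erosion partition (E-cadherin
  surface retention).
* **Motility** — per-track speed (path length / elapsed time, µm/min),
  straightness (net displacement / path length ∈ [0, 1]),
  distance-from-centre time courses, optogenetic reversal classification and
  cumulative transmigration counts.
* **Statistics** — two-sided Mann–Whitney rank-sum tests (exact for small
  tie-free samples) and Fisher's exact test for proportions, plus
  mean ± SD/SEM summaries.

The synthetic module simulates two-channel rosette movies (membrane +
cortical reporter with an angular cap of enrichment, oriented radially
inward or randomly reorienting), depth attenuation `exp(-z/λ)`,
Poisson + Gaussian noise, and persistent/directed 3D walks — all bit-wise
reproducible from a parameter record.

## Worked example

Run the full two-condition workflow (simulate a guided and a randomly
reorienting cluster, quantify both, compare):

```bash
disperseq run --seed 1 --out results/
```

which prints (abridged):

```json
{
  "wt_mean_orientation_deg": 1.80,
  "mutant_mean_orientation_deg": 91.90,
  "orientation_ranksum_p": 3.3e-35,
  "wt_reorientation_events": [0, 0, 0, 0, 0, 0],
  "mutant_reorientation_events": [1, 3, 1, 0, 1, 2, 1, 1, 0, 0],
  "reorientation_ranksum_p": 0.0126,
  "wt_radial_center_contrast": 1.25,
  "mutant_radial_center_contrast": 0.82,
  "speed_ranksum_p": 0.68,
  "straightness_ranksum_p": 1.4e-09
}
```

Reading this: guided cells keep their cortical cap pointed at the cluster
centre (mean orientation ≈ 2°, zero reorientation events) while mutant-like
cells are orientation-random (≈ 90°) and reorient significantly more often
(rank-sum p ≈ 0.013). The guided cluster's reporter is centre-enriched
(centre/mid contrast 1.25 vs 0.82). The two walk ensembles differ only in
persistence: speeds are statistically indistinguishable (p = 0.68) while
straightness separates them decisively (p ≈ 1e-09) — the motility signature
of guided versus random migration. Per-cell records, radial profiles, track
tables and a provenance record (config hash, seed, versions) are written
under `results/`.

Every subcommand is also usable on real data, e.g.

```bash
disperseq radial --movie movie.ome.tif --mask labels.tif \
    --background bg_roi.tif --bins 50 --out profile.csv
disperseq tracks --in tracks.csv --reference 0,0,0 --relative
```

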