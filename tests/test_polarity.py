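"""Polarity detection, orientation, reorientation and posterior intensity."""

import math

import numpy as np
import pytest

from disperseq import (
    ClusterSimParams,
    Disk,
    PolarityParams,
    detect_polarized_region,
    generate_cluster_movie,
    generate_shape_mask,
    orientation_angle,
    polarity_ratio,
    polarity_timecourse,
    posterior_intensity_timecourse,
    reorientation_events,
)
from disperseq.errors import DisperseqError, UndefinedOrientationError
from disperseq.polarity import membrane_cytoplasm_split
from disperseq.segmentation import periphery_mask


class TestPolarityRatio:
    def test_equal_intensity_gives_unit_ratio(self):
        img = np.full((10, 10), 5.0)
        a = np.zeros_like(img, dtype=bool)
        b = np.zeros_like(img, dtype=bool)
        a[:3], b[5:] = True, True
        ratio, flag = polarity_ratio(img, a, b)
        assert ratio == 1.0 and not flag

    def test_one_point_five_fold(self):
        img = np.full((10, 10), 10.0)
        a = np.zeros_like(img, dtype=bool)
        b = np.zeros_like(img, dtype=bool)
        a[:3], b[5:] = True, True
        img[a] = 15.0
        ratio, flag = polarity_ratio(img, a, b)
        assert ratio == pytest.approx(1.5) and flag

    def test_zero_cytoplasm_mean_raises(self):
        img = np.zeros((5, 5))
        roi = np.ones_like(img, dtype=bool)
        with pytest.raises(DisperseqError):
            polarity_ratio(img, roi, roi)

    def test_noisy_cap_ratio_recovers_noiseless_oracle(self):
        """50 noisy replicates: mean cap/cortex ratio within 3 SE of the
        noiseless-render value (the true enrichment)."""
        base = dict(
            n_cells=1,
            cell_radius_um=2.5,
            cluster_radius_um=7.5,
            n_frames=1,
            background_level=0.0,
            depth_attenuation_um=np.inf,
        )
        noiseless, truth = generate_cluster_movie(
            ClusterSimParams(**base, noise="none", seed=0)
        )
        cap_roi, cortex_roi = cap_and_cortex_rois(noiseless, truth)
        oracle, _ = polarity_ratio(noiseless.channel("reporter")[0], cap_roi, cortex_roi)
        assert oracle == pytest.approx(2.0)

        ratios = []
        for k in range(50):
            movie, _ = generate_cluster_movie(
                ClusterSimParams(
                    **base, noise="poisson_gaussian", gaussian_sd=5.0,
                    seed=0, noise_seed=k,  # same geometry, new noise draw
                )
            )
            r, _ = polarity_ratio(movie.channel("reporter")[0], cap_roi, cortex_roi)
            ratios.append(r)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / math.sqrt(ratios.size)
        assert abs(ratios.mean() - oracle) < 3 * se


def cap_and_cortex_rois(movie, truth):
    """True cap voxels and non-cap cortex voxels from a noiseless render."""
    rep = movie.channel("reporter")[0]
    cap = rep == rep.max()
    cortex = (rep > 0) & ~cap
    return cap, cortex


class TestDetectPolarizedRegion:
    def make_cell(self, radius=15):
        mask = generate_shape_mask(Disk(radius)).astype(bool)
        img = np.full(mask.shape, 50.0)
        img[~mask] = 0.0
        return img, mask

    def test_uniform_cortex_is_undetected(self):
        img, mask = self.make_cell()
        assert detect_polarized_region(img, mask) is None

    def test_patch_at_min_size_is_undetected(self):
        img, mask = self.make_cell()
        periph = periphery_mask(mask, 2)
        coords = np.argwhere(periph)[:9]
        img[tuple(coords.T)] = 500.0
        # 9 px <= min_region_px -> no qualifying component
        det = detect_polarized_region(img, mask, PolarityParams(min_region_px=10))
        assert det is None

    def test_bright_cap_matches_connected_component_oracle(self):
        """Detected pixel set equals a hand-rolled flood-fill on the candidates."""
        img, mask = self.make_cell()
        periph = periphery_mask(mask, 2)
        rows = np.argwhere(periph)
        top = rows[rows[:, 0] <= rows[:, 0].min() + 3]  # ~cap at the top
        img[tuple(top.T)] = 500.0
        det = detect_polarized_region(img, mask)
        assert det is not None
        region, centroid = det

        vals = img[mask]
        mu, sd = vals.mean(), vals.std(ddof=1)
        candidates = periph & (img > mu + 1.5 * sd)
        # flood fill (8-connectivity) oracle
        seen = np.zeros_like(candidates)
        comps = []
        for seed in map(tuple, np.argwhere(candidates)):
            if seen[seed]:
                continue
            stack, comp = [seed], []
            seen[seed] = True
            while stack:
                i, j = stack.pop()
                comp.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (
                            0 <= ni < candidates.shape[0]
                            and 0 <= nj < candidates.shape[1]
                            and candidates[ni, nj]
                            and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            comps.append(comp)
        big = [c for c in comps if len(c) > 10]
        assert len(big) == 1
        oracle = np.zeros_like(candidates)
        oracle[tuple(np.array(big[0]).T)] = True
        assert np.array_equal(region, oracle)
        assert np.allclose(centroid, np.argwhere(oracle).mean(axis=0))

    def test_brightest_component_wins(self):
        img, mask = self.make_cell()
        periph = periphery_mask(mask, 2)
        rows = np.argwhere(periph)
        top = rows[rows[:, 0] <= rows[:, 0].min() + 3]
        bottom = rows[rows[:, 0] >= rows[:, 0].max() - 3]
        img[tuple(top.T)] = 400.0
        img[tuple(bottom.T)] = 500.0
        det = detect_polarized_region(img, mask)
        assert det is not None
        _, centroid = det
        assert centroid[0] > mask.shape[0] / 2  # picked the brighter bottom cap


class TestOrientationAngle:
    @pytest.mark.parametrize(
        "region, expected",
        [((0, 5), 0.0), ((0, -5), 180.0), ((5, 0), 90.0)],
    )
    def test_constructed_geometries(self, region, expected):
        assert orientation_angle((0, 0), region, (0, 10)) == pytest.approx(expected)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            cell = rng.normal(size=3)
            region = cell + rng.normal(size=3)
            ref = cell + rng.normal(size=3)
            base = orientation_angle(cell, region, ref)
            # random rotation via QR decomposition
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            rot = lambda p: q @ p
            assert orientation_angle(rot(cell), rot(region), rot(ref)) == pytest.approx(base)

    def test_zero_vector_raises(self):
        with pytest.raises(UndefinedOrientationError):
            orientation_angle((0, 0), (0, 0), (1, 1))


class TestReorientationEvents:
    def test_constant_series_has_no_events(self):
        assert reorientation_events([30.0] * 10) == 0

    def test_single_large_shift(self):
        assert reorientation_events([10.0, 80.0]) == 1

    def test_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(13)
        series = rng.uniform(0, 180, size=300).astype(object)
        gaps = rng.choice(300, size=60, replace=False)
        for g in gaps:
            series[g] = None
        count = reorientation_events(series, threshold_deg=60.0)
        detected = [s for s in series if s is not None]
        oracle = sum(
            1 for a, b in zip(detected[:-1], detected[1:]) if abs(b - a) > 60.0
        )
        assert count == oracle

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(14)
        series = rng.uniform(0, 120, size=50)
        assert reorientation_events(series) == reorientation_events(series + 37.0)

    def test_skip_gap_mode(self):
        series = [10.0, None, 80.0, 85.0]
        assert reorientation_events(series, across_gaps=True) == 1
        assert reorientation_events(series, across_gaps=False) == 0

    def test_too_few_detected_raises(self):
        with pytest.raises(DisperseqError):
            reorientation_events([None, 30.0, None])


class TestPosteriorIntensity:
    def make_cell(self, radius=15, base=10.0):
        mask = generate_shape_mask(Disk(radius)).astype(bool)
        img = np.full(mask.shape, 0.0)
        img[mask] = base
        return img, mask

    def test_uniform_cell_equals_whole_cell_mean(self):
        img, mask = self.make_cell()
        out = posterior_intensity_timecourse(
            img[None], mask[None], np.array([[1.0, 0.0]])
        )
        assert out[0] == pytest.approx(img[mask].mean())

    def test_bottom_rows_twice_as_bright_no_rotation(self):
        img, mask = self.make_cell()
        rows = np.flatnonzero(mask.any(axis=1))
        n_post = math.ceil(0.2 * rows.size)
        post = np.zeros_like(mask)
        post[rows[-n_post:]] = True
        post &= mask
        img[post] = 20.0
        out = posterior_intensity_timecourse(
            img[None], mask[None], np.array([[1.0, 0.0]])
        )
        upper_mean = img[mask & ~post].mean()
        assert out[0] == pytest.approx(2.0 * upper_mean)

    def test_rotated_cap_matches_ground_truth_pixel_oracle(self):
        """Posterior pointing right: rotation recovers the unrotated-cap mean
        within interpolation tolerance (< 2% relative error)."""
        img, mask = self.make_cell()
        cols = np.flatnonzero(mask.any(axis=0))
        n_post = math.ceil(0.2 * cols.size)
        cap = np.zeros_like(mask)
        cap[:, cols[-n_post:]] = True
        cap &= mask
        img[cap] = 20.0
        out = posterior_intensity_timecourse(
            img[None], mask[None], np.array([[0.0, 1.0]])
        )
        oracle = img[cap].mean()
        assert abs(out[0] - oracle) / oracle < 0.02

    def test_small_cell_warns_and_uses_lowest_row(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:7, 2:8] = True
        img = np.full((10, 10), 5.0)
        img[6] = 9.0
        with pytest.warns(UserWarning, match="rows"):
            out = posterior_intensity_timecourse(
                img[None], mask[None], np.array([[1.0, 0.0]])
            )
        assert out[0] == pytest.approx(9.0)


class TestPolarityTimecourse:
    def test_zero_reporter_all_undetected(self):
        labels = np.zeros((3, 30, 30), dtype=int)
        disk = generate_shape_mask(Disk(10)).astype(bool)
        labels[:, 3 : 3 + disk.shape[0], 3 : 3 + disk.shape[1]] = disk
        images = np.zeros_like(labels, dtype=float)
        records = polarity_timecourse(images, labels, (15.0, 15.0))
        assert len(records) == 3
        assert not any(r.detected for r in records)

    def test_records_match_componentwise_oracle(self):
        """Each record equals running the detection/ratio/orientation steps
        individually on that frame."""
        rng = np.random.default_rng(23)
        disk = generate_shape_mask(Disk(12)).astype(bool)
        labels = np.zeros((4, 30, 30), dtype=int)
        labels[:, 1 : 1 + disk.shape[0], 1 : 1 + disk.shape[1]] = disk
        images = rng.uniform(0, 30, size=labels.shape)
        # add a moving bright arc so some frames detect
        for t in range(4):
            periph = periphery_mask(labels[t] == 1, 2)
            coords = np.argwhere(periph)
            sel = coords[t * 12 : t * 12 + 14]
            images[t][tuple(sel.T)] = 300.0
        ref = (40.0, 40.0)
        params = PolarityParams()
        records = polarity_timecourse(images, labels, ref, params=params)
        assert len(records) == 4
        for rec in records:
            mask = labels[rec.frame] == 1
            det = detect_polarized_region(images[rec.frame], mask, params)
            assert rec.detected == (det is not None)
            if det is None:
                continue
            region, centroid = det
            _, cyto = membrane_cytoplasm_split(mask, params.erosion_radius_px)
            ratio, _ = polarity_ratio(images[rec.frame], region, cyto, params)
            assert rec.polarized_intensity == pytest.approx(ratio)
            cell_c = np.argwhere(mask).mean(axis=0)
            assert rec.orientation_deg == pytest.approx(
                orientation_angle(cell_c, centroid, ref)
            )
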