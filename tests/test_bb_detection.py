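"""Maxima finding, adaptive thresholding, interior and OA filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

import ciliarray as ca
from ciliarray.bb_detection import (
    adaptive_threshold, box_moments, classify_oral_apparatus, find_maxima,
    interior_depths, remove_interior,
)
from ciliarray.io_config import ImageStack, PipelineConfig
from tests.conftest import match_to_ground_truth


def spot_stack(centers_um, amps=None, shape=(20, 80, 80),
               voxel=(0.3, 0.125, 0.125), sigma=(0.1, 0.1, 0.35), base=0.0):
    """Small stack with Gaussian spots at given µm positions."""
    dz, dy, dx = voxel
    img = np.full(shape, base, dtype=np.float64)
    if amps is None:
        amps = [1000.0] * len(centers_um)
    zz = np.arange(shape[0]) * dz
    yy = np.arange(shape[1]) * dy
    xx = np.arange(shape[2]) * dx
    for (x, y, z), a in zip(centers_um, amps):
        img += a * (
            np.exp(-0.5 * ((zz - z) / sigma[2]) ** 2)[:, None, None]
            * np.exp(-0.5 * ((yy - y) / sigma[1]) ** 2)[None, :, None]
            * np.exp(-0.5 * ((xx - x) / sigma[0]) ** 2)[None, None, :]
        )
    return ImageStack(img.astype(np.float32), voxel)


class TestFindMaxima:
    def test_two_spots_beyond_search_radius(self):
        stack = spot_stack([(3.0, 3.0, 3.0), (4.0, 3.0, 3.0)])
        maxima = find_maxima(stack)
        assert len(maxima) == 2

    def test_two_spots_within_search_radius_merge(self):
        stack = spot_stack([(3.0, 3.0, 3.0), (3.2, 3.0, 3.0)])
        maxima = find_maxima(stack)
        assert len(maxima) == 1

    def test_plateau_tie_keeps_lexicographic_smallest(self):
        img = np.zeros((5, 9, 9), dtype=np.float32)
        img[2, 4, 4] = img[2, 4, 5] = 7.0  # flat two-voxel plateau
        stack = ImageStack(img, (0.3, 0.125, 0.125))
        cfg = PipelineConfig(detect_sigma_um=1e-6)  # effectively no smoothing
        maxima = find_maxima(stack, cfg)
        assert len(maxima) == 1
        assert (maxima.iloc[0].iy, maxima.iloc[0].ix) == (4, 4)

    def test_calibration_too_coarse(self):
        stack = ImageStack(np.ones((4, 6, 6), np.float32), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="too coarse"):
            find_maxima(stack)

    def test_ground_truth_recovered_on_clean_cell(self, clean_cell):
        spec, gt, stack = clean_cell
        cropped, offset, _ = ca.extract_cell(stack)
        maxima = find_maxima(cropped)
        pos = maxima[["x_um", "y_um", "z_um"]].to_numpy() + offset
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(gt.bb_positions, k=1)
        dz, dy, dx = spec.voxel_size
        assert (d <= np.linalg.norm([dx, dy, dz])).mean() >= 0.99


class TestAdaptiveThreshold:
    @staticmethod
    def df(zs, intensities):
        return pd.DataFrame({
            "iz": np.zeros(len(zs), int), "iy": 0, "ix": 0,
            "x_um": 0.0, "y_um": 0.0, "z_um": np.asarray(zs, float),
            "intensity": np.asarray(intensities, float),
            "accepted": True, "reason": "none", "threshold": np.nan,
        })

    def test_printed_formula_value(self):
        # window: avg 100, sd 10, cv 0.1 -> threshold (5.4 * 10) + 100 = 154
        maxima = self.df([0.0, 0.0], [90.0, 110.0])
        out = adaptive_threshold(maxima)
        assert np.allclose(out["threshold"], 154.0)
        assert not out["accepted"].any()

    def test_degenerate_equal_intensities(self):
        maxima = self.df([0.0] * 5, [100.0] * 5)
        out = adaptive_threshold(maxima)
        # sd = 0 -> threshold = mean; nothing is strictly above it
        assert np.allclose(out["threshold"], 100.0)
        assert not out["accepted"].any()

    def test_multiplier_clamped_when_cv_above_one(self):
        vals = [1.0, 1.0, 1.0, 1.0, 500.0]  # cv > 1
        maxima = self.df([0.0] * 5, vals)
        out = adaptive_threshold(maxima)
        assert np.allclose(out["threshold"], np.mean(vals))
        assert out["accepted"].sum() == 1  # only the bright one exceeds the mean

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(0)
        zs = rng.uniform(0, 10, 200).round(1)
        vals = rng.lognormal(4.0, 0.5, 200)
        a = adaptive_threshold(self.df(zs, vals))
        b = adaptive_threshold(self.df(zs, vals * 7.3))
        assert np.array_equal(a["accepted"], b["accepted"])
        assert np.allclose(b["threshold"], a["threshold"] * 7.3, rtol=1e-12)

    def test_rolling_window_is_local(self):
        # bright plane far from a dim plane: each judged by its own window
        zs = [0.0] * 20 + [10.0] * 20
        vals = [100.0 + i for i in range(20)] + [1000.0 + i for i in range(20)]
        out = adaptive_threshold(self.df(zs, vals))
        thr_near = out.loc[out.z_um == 0.0, "threshold"].iloc[0]
        thr_far = out.loc[out.z_um == 10.0, "threshold"].iloc[0]
        assert thr_far > thr_near * 5

    def test_needs_two_maxima(self):
        with pytest.raises(ValueError):
            adaptive_threshold(self.df([0.0], [1.0]))


def exact_hull_surface_distance(points):
    """Oracle: exact min distance to any hull facet *triangle* (interior pts)."""
    hull = ConvexHull(points)
    out = np.full(len(points), np.inf)
    for simplex in hull.simplices:
        a, b, c = points[simplex]
        for i, p in enumerate(points):
            out[i] = min(out[i], _point_triangle_distance(p, a, b, c))
    return out


def _point_triangle_distance(p, a, b, c):
    # standard region-based point/triangle distance
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(ap - t * ab)
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(ap - t * ac)
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + t * (c - b)))
    n = np.cross(ab, ac)
    return abs(ap @ (n / np.linalg.norm(n)))


class TestRemoveInterior:
    @staticmethod
    def sphere_cloud(n=50, r=10.0, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        return r * v / np.linalg.norm(v, axis=1)[:, None]

    @staticmethod
    def as_df(points):
        return pd.DataFrame({
            "iz": 0, "iy": 0, "ix": 0,
            "x_um": points[:, 0], "y_um": points[:, 1], "z_um": points[:, 2],
            "intensity": 1.0, "accepted": True, "reason": "none",
            "threshold": np.nan,
        })

    def test_hull_vertices_retained(self):
        pts = self.sphere_cloud(40)
        out = remove_interior(self.as_df(pts))
        assert out["accepted"].all()

    def test_deep_internal_points_deleted(self):
        surface = self.sphere_cloud(200, r=10.0)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(10, 3))
        internal = 7.0 * v / np.linalg.norm(v, axis=1)[:, None]  # depth ~3 µm
        df = self.as_df(np.vstack([surface, internal]))
        out = remove_interior(df)
        assert out["accepted"][:200].all()
        assert not out["accepted"][200:].any()
        assert (out["reason"][200:] == "interior").all()

    def test_shallow_point_within_cut_kept(self):
        surface = self.sphere_cloud(60, r=10.0)
        shallow = np.array([[0.0, 0.0, 8.5]])  # ~1.5 µm deep < 2.25
        out = remove_interior(self.as_df(np.vstack([surface, shallow])))
        assert out["accepted"].iloc[-1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_point_to_facet_oracle(self, seed):
        rng = np.random.default_rng(seed)
        surface = self.sphere_cloud(30, r=8.0, seed=seed)
        inner = rng.uniform(-4, 4, size=(15, 3))
        pts = np.vstack([surface, inner])
        depths = interior_depths(pts)
        oracle = exact_hull_surface_distance(pts)
        assert np.allclose(depths, oracle, atol=1e-9)

    def test_degenerate_coplanar_skipped(self):
        pts = np.zeros((6, 3))
        pts[:, 0] = np.arange(6)
        pts[:, 1] = [0, 1, 2, 0, 1, 2]
        out = remove_interior(self.as_df(pts))
        assert out["accepted"].all()  # filter skipped, nothing deleted


class TestClassifyOA:
    def test_isolated_spot_positive_skew_kurtosis(self):
        stack = spot_stack([(5.0, 5.0, 3.0)], amps=[1000.0], base=10.0)
        maxima = find_maxima(stack)
        out = classify_oral_apparatus(maxima, stack)
        m = out.iloc[out["intensity"].idxmax()]
        assert m["skew"] > 0 and m["kurtosis"] > 0
        assert m["accepted"]

    def test_uniform_box_degenerate_excluded(self):
        img = np.full((5, 40, 40), 50.0, dtype=np.float32)
        img[2, 20, 20] = 50.0  # plateau; any maximum has a constant box
        stack = ImageStack(img, (0.3, 0.125, 0.125))
        maxima = find_maxima(stack)
        out = classify_oral_apparatus(maxima, stack)
        assert not out["accepted"].any()
        assert (out["reason"] == "oral_apparatus").all()

    def test_box_moments_degenerate(self):
        plane = np.zeros((20, 20))
        sk, ku, clipped = box_moments(plane, 10, 10, 4)
        assert np.isnan(sk) and np.isnan(ku)

    def test_box_clipped_at_edge_flagged(self):
        stack = spot_stack([(0.2, 0.2, 3.0)], base=10.0)
        maxima = find_maxima(stack)
        out = classify_oral_apparatus(maxima, stack)
        assert out["box_clipped"].any()

    def test_synthetic_oa_cluster_excluded(self, analyzed_default):
        gt, res = analyzed_default
        oa_est = res.cell_stack.oa_centroid + res.crop_offset_um
        assert np.linalg.norm(oa_est - gt.oa_centroid) <= 1.5


class TestPipelineProperties:
    def test_monotone_shrinkage_and_flags(self, analyzed_default):
        _, res = analyzed_default
        audit = res.audit
        # accepted implies no rejection reason, and every rejection has one
        assert (audit.loc[audit["accepted"], "reason"] == "none").all()
        assert (audit.loc[~audit["accepted"], "reason"] != "none").all()
        # each stage only removes: counts ordered
        n_all = len(audit)
        n_thr = (audit["reason"] != "noise").sum()
        n_int = n_thr - (audit["reason"] == "interior").sum()
        n_cort = audit["accepted"].sum()
        assert n_all >= n_thr >= n_int >= n_cort > 0

    def test_detection_performance_on_noisy_default(self, analyzed_default):
        gt, res = analyzed_default
        recall, precision, _, _ = match_to_ground_truth(gt, res)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_far_surface_bbs_survive_attenuation(self, default_cell, analyzed_default):
        spec, gt, _ = default_cell
        _, res = analyzed_default
        far = gt.bb_positions[:, 2] > spec.center[2] + 0.5 * spec.semi_axes[2]
        from scipy.spatial import cKDTree
        det = res.cell_stack.positions + res.crop_offset_um
        d, _ = cKDTree(det).query(gt.bb_positions[far], k=1)
        assert (d <= 0.5).mean() >= 0.9
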