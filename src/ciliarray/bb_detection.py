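"""Identify individual basal bodies in 3D despite depth-dependent attenuation.

Stage order is fixed and monotone (each stage only removes candidates):

1. ``find_maxima`` — smooth the BB channel with a small Gaussian and collect
   every 3D local maximum within an anisotropic ellipsoidal neighbourhood
   (0.25 µm in xy, 0.6 µm in z — the approximate size of one BB).
2. ``adaptive_threshold`` — separate real BB peaks from noise peaks with a
   depth-adaptive intensity threshold computed from the population of maxima
   in a rolling 1.5 µm z window: ``((s − cv·s)·sd) + avg`` with sensitivity
   ``s = 6``.  Because the statistics roll with z, BBs on the far side of the
   cell survive the threshold despite strong signal attenuation.
3. ``remove_interior`` — delete maxima deeper than 2.25 µm under the surface
   of the convex hull of all accepted maxima (internalized BBs).
4. ``classify_oral_apparatus`` — reject maxima sitting on the homogeneous
   bright oral-apparatus plateau using the skewness + kurtosis of the pixel
   histogram in a 1 µm² box (cortical BBs: peaked, positive; OA: flat,
   negative; excluded when the sum is < 1).

The per-maximum audit trail (stage, local threshold, box statistics) is kept
on the returned table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import ConvexHull, cKDTree

from .io_config import ImageStack, PipelineConfig, logger


def _ellipsoid_footprint(voxel_size, r_xy_um, r_z_um) -> np.ndarray:
    """Boolean (z, y, x) footprint of the anisotropic search neighbourhood."""
    dz, dy, dx = voxel_size
    rz = int(np.floor(r_z_um / dz))
    ry = int(np.floor(r_xy_um / dy))
    rx = int(np.floor(r_xy_um / dx))
    if max(rz, ry, rx) < 1:
        raise ValueError(
            "calibration too coarse: maxima search neighbourhood smaller than one voxel"
        )
    zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    return (
        (zz * dz / r_z_um) ** 2
        + (yy * dy / r_xy_um) ** 2
        + (xx * dx / r_xy_um) ** 2
    ) <= 1.0 + 1e-9


def find_maxima(stack: ImageStack, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """All 3D local maxima of the smoothed BB channel (no intensity cut yet).

    A voxel is a maximum iff its smoothed intensity is >= every voxel in the
    ellipsoidal neighbourhood; plateau ties keep the lexicographically
    smallest (z, y, x).  Zero-intensity voxels (the region zeroed by the cell
    crop) are not peaks.  Returns a table with voxel and µm positions and the
    smoothed peak intensity.
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    img = stack.channel(cfg.bb_channel).astype(np.float32)
    sigma = (cfg.detect_sigma_um / dz, cfg.detect_sigma_um / dy, cfg.detect_sigma_um / dx)
    smoothed = ndi.gaussian_filter(img, sigma)

    fp = _ellipsoid_footprint(stack.voxel_size, cfg.maxima_xy_um, cfg.maxima_z_um)
    maxf = ndi.maximum_filter(smoothed, footprint=fp, mode="nearest")
    cand = (smoothed >= maxf) & (smoothed > 0)
    zz, yy, xx = np.nonzero(cand)
    vals = smoothed[zz, yy, xx]

    # plateau tie-break: among equal-valued candidates within one search
    # radius of each other, keep the lexicographically smallest coordinate
    # (greedy non-max suppression in lexicographic order)
    if len(vals):
        order = np.lexsort((xx, yy, zz))
        zz, yy, xx, vals = zz[order], yy[order], xx[order], vals[order]
        _, inverse, counts = np.unique(vals, return_inverse=True, return_counts=True)
        drop = np.zeros(len(vals), dtype=bool)
        if np.any(counts > 1):
            scaled = np.column_stack(
                [zz * dz / cfg.maxima_z_um, yy * dy / cfg.maxima_xy_um,
                 xx * dx / cfg.maxima_xy_um]
            )
            for v_idx in np.flatnonzero(counts > 1):
                members = np.flatnonzero(inverse == v_idx)  # lexicographic order
                tree = cKDTree(scaled[members])
                pairs = tree.query_pairs(1.0 + 1e-9, output_type="ndarray")
                if len(pairs) == 0:
                    continue
                adj = [[] for _ in range(len(members))]
                for a, b in pairs:  # a < b holds for query_pairs
                    adj[a].append(b)
                local_drop = np.zeros(len(members), dtype=bool)
                for a in range(len(members)):
                    if local_drop[a]:
                        continue
                    local_drop[adj[a]] = True
                drop[members[local_drop]] = True
        zz, yy, xx, vals = zz[~drop], yy[~drop], xx[~drop], vals[~drop]

    df = pd.DataFrame({
        "iz": zz.astype(int), "iy": yy.astype(int), "ix": xx.astype(int),
        "x_um": xx * dx, "y_um": yy * dy, "z_um": zz * dz,
        "intensity": vals.astype(float),
    })
    df["accepted"] = True
    df["reason"] = "none"
    df["threshold"] = np.nan
    logger.info("find_maxima: %d local maxima", len(df))
    return df


def adaptive_threshold(maxima: pd.DataFrame,
                       cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Apply the rolling-z adaptive intensity threshold to the maxima table.

    For each z plane the statistics (avg, sd, cv) are computed over the peak
    intensities of *all* maxima whose z lies within ±half the rolling window
    (1.5 µm total).  A maximum is accepted iff its intensity exceeds
    ``((s − cv·s)·sd) + avg``; the multiplier is clamped at zero when cv > 1
    so the threshold never drops below the window mean.
    """
    cfg = cfg or PipelineConfig()
    if len(maxima) < 2:
        raise ValueError("adaptive threshold needs at least 2 maxima")
    df = maxima.copy()
    z = df["z_um"].to_numpy()
    inten = df["intensity"].to_numpy()
    half = cfg.rolling_z_um / 2.0
    all_avg, all_sd = float(inten.mean()), float(inten.std())

    thr = np.empty(len(df))
    for plane in np.unique(z):
        sel = np.abs(z - plane) <= half + 1e-9
        window = inten[sel]
        here = z == plane
        if window.size == 0:  # defensive; the plane's own maxima are in-window
            logger.warning("empty rolling window at z=%.2f µm; whole-stack stats", plane)
            avg, sd = all_avg, all_sd
        else:
            avg, sd = float(window.mean()), float(window.std())
        cv = sd / avg if avg > 0 else 0.0
        mult = max(cfg.sensitivity - cv * cfg.sensitivity, 0.0)
        thr[here] = mult * sd + avg

    df["threshold"] = thr
    reject = ~(inten > thr) & df["accepted"].to_numpy()
    df.loc[reject, "accepted"] = False
    df.loc[reject, "reason"] = "noise"
    logger.info("adaptive_threshold: %d/%d maxima accepted",
                int(df["accepted"].sum()), len(df))
    return df


def interior_depths(points: np.ndarray) -> np.ndarray:
    """Depth of each point under the surface of the points' own convex hull.

    For a point inside a convex polytope the distance to the boundary equals
    the minimum over facets of the (positive) plane distance; hull vertices
    get depth 0.
    """
    hull = ConvexHull(points)
    # equations: a·p + b <= 0 inside, |a| = 1
    signed = points @ hull.equations[:, :3].T + hull.equations[:, 3]
    return np.maximum(-signed.max(axis=1), 0.0)


def remove_interior(maxima: pd.DataFrame,
                    cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Delete accepted maxima deeper than the interior cut under the hull."""
    cfg = cfg or PipelineConfig()
    df = maxima.copy()
    acc = df["accepted"].to_numpy()
    pts = df.loc[acc, ["x_um", "y_um", "z_um"]].to_numpy()
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        logger.warning("interior filter skipped: degenerate point set (%d points)", len(pts))
        return df
    depth = interior_depths(pts)
    deep = depth > cfg.interior_depth_um
    idx = df.index[acc][deep]
    df.loc[idx, "accepted"] = False
    df.loc[idx, "reason"] = "interior"
    logger.info("remove_interior: deleted %d interior maxima", int(deep.sum()))
    return df


def box_moments(plane: np.ndarray, iy: int, ix: int, half_px: int):
    """Sample skewness and excess kurtosis of a (2·half+1)² box on a
    background-subtracted plane (bias-uncorrected moment definitions).

    Returns ``(skew, kurtosis, clipped)``; degenerate (zero-variance) boxes
    return NaNs.
    """
    ny, nx = plane.shape
    y0, y1 = max(0, iy - half_px), min(ny, iy + half_px + 1)
    x0, x1 = max(0, ix - half_px), min(nx, ix + half_px + 1)
    clipped = (y1 - y0) != 2 * half_px + 1 or (x1 - x0) != 2 * half_px + 1
    vals = plane[y0:y1, x0:x1].ravel()
    if vals.size < 4 or np.ptp(vals) == 0:
        return np.nan, np.nan, clipped
    sk = float(stats.skew(vals, bias=True))
    ku = float(stats.kurtosis(vals, fisher=True, bias=True))
    return sk, ku, clipped


def classify_oral_apparatus(maxima: pd.DataFrame, stack: ImageStack,
                            cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Split accepted maxima into cortical BBs and oral-apparatus maxima.

    The box statistics are computed on the raw, plane-mean-subtracted
    z-plane of the BB channel.  Maxima whose skew + kurtosis is below the
    cutoff (or undefined) are reclassified as ``oral_apparatus`` but kept in
    the table so the OA centroid can be located downstream.
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    img = stack.channel(cfg.bb_channel)
    half_px = max(1, int(round(np.sqrt(cfg.shape_box_um2) / 2.0 / dx)))

    df = maxima.copy()
    for col, default in (("skew", np.nan), ("kurtosis", np.nan), ("box_clipped", False)):
        df[col] = default

    planes = {}
    acc_idx = df.index[df["accepted"]]
    for i in acc_idx:
        iz = int(df.at[i, "iz"])
        if iz not in planes:
            p = img[iz].astype(np.float64)
            planes[iz] = p - p.mean()
        sk, ku, clipped = box_moments(planes[iz], int(df.at[i, "iy"]),
                                      int(df.at[i, "ix"]), half_px)
        df.at[i, "skew"], df.at[i, "kurtosis"], df.at[i, "box_clipped"] = sk, ku, clipped
        if not np.isfinite(sk) or not np.isfinite(ku) or sk + ku < cfg.skewkurt_cutoff:
            df.at[i, "accepted"] = False
            df.at[i, "reason"] = "oral_apparatus"
    n_oa = int((df["reason"] == "oral_apparatus").sum())
    logger.info("classify_oral_apparatus: %d OA maxima, %d cortical BBs",
                n_oa, int(df["accepted"].sum()))
    return df


def measure_bb_intensities(stack: ImageStack, positions_um: np.ndarray,
                           cfg: PipelineConfig | None = None) -> np.ndarray:
    """Background-subtracted integrated intensity per BB and channel.

    The integral runs over a 0.5 µm-radius sphere at the BB position; the
    local background is the median of a surrounding shell (1–1.8× radius).
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    r = cfg.intensity_radius_um
    rz, ry, rx = int(np.ceil(1.8 * r / dz)), int(np.ceil(1.8 * r / dy)), int(np.ceil(1.8 * r / dx))
    zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    dist = np.sqrt((zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2)
    core = dist <= r
    shell = (dist > r) & (dist <= 1.8 * r)

    pos = np.atleast_2d(positions_um)
    out = np.zeros((len(pos), stack.n_channels))
    nz, ny, nx = stack.shape_zyx
    for ch in range(stack.n_channels):
        img = stack.voxels[ch]
        for i, (x, y, z) in enumerate(pos):
            iz, iy, ix = int(round(z / dz)), int(round(y / dy)), int(round(x / dx))
            z0, z1 = max(0, iz - rz), min(nz, iz + rz + 1)
            y0, y1 = max(0, iy - ry), min(ny, iy + ry + 1)
            x0, x1 = max(0, ix - rx), min(nx, ix + rx + 1)
            sub = img[z0:z1, y0:y1, x0:x1]
            cz, cy, cx = iz - z0, iy - y0, ix - x0
            fz = slice(rz - cz, rz - cz + sub.shape[0])
            fy = slice(ry - cy, ry - cy + sub.shape[1])
            fx = slice(rx - cx, rx - cx + sub.shape[2])
            m_core = core[fz, fy, fx]
            m_shell = shell[fz, fy, fx]
            bg = float(np.median(sub[m_shell])) if m_shell.any() else 0.0
            out[i, ch] = float((sub[m_core] - bg).sum())
    return out


def detect_bbs(stack: ImageStack, cfg: PipelineConfig | None = None):
    """Run the full detection chain on a cropped single-cell stack.

    Returns ``(bbs, oa_maxima, audit)``: the cortical BB table (µm positions,
    per-channel intensities, box statistics), the OA-classified maxima and
    the complete audit table of every local maximum.
    """
    cfg = cfg or PipelineConfig()
    audit = find_maxima(stack, cfg)
    audit = adaptive_threshold(audit, cfg)
    audit = remove_interior(audit, cfg)
    audit = classify_oral_apparatus(audit, stack, cfg)

    bbs = audit[audit["accepted"]].reset_index(drop=True).copy()
    oa = audit[audit["reason"] == "oral_apparatus"].reset_index(drop=True).copy()
    if len(bbs):
        inten = measure_bb_intensities(
            stack, bbs[["x_um", "y_um", "z_um"]].to_numpy(), cfg
        )
        for ch, name in enumerate(stack.channel_names):
            bbs[f"intensity_{name}"] = inten[:, ch]
    return bbs, oa, audit
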