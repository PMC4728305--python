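"""Cell polarity, oral-apparatus location and ciliary-row linking.

From the cortical BB point cloud this module determines the anteroposterior
axis (the BB pairs with the greatest separation), assigns polarity (the
anterior pole carries more closely spaced, hence brighter-integrating, BBs
and the oral apparatus), and connects each BB to its anterior partner within
a ciliary row using a geometric score: the candidate's distance plus its
distance from the plane through the BB and the two poles.  Links are made
only when the forward and reverse searches agree on the same reciprocal
pair; leftovers fall back to the closest free candidate under 5 µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree

from .io_config import ImageStack, PipelineConfig, logger


class PolarityError(RuntimeError):
    """Polarity could not be established."""


@dataclass
class CellModel:
    """One reconstructed cell: cortical BBs, poles, OA and hull geometry."""

    bbs: pd.DataFrame                  # per-BB table incl. x_um/y_um/z_um
    pole_anterior: np.ndarray
    pole_posterior: np.ndarray
    oa_centroid: np.ndarray | None
    hull_surface_area: float
    hull_volume: float
    polarity_flag: str = "ok"          # ok | oa_override | no_oa

    @property
    def axis(self) -> np.ndarray:
        """Unit vector pointing posterior → anterior."""
        v = self.pole_anterior - self.pole_posterior
        return v / np.linalg.norm(v)

    @property
    def positions(self) -> np.ndarray:
        return self.bbs[["x_um", "y_um", "z_um"]].to_numpy()


@dataclass
class RowGraph:
    """Directed anterior-partner links between BBs.

    ``links`` has one row per BB with columns ``bb_id``, ``anterior_id``
    (-1 = unlinked), ``length_um``, ``angdev_deg`` and ``provenance``
    (reciprocal | fallback | unlinked).  In- and out-degree are both ≤ 1, so
    links form disjoint chains running posterior → anterior.
    """

    links: pd.DataFrame

    @property
    def linked(self) -> pd.DataFrame:
        return self.links[self.links["anterior_id"] >= 0]


# ---------------------------------------------------------------------------
# poles and polarity
# ---------------------------------------------------------------------------

def find_poles(positions: np.ndarray, n_extreme: int = 10):
    """Locate the two cell poles from the BB point cloud.

    Each BB's maximum distance to any other BB is computed; the ``2·n``
    BBs with the greatest such distances are the most anterior and most
    posterior BBs.  They are split into the two end clusters by the sign of
    their projection on the cloud's principal axis, and each pole is the
    centroid of its cluster.
    """
    p = np.asarray(positions, dtype=float)
    if len(p) < 2 * n_extreme:
        raise ValueError(f"need at least {2 * n_extreme} BBs to locate poles")
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    maxdist = np.sqrt(d2.max(axis=1))
    top = np.argsort(maxdist)[-2 * n_extreme:]

    sel = p[top] - p.mean(axis=0)
    # principal axis of the extreme points
    _, _, vt = np.linalg.svd(sel - sel.mean(axis=0), full_matrices=False)
    proj = sel @ vt[0]
    side_a, side_b = top[proj > 0], top[proj <= 0]
    if len(side_a) == 0 or len(side_b) == 0 or np.ptp(proj) < 1e-6:
        raise PolarityError("pole clusters not separable: point cloud has no elongation")
    pole_a, pole_b = p[side_a].mean(axis=0), p[side_b].mean(axis=0)
    # the pole clusters of an elongated cell sit at the ends of the cloud; on
    # a round cloud the extreme points scatter and their centroids collapse
    # toward the centre
    if np.linalg.norm(pole_a - pole_b) < 0.8 * maxdist.max():
        raise PolarityError("pole clusters not separable: point cloud has no elongation")
    return pole_a, pole_b


def locate_oral_apparatus(oa_maxima: pd.DataFrame,
                          cluster_um: float = 2.0) -> np.ndarray | None:
    """Centroid of the oral apparatus from the OA-classified maxima.

    The OA appears as one continuous cluster of homogeneous peaks; stray
    isolated misclassifications elsewhere on the cortex are excluded by
    keeping only the largest single-linkage cluster (link radius
    ``cluster_um``) before taking the centroid.  Returns ``None`` when no
    maxima were OA-classified.
    """
    if oa_maxima is None or len(oa_maxima) == 0:
        return None
    pos = oa_maxima[["x_um", "y_um", "z_um"]].to_numpy()
    if len(pos) > 1:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cluster_um, output_type="ndarray")
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(pos), len(pos)),
        )
        n_comp, labels = connected_components(adj, directed=False)
        largest = np.bincount(labels).argmax()
        pos = pos[labels == largest]
    return pos.mean(axis=0)


def assign_polarity(stack: ImageStack, pole_a: np.ndarray, pole_b: np.ndarray,
                    oa_centroid: np.ndarray | None,
                    cfg: PipelineConfig | None = None):
    """Decide which pole is anterior.

    The BB-channel intensity is integrated in a sphere (default radius 5 µm)
    around each pole; the brighter pole is anterior.  When the OA centroid
    disagrees (it must fall in the anterior half), the OA cue wins and the
    cell is flagged.  Near-equal integrals with no OA raise
    :class:`PolarityError`.

    Returns ``(pole_anterior, pole_posterior, flag)``.
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    img = stack.channel(cfg.bb_channel)
    nz, ny, nx = img.shape

    def integrate(pole):
        r = cfg.pole_sphere_um
        x, y, z = pole
        z0, z1 = max(0, int((z - r) / dz)), min(nz, int((z + r) / dz) + 1)
        y0, y1 = max(0, int((y - r) / dy)), min(ny, int((y + r) / dy) + 1)
        x0, x1 = max(0, int((x - r) / dx)), min(nx, int((x + r) / dx) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            return 0.0
        zz = np.arange(z0, z1) * dz - z
        yy = np.arange(y0, y1) * dy - y
        xx = np.arange(x0, x1) * dx - x
        m = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
             + xx[None, None, :] ** 2) <= r * r
        return float(img[z0:z1, y0:y1, x0:x1][m].sum())

    int_a, int_b = integrate(pole_a), integrate(pole_b)
    brighter, dimmer = (pole_a, pole_b) if int_a >= int_b else (pole_b, pole_a)

    flag = "ok"
    if oa_centroid is not None:
        mid = 0.5 * (pole_a + pole_b)
        axis = brighter - dimmer
        oa_anterior = float((oa_centroid - mid) @ axis) > 0
        if not oa_anterior:
            logger.info("polarity: OA cue overrides pole-intensity cue")
            brighter, dimmer = dimmer, brighter
            flag = "oa_override"
    else:
        total = int_a + int_b
        if total > 0 and abs(int_a - int_b) / max(int_a, int_b) < 0.05:
            raise PolarityError("polarity ambiguous: pole intensities within 5%, no OA")
        flag = "no_oa"
    return brighter, dimmer, flag


# ---------------------------------------------------------------------------
# row linking
# ---------------------------------------------------------------------------

def _plane_distances(points: np.ndarray, ref: np.ndarray,
                     pole_a: np.ndarray, pole_p: np.ndarray) -> np.ndarray:
    """Distance of each point from the plane through ref and the two poles.

    Degenerate planes (ref collinear with the pole axis) return +inf so the
    caller skips those scores.
    """
    n = np.cross(pole_a - ref, pole_p - ref)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        return np.full(len(points), np.inf)
    return np.abs((points - ref) @ (n / nn))


def connect_rows(positions: np.ndarray, pole_anterior: np.ndarray,
                 pole_posterior: np.ndarray,
                 cfg: PipelineConfig | None = None) -> RowGraph:
    """Link every BB to its most plausible anterior partner.

    Candidates are BBs with strictly greater projection on the
    posterior→anterior axis.  The score of candidate ``c`` for BB ``b`` is
    ``‖b−c‖ + w·dist(c, plane(b, poles))``; reverse scores swap the roles
    (plane through the candidate).  Reciprocal agreement links are accepted
    simultaneously round by round, consuming one out-slot (of the posterior
    BB) and one in-slot (of the anterior partner).  Remaining BBs fall back
    to the closest anterior candidate with a free in-slot if closer than the
    fallback radius; otherwise they stay unlinked.
    """
    cfg = cfg or PipelineConfig()
    p = np.asarray(positions, dtype=float)
    n = len(p)
    axis = pole_anterior - pole_posterior
    axis = axis / np.linalg.norm(axis)
    proj = p @ axis

    dist = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
    plane_d = np.empty((n, n))
    for i in range(n):
        plane_d[i] = _plane_distances(p, p[i], pole_anterior, pole_posterior)

    anterior_of = np.full(n, -1, dtype=int)   # out-edge: my anterior partner
    posterior_of = np.full(n, -1, dtype=int)  # in-edge: who links to me
    strictly_anterior = proj[None, :] > proj[:, None]  # [b, c]

    with np.errstate(invalid="ignore"):
        fwd_score = dist + cfg.plane_weight * plane_d          # plane through b
        rev_score = dist + cfg.plane_weight * plane_d.T        # plane through c
    fwd_score[~strictly_anterior] = np.inf
    rev_score[~strictly_anterior] = np.inf
    np.fill_diagonal(fwd_score, np.inf)
    np.fill_diagonal(rev_score, np.inf)

    while True:
        open_out = anterior_of < 0
        open_in = posterior_of < 0
        f = fwd_score.copy()
        f[~open_out, :] = np.inf
        f[:, ~open_in] = np.inf
        r = rev_score.copy()
        r[~open_out, :] = np.inf
        r[:, ~open_in] = np.inf
        if not np.isfinite(f).any():
            break
        fwd_choice = np.where(np.isfinite(f).any(axis=1), f.argmin(axis=1), -1)
        rev_choice = np.where(np.isfinite(r).any(axis=0), r.argmin(axis=0), -1)
        new = [
            (b, c) for b, c in enumerate(fwd_choice)
            if c >= 0 and rev_choice[c] == b
        ]
        if not new:
            break
        for b, c in new:
            anterior_of[b] = c
            posterior_of[c] = b

    # fallback pass: closest free anterior candidate under the radius
    provenance = np.where(anterior_of >= 0, "reciprocal", "unlinked").astype(object)
    order = np.argsort(proj)  # posterior first, deterministic
    for b in order:
        if anterior_of[b] >= 0:
            continue
        cand = np.flatnonzero(strictly_anterior[b] & (posterior_of < 0))
        cand = cand[cand != b]
        if len(cand) == 0:
            continue
        c = cand[dist[b, cand].argmin()]
        if dist[b, c] < cfg.fallback_link_um:
            anterior_of[b] = c
            posterior_of[c] = b
            provenance[b] = "fallback"

    length = np.where(anterior_of >= 0, dist[np.arange(n), anterior_of], np.nan)
    angdev = np.full(n, np.nan)
    for b in np.flatnonzero(anterior_of >= 0):
        c = anterior_of[b]
        pd_bc = plane_d[b, c]
        if np.isfinite(pd_bc) and length[b] > 0:
            angdev[b] = np.degrees(np.arcsin(min(1.0, pd_bc / length[b])))
    links = pd.DataFrame({
        "bb_id": np.arange(n),
        "anterior_id": anterior_of,
        "length_um": length,
        "angdev_deg": angdev,
        "provenance": provenance,
    })
    logger.info(
        "connect_rows: %d reciprocal, %d fallback, %d unlinked",
        int((links["provenance"] == "reciprocal").sum()),
        int((links["provenance"] == "fallback").sum()),
        int((links["provenance"] == "unlinked").sum()),
    )
    return RowGraph(links=links)


def connect_rows_bruteforce(positions, pole_anterior, pole_posterior,
                            cfg: PipelineConfig | None = None) -> RowGraph:
    """Reference implementation of the reciprocal matching (small inputs).

    Re-evaluates every forward/reverse score from scratch each round and
    accepts all agreeing pairs simultaneously; used as an oracle for
    :func:`connect_rows`.
    """
    cfg = cfg or PipelineConfig()
    p = np.asarray(positions, dtype=float)
    n = len(p)
    axis = pole_anterior - pole_posterior
    axis = axis / np.linalg.norm(axis)
    proj = p @ axis
    anterior_of = np.full(n, -1, dtype=int)
    posterior_of = np.full(n, -1, dtype=int)

    while True:
        fwd, rev = {}, {}
        for b in range(n):
            if anterior_of[b] >= 0:
                continue
            best, best_s = -1, np.inf
            for c in range(n):
                if c == b or posterior_of[c] >= 0 or proj[c] <= proj[b]:
                    continue
                s = np.linalg.norm(p[b] - p[c]) + cfg.plane_weight * _plane_distances(
                    p[[c]], p[b], pole_anterior, pole_posterior)[0]
                if s < best_s:
                    best, best_s = c, s
            fwd[b] = best
        for c in range(n):
            if posterior_of[c] >= 0:
                continue
            best, best_s = -1, np.inf
            for b in range(n):
                if b == c or anterior_of[b] >= 0 or proj[c] <= proj[b]:
                    continue
                s = np.linalg.norm(p[b] - p[c]) + cfg.plane_weight * _plane_distances(
                    p[[b]], p[c], pole_anterior, pole_posterior)[0]
                if s < best_s:
                    best, best_s = b, s
            rev[c] = best
        new = [(b, c) for b, c in fwd.items() if c >= 0 and rev.get(c) == b]
        if not new:
            break
        for b, c in new:
            anterior_of[b] = c
            posterior_of[c] = b

    for b in np.argsort(proj):
        if anterior_of[b] >= 0:
            continue
        best, best_d = -1, np.inf
        for c in range(n):
            if c == b or posterior_of[c] >= 0 or proj[c] <= proj[b]:
                continue
            d = np.linalg.norm(p[b] - p[c])
            if d < best_d:
                best, best_d = c, d
        if best >= 0 and best_d < cfg.fallback_link_um:
            anterior_of[b] = best
            posterior_of[best] = b

    length = [np.linalg.norm(p[c] - p[b]) if c >= 0 else np.nan
              for b, c in enumerate(anterior_of)]
    links = pd.DataFrame({
        "bb_id": np.arange(n),
        "anterior_id": anterior_of,
        "length_um": length,
        "angdev_deg": np.nan,
        "provenance": ["reciprocal" if c >= 0 else "unlinked" for c in anterior_of],
    })
    return RowGraph(links=links)


# ---------------------------------------------------------------------------
# cell model assembly and canonical frame
# ---------------------------------------------------------------------------

def hull_geometry(positions: np.ndarray) -> tuple[float, float]:
    """Convex-hull surface area (µm²) and volume (µm³) of the BB cloud."""
    hull = ConvexHull(np.asarray(positions, dtype=float))
    return float(hull.area), float(hull.volume)


def build_cell_model(bbs: pd.DataFrame, oa_maxima: pd.DataFrame,
                     stack: ImageStack,
                     cfg: PipelineConfig | None = None) -> CellModel:
    """Assemble a :class:`CellModel` from detection output."""
    cfg = cfg or PipelineConfig()
    pos = bbs[["x_um", "y_um", "z_um"]].to_numpy()
    pole_a, pole_b = find_poles(pos)
    oa_centroid = locate_oral_apparatus(oa_maxima)
    pole_ant, pole_post, flag = assign_polarity(stack, pole_a, pole_b, oa_centroid, cfg)
    area, volume = hull_geometry(pos)
    if oa_centroid is None:
        flag = "no_oa"
        logger.warning("no OA maxima: rotational domains will be unavailable")
    return CellModel(
        bbs=bbs.reset_index(drop=True), pole_anterior=pole_ant,
        pole_posterior=pole_post, oa_centroid=oa_centroid,
        hull_surface_area=area, hull_volume=volume, polarity_flag=flag,
    )


def rotate_to_axis(cell: CellModel) -> CellModel:
    """Rigidly move the cell into its canonical frame.

    The pole midpoint goes to the origin, the posterior→anterior axis to +x,
    and the frame is spun about x so the OA centroid sits at azimuth 0°
    (+y).  Pairwise distances are preserved to machine precision.
    """
    mid = 0.5 * (cell.pole_anterior + cell.pole_posterior)
    ex = cell.axis
    # temporary perpendicular pair
    seed = np.array([0.0, 1.0, 0.0])
    if abs(ex @ seed) > 0.9:
        seed = np.array([0.0, 0.0, 1.0])
    ey = seed - (seed @ ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])  # world → cell frame

    if cell.oa_centroid is not None:
        oa = R @ (cell.oa_centroid - mid)
        ang = np.arctan2(oa[2], oa[1])  # current azimuth about +x
        ca, sa = np.cos(-ang), np.sin(-ang)
        spin = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        R = spin @ R

    def transform(points):
        return (np.atleast_2d(points) - mid) @ R.T

    bbs = cell.bbs.copy()
    newpos = transform(cell.positions)
    bbs[["x_um", "y_um", "z_um"]] = newpos
    return CellModel(
        bbs=bbs,
        pole_anterior=transform(cell.pole_anterior)[0],
        pole_posterior=transform(cell.pole_posterior)[0],
        oa_centroid=None if cell.oa_centroid is None else transform(cell.oa_centroid)[0],
        hull_surface_area=cell.hull_surface_area,
        hull_volume=cell.hull_volume,
        polarity_flag=cell.polarity_flag,
    )
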