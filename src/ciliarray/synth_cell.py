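"""Ground-truthed synthetic *Tetrahymena*-like cells.

The generator emulates the stereotypical geometry of a *Tetrahymena*
multi-ciliary array: a prolate-ellipsoid cell surface whose long axis is the
anteroposterior axis, 18–21 longitudinal ciliary rows of diffraction-limited
basal-body (BB) spots laid out as ellipsoid meridians, anterior-tight /
posterior-loose within-row spacing, and a dense anterior-ventral oral
apparatus (OA) rendered as tightly packed spots on a homogeneous bright
plateau.  Rendering adds a Gaussian point-spread function, exponential
depth-dependent intensity attenuation along the optical (z) axis, Poisson
shot noise and Gaussian read noise.

Perturbations model mutant phenotypes: deletion runs that open spacing gaps
wider than 3 µm, lateral row disorientation jitter, and dim "daughter" BBs
whose second-marker intensity falls below half of their posterior
neighbour's.

All randomness flows from one seeded :class:`numpy.random.Generator`; the
same spec and seed reproduce bit-identical ground truth and image stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .io_config import ImageStack


def default_spacing_profile(t):
    """Within-row BB spacing (µm) as a function of normalized axial position.

    ``t`` runs 0 at the anterior pole to 1 at the posterior pole.  Anterior
    BBs sit tight (~1.2 µm) and spacing loosens toward the posterior
    (~2.1 µm), reproducing the anterior-to-posterior spacing gradient of
    wild-type cells.
    """
    return 1.2 + 0.9 * np.asarray(t, dtype=float)


@dataclass
class CellSpec:
    """Parameters of one synthetic cell.

    ``semi_axes`` are the ellipsoid semi-axes (x, y, z) in µm with x the
    anteroposterior (long) axis; ``voxel_size`` and ``psf_sigma`` follow the
    package conventions (``voxel_size`` in (dz, dy, dx) axis order,
    ``psf_sigma`` as (x, y, z) µm).  ``noise_model`` is
    ``(gaussian_read_sd, poisson_gain)`` in camera units; a zero entry
    disables that noise source.  ``attenuation_coeff`` is the fractional
    intensity loss per µm of depth; the default makes the far cell surface
    ~35% as bright as the near surface for the default cell diameter.
    """

    semi_axes: tuple[float, float, float] = (20.0, 10.5, 10.5)
    n_rows: int = 20
    bb_spacing_profile: Callable = default_spacing_profile
    # OA azimuth -90° = ventral surface toward the coverslip, the usual
    # mounting orientation; axial t = 0.15 puts it anterior-ventral
    oa_center: tuple[float, float] = (-90.0, 0.15)
    oa_bb_count: int = 150
    oa_spacing_um: float = 0.3
    noise_model: tuple[float, float] = (10.0, 2.0)
    attenuation_coeff: float = 0.043
    psf_sigma: tuple[float, float, float] = (0.10, 0.10, 0.35)
    voxel_size: tuple[float, float, float] = (0.3, 0.125, 0.125)
    seed: int = 0
    # secondary knobs
    t_margin: float = 0.02          # anterior row margin (normalized axial t)
    t_margin_posterior: float = 0.01  # rows run closer to the posterior tip
    margin_um: float = 6.0          # empty border around the cell in the stack
    bb_amplitude: float = 2000.0    # peak ADU of an unattenuated unit-intensity BB
    background: float = 100.0       # uniform camera offset
    cell_background: float = 150.0  # diffuse cytoplasmic staining (ADU, attenuated)
    oa_plateau_amplitude: float = 800.0
    channel_names: tuple[str, ...] = ("centrin", "poc1")
    channel_cv: tuple[float, ...] = (0.05, 0.08)

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if not (12 <= self.n_rows <= 30):
            raise ValueError(f"n_rows must be in [12, 30], got {self.n_rows}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        t_check = np.linspace(0, 1, 101)
        if np.any(np.asarray(self.bb_spacing_profile(t_check)) <= 0):
            raise ValueError("spacing profile must be > 0 everywhere")
        if not (0 < self.t_margin < 0.5) or not (0 < self.t_margin_posterior < 0.5):
            raise ValueError("row margins must be in (0, 0.5)")

    @property
    def center(self) -> np.ndarray:
        """Cell centre in the stack frame (x, y, z), µm."""
        a, b, c = self.semi_axes
        m = self.margin_um
        return np.array([a + m, b + m, c + m])


@dataclass
class GroundTruth:
    """True BB layout of one synthetic cell (positions in stack-frame µm)."""

    bb_positions: np.ndarray            # (N, 3) cortical BBs, (x, y, z)
    row_id: np.ndarray                  # (N,) int
    order_in_row: np.ndarray            # (N,) int, 0 = most anterior
    pole_anterior: np.ndarray           # (3,)
    pole_posterior: np.ndarray          # (3,)
    oa_positions: np.ndarray            # (M, 3)
    daughter_flags: np.ndarray          # (N,) bool
    intensities: np.ndarray             # (N, n_channels) true unit intensities
    oa_intensities: np.ndarray          # (M, n_channels)
    channel_names: tuple[str, ...]
    semi_axes: tuple[float, float, float]
    center: np.ndarray

    @property
    def n_bbs(self) -> int:
        return len(self.bb_positions)

    @property
    def oa_centroid(self) -> np.ndarray:
        return self.oa_positions.mean(axis=0)

    def anterior_partner_ids(self) -> np.ndarray:
        """Index of each BB's true within-row anterior partner (-1 = none).

        The anterior partner of a BB with within-row order ``j`` is the
        surviving BB of the same row with the largest order smaller than
        ``j``.
        """
        out = np.full(self.n_bbs, -1, dtype=int)
        for row in np.unique(self.row_id):
            idx = np.flatnonzero(self.row_id == row)
            idx = idx[np.argsort(self.order_in_row[idx])]
            out[idx[1:]] = idx[:-1]
        return out

    def subset(self, keep: np.ndarray) -> "GroundTruth":
        keep = np.asarray(keep)
        return replace(
            self,
            bb_positions=self.bb_positions[keep],
            row_id=self.row_id[keep],
            order_in_row=self.order_in_row[keep],
            daughter_flags=self.daughter_flags[keep],
            intensities=self.intensities[keep],
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _meridian_point(theta, phi, semi_axes):
    """Ellipsoid surface point(s) at polar angle theta (0 = anterior pole)."""
    a, b, c = semi_axes
    theta = np.asarray(theta, dtype=float)
    return np.stack(
        [a * np.cos(theta),
         b * np.sin(theta) * np.cos(phi),
         c * np.sin(theta) * np.sin(phi)],
        axis=-1,
    )


def _meridian_speed(theta, phi, semi_axes):
    """|d position / d theta| along the meridian at azimuth phi."""
    a, b, c = semi_axes
    r2 = (b * np.cos(phi)) ** 2 + (c * np.sin(phi)) ** 2
    return np.sqrt(a**2 * np.sin(theta) ** 2 + r2 * np.cos(theta) ** 2)


def project_to_surface(points_centered, semi_axes):
    """Radially rescale centred points onto the ellipsoid surface."""
    p = np.atleast_2d(points_centered)
    s = np.asarray(semi_axes, dtype=float)
    r = np.sqrt(((p / s) ** 2).sum(axis=1))
    return p / r[:, None]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_basal_bodies(spec: CellSpec) -> GroundTruth:
    """Lay out cortical rows and the oral apparatus on the ellipsoid surface.

    Rows are meridians at equal azimuthal offsets; within-row positions are
    obtained by stepping the meridian arc length by ``bb_spacing_profile``
    evaluated at the local normalized axial position (midpoint rule, one
    refinement, so constant profiles step the arc to well under 1%).  A spec
    whose profile leaves any row with fewer than 3 BBs is rejected.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.semi_axes[0]
    t0, t1 = spec.t_margin, 1.0 - spec.t_margin_posterior
    theta_min = float(np.arccos(1.0 - 2.0 * t0))
    theta_max = float(np.arccos(1.0 - 2.0 * t1))

    positions, rows, orders = [], [], []
    for k in range(spec.n_rows):
        phi = 2.0 * np.pi * k / spec.n_rows
        theta = theta_min
        thetas = [theta]
        while True:
            t = (1.0 - np.cos(theta)) / 2.0
            step = float(spec.bb_spacing_profile(t))
            # midpoint refinement of d(theta) = ds / g(theta)
            dth = step / _meridian_speed(theta, phi, spec.semi_axes)
            dth = step / _meridian_speed(theta + dth / 2.0, phi, spec.semi_axes)
            theta = theta + dth
            if theta > theta_max:
                break
            thetas.append(theta)
        if len(thetas) < 3:
            raise ValueError(
                f"spacing profile too coarse: row {k} holds {len(thetas)} BBs (< 3)"
            )
        pts = _meridian_point(np.array(thetas), phi, spec.semi_axes)
        positions.append(pts)
        rows.append(np.full(len(pts), k))
        orders.append(np.arange(len(pts)))

    bb = np.concatenate(positions) + spec.center
    row_id = np.concatenate(rows).astype(int)
    order = np.concatenate(orders).astype(int)
    n = len(bb)

    # oral apparatus: sunflower-packed disc in the local tangent plane at
    # oa_center, projected back onto the surface; spot spacing near the
    # diffraction limit so the cluster images as a homogeneous bright patch.
    az_deg, t_oa = spec.oa_center
    theta_oa = float(np.arccos(1.0 - 2.0 * t_oa))
    phi_oa = np.deg2rad(az_deg)
    c0 = _meridian_point(theta_oa, phi_oa, spec.semi_axes)
    normal = 2.0 * c0 / np.asarray(spec.semi_axes, dtype=float) ** 2
    normal = normal / np.linalg.norm(normal)
    u = np.array([1.0, 0.0, 0.0]) - normal[0] * normal
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)
    m = spec.oa_bb_count
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(m)
    rad = spec.oa_spacing_um * np.sqrt((i + 0.5) / np.pi)
    ang = i * golden
    disc = (rad * np.cos(ang))[:, None] * u + (rad * np.sin(ang))[:, None] * v
    oa = project_to_surface(c0 + disc, spec.semi_axes) + spec.center

    # the oral apparatus displaces cortical rows: remove row BBs under its
    # footprint (plus half a spot spacing of clearance)
    oa_radius = float(rad.max()) if m else 0.0
    if m:
        clear = np.linalg.norm(bb - (c0 + spec.center), axis=1) > oa_radius + 0.5
        bb, row_id, order = bb[clear], row_id[clear], order[clear]
        n = len(bb)

    n_ch = len(spec.channel_names)
    intens = np.empty((n, n_ch))
    oa_intens = np.empty((m, n_ch))
    for ch, cv in enumerate(spec.channel_cv):
        intens[:, ch] = np.clip(rng.normal(1.0, cv, size=n), 0.2, None)
        oa_intens[:, ch] = np.clip(rng.normal(1.0, cv, size=m), 0.2, None)

    apex = np.array([a, 0.0, 0.0])
    return GroundTruth(
        bb_positions=bb,
        row_id=row_id,
        order_in_row=order,
        pole_anterior=spec.center + apex,
        pole_posterior=spec.center - apex,
        oa_positions=oa,
        daughter_flags=np.zeros(n, dtype=bool),
        intensities=intens,
        oa_intensities=oa_intens,
        channel_names=tuple(spec.channel_names),
        semi_axes=tuple(spec.semi_axes),
        center=spec.center.copy(),
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def inject_perturbations(
    gt: GroundTruth,
    gap_rate: float = 0.0,
    disorient_sd: float = 0.0,
    daughter_rate: float = 0.0,
    seed: int = 0,
    gap_min_um: float = 3.0,
) -> GroundTruth:
    """Apply mutant-style perturbations to a ground-truth layout.

    ``gap_rate``
        Fraction of cortical BBs deleted as contiguous runs; each run is
        extended until the surviving flanking pair is more than
        ``gap_min_um`` apart (poc1Δ-style spacing gaps).
    ``disorient_sd``
        Angular sd (degrees) of lateral jitter about the row plane (the
        plane through the BB and the two poles), scaled by the local
        within-row spacing (disA-1-style disorientation).
    ``daughter_rate``
        Per-link probability that the anterior member of a within-row pair
        is turned into a dim daughter: its second-marker intensity is set
        below half of its posterior neighbour's.

    All rates of zero return an identical copy.  Randomness comes solely
    from ``seed``.
    """
    for name, r in (("gap_rate", gap_rate), ("daughter_rate", daughter_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    gt = replace(
        gt,
        bb_positions=gt.bb_positions.copy(),
        daughter_flags=gt.daughter_flags.copy(),
        intensities=gt.intensities.copy(),
    )

    # ---- gaps: delete runs so flanking survivors are > gap_min_um apart
    if gap_rate > 0:
        target = int(round(gap_rate * gt.n_bbs))
        alive = np.ones(gt.n_bbs, dtype=bool)
        deleted = 0
        rows = list(np.unique(gt.row_id))
        attempts = 0
        while deleted < target and attempts < 20 * len(rows):
            attempts += 1
            row = rows[rng.integers(len(rows))]
            idx = np.flatnonzero((gt.row_id == row) & alive)
            idx = idx[np.argsort(gt.order_in_row[idx])]
            if len(idx) < 5:
                continue
            start = int(rng.integers(1, len(idx) - 2))
            stop = start + 1
            while stop < len(idx) - 1:
                gap = np.linalg.norm(
                    gt.bb_positions[idx[stop]] - gt.bb_positions[idx[start - 1]]
                )
                if gap > gap_min_um:
                    break
                stop += 1
            else:
                continue
            alive[idx[start:stop]] = False
            deleted += stop - start
        gt = gt.subset(alive)

    # ---- disorientation: lateral (off-row-plane) jitter
    if disorient_sd > 0:
        sd = np.deg2rad(disorient_sd)
        axis = gt.pole_anterior - gt.pole_posterior
        axis = axis / np.linalg.norm(axis)
        anterior = gt.anterior_partner_ids()
        # local spacing: distance to the anterior partner, or to the posterior
        # partner for row heads
        spacing = np.full(gt.n_bbs, np.nan)
        has_ant = anterior >= 0
        spacing[has_ant] = np.linalg.norm(
            gt.bb_positions[anterior[has_ant]] - gt.bb_positions[has_ant], axis=1
        )
        for i in np.flatnonzero(~has_ant):
            same = np.flatnonzero(gt.row_id == gt.row_id[i])
            others = same[same != i]
            if len(others):
                spacing[i] = np.linalg.norm(
                    gt.bb_positions[others] - gt.bb_positions[i], axis=1
                ).min()
            else:
                spacing[i] = 1.0
        # off-plane direction: normal of the plane through the BB and both poles
        rel = gt.bb_positions - gt.pole_posterior
        normal = np.cross(axis, rel)
        norms = np.linalg.norm(normal, axis=1)
        ok = norms > 1e-9
        normal[ok] /= norms[ok, None]
        eps = rng.normal(0.0, sd, size=gt.n_bbs)
        shift = spacing * np.tan(np.clip(eps, -np.pi / 3, np.pi / 3))
        gt.bb_positions[ok] += shift[ok, None] * normal[ok]

    # ---- daughters: dim the anterior member of selected within-row pairs
    if daughter_rate > 0:
        try:
            ch2 = gt.channel_names.index("poc1")
        except ValueError:
            ch2 = min(1, gt.intensities.shape[1] - 1)
        anterior = gt.anterior_partner_ids()
        # walk each row posterior→anterior so ratios are against final values
        for row in np.unique(gt.row_id):
            idx = np.flatnonzero(gt.row_id == row)
            idx = idx[np.argsort(gt.order_in_row[idx])][::-1]  # posterior first
            for j in range(len(idx) - 1):
                post, ant = idx[j], idx[j + 1]
                if rng.random() < daughter_rate:
                    frac = rng.uniform(0.25, 0.45)
                    gt.intensities[ant, ch2] = frac * gt.intensities[post, ch2]
                    gt.daughter_flags[ant] = True
    return gt


def add_close_pairs(gt: GroundTruth, n_pairs: int, seed: int = 0) -> GroundTruth:
    """Insert BBs at within-row link midpoints, creating closely spaced pairs.

    Models the compensatory increase in < 1 µm spacings that balances large
    gaps.  New BBs take the mean intensity of the flanking pair and rows are
    re-ordered by axial position afterwards.
    """
    rng = np.random.default_rng(seed)
    anterior = gt.anterior_partner_ids()
    linked = np.flatnonzero(anterior >= 0)
    chosen = rng.choice(linked, size=min(n_pairs, len(linked)), replace=False)
    mids = 0.5 * (gt.bb_positions[chosen] + gt.bb_positions[anterior[chosen]])
    mids = project_to_surface(mids - gt.center, gt.semi_axes) + gt.center
    new_int = 0.5 * (gt.intensities[chosen] + gt.intensities[anterior[chosen]])

    pos = np.vstack([gt.bb_positions, mids])
    row = np.concatenate([gt.row_id, gt.row_id[chosen]])
    inten = np.vstack([gt.intensities, new_int])
    daught = np.concatenate([gt.daughter_flags, np.zeros(len(mids), dtype=bool)])
    # re-derive within-row order from axial position (x decreases to posterior)
    order = np.zeros(len(pos), dtype=int)
    for r in np.unique(row):
        idx = np.flatnonzero(row == r)
        order[idx[np.argsort(-pos[idx, 0])]] = np.arange(len(idx))
    return replace(
        gt, bb_positions=pos, row_id=row, order_in_row=order,
        intensities=inten, daughter_flags=daught,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _splat_gaussians(canvas, centers_um, amplitudes, sigma_um, voxel_size):
    """Add 3D Gaussians (peak = amplitude) onto a (z, y, x) canvas in place."""
    dz, dy, dx = voxel_size
    sx, sy, sz = sigma_um
    nz, ny, nx = canvas.shape
    half = (
        max(1, int(np.ceil(4 * sz / dz))),
        max(1, int(np.ceil(4 * sy / dy))),
        max(1, int(np.ceil(4 * sx / dx))),
    )
    for (x, y, z), amp in zip(np.atleast_2d(centers_um), np.atleast_1d(amplitudes)):
        iz, iy, ix = int(round(z / dz)), int(round(y / dy)), int(round(x / dx))
        z0, z1 = max(0, iz - half[0]), min(nz, iz + half[0] + 1)
        y0, y1 = max(0, iy - half[1]), min(ny, iy + half[1] + 1)
        x0, x1 = max(0, ix - half[2]), min(nx, ix + half[2] + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        gz = np.exp(-0.5 * ((np.arange(z0, z1) * dz - z) / sz) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0, y1) * dy - y) / sy) ** 2)
        gx = np.exp(-0.5 * ((np.arange(x0, x1) * dx - x) / sx) ** 2)
        canvas[z0:z1, y0:y1, x0:x1] += amp * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def render_stack(gt: GroundTruth, spec: CellSpec) -> ImageStack:
    """Render the ground truth into a calibrated multi-channel stack.

    Every BB becomes a 3D Gaussian of ``psf_sigma`` whose amplitude is the
    per-channel true intensity scaled by ``bb_amplitude`` and by the depth
    attenuation ``(1 - attenuation_coeff) ** z``.  The OA cluster sits on a
    homogeneous super-Gaussian plateau.  Poisson shot noise (via the camera
    gain) and Gaussian read noise are added last; the uniform camera offset
    is not attenuated.
    """
    dz, dy, dx = spec.voxel_size
    a, b, c = spec.semi_axes
    m = spec.margin_um
    nx = int(round(2 * (a + m) / dx)) + 1
    ny = int(round(2 * (b + m) / dy)) + 1
    nz = int(round(2 * (c + m) / dz)) + 1
    read_sd, gain = spec.noise_model
    rng = np.random.default_rng((spec.seed, 0xC111A))

    all_pos = np.vstack([gt.bb_positions, gt.oa_positions])
    atten = (1.0 - spec.attenuation_coeff) ** all_pos[:, 2]

    # diffuse cytoplasmic staining fills the cell body (soft 1 µm edge) and
    # attenuates with depth like every other fluorescence term
    body = None
    if spec.cell_background > 0:
        zz = (np.arange(nz)[:, None, None] * dz - spec.center[2]) / spec.semi_axes[2]
        yy = (np.arange(ny)[None, :, None] * dy - spec.center[1]) / spec.semi_axes[1]
        xx = (np.arange(nx)[None, None, :] * dx - spec.center[0]) / spec.semi_axes[0]
        inside = (xx**2 + yy**2 + zz**2 <= 1.0).astype(np.float32)
        from scipy import ndimage as _ndi
        inside = _ndi.gaussian_filter(inside, (1.0 / dz, 1.0 / dy, 1.0 / dx))
        body = spec.cell_background * inside
        body *= (1.0 - spec.attenuation_coeff) ** (
            np.arange(nz, dtype=np.float32)[:, None, None] * dz
        )

    channels = []
    for ch in range(len(gt.channel_names)):
        canvas = np.zeros((nz, ny, nx), dtype=np.float64)
        amp = np.concatenate([gt.intensities[:, ch], gt.oa_intensities[:, ch]])
        _splat_gaussians(
            canvas, all_pos, spec.bb_amplitude * amp * atten,
            spec.psf_sigma, spec.voxel_size,
        )
        if len(gt.oa_positions) and spec.oa_plateau_amplitude > 0:
            oa_c = gt.oa_centroid
            rad = np.linalg.norm(gt.oa_positions - oa_c, axis=1)
            r_plateau = max(1.0, float(rad.max()) + 0.5)
            zz = np.arange(nz)[:, None, None] * dz - oa_c[2]
            yy = np.arange(ny)[None, :, None] * dy - oa_c[1]
            xx = np.arange(nx)[None, None, :] * dx - oa_c[0]
            r4 = ((xx / r_plateau) ** 2 + (yy / r_plateau) ** 2
                  + (zz / (0.6 * r_plateau)) ** 2) ** 2
            plateau = spec.oa_plateau_amplitude * np.exp(-r4)
            plateau *= (1.0 - spec.attenuation_coeff) ** (
                np.arange(nz)[:, None, None] * dz
            )
            canvas += plateau
        if body is not None:
            canvas += body
        canvas += spec.background
        if gain > 0:
            canvas = rng.poisson(np.maximum(canvas, 0.0) / gain) * gain
        if read_sd > 0:
            canvas = canvas + rng.normal(0.0, read_sd, size=canvas.shape)
        channels.append(np.maximum(canvas, 0.0).astype(np.float32))

    return ImageStack(
        voxels=np.stack(channels),
        voxel_size=spec.voxel_size,
        channel_names=list(gt.channel_names),
    )


# ---------------------------------------------------------------------------
# presets and files
# ---------------------------------------------------------------------------

def tetrahymena_preset(seed: int = 0, **overrides) -> CellSpec:
    """The default wild-type-like cell: ~40 µm long, 20 rows, ~580 cortical
    BBs plus a 150-BB oral apparatus, far surface ~35% as bright as the near
    surface."""
    return CellSpec(seed=seed, **overrides)


def make_cell(spec: CellSpec, gap_rate=0.0, disorient_sd=0.0, daughter_rate=0.0):
    """Convenience: place, perturb and render one cell.

    Returns ``(ground_truth, image_stack)``.  Perturbations use a seed
    derived from ``spec.seed`` so one integer reproduces the whole cell.
    """
    gt = place_basal_bodies(spec)
    if gap_rate or disorient_sd or daughter_rate:
        gt = inject_perturbations(
            gt, gap_rate=gap_rate, disorient_sd=disorient_sd,
            daughter_rate=daughter_rate, seed=spec.seed + 1,
        )
    return gt, render_stack(gt, spec)


def write_ground_truth(gt: GroundTruth, path) -> pd.DataFrame:
    """Write the ground-truth table (cortical BBs then OA BBs) as CSV."""
    n, m = gt.n_bbs, len(gt.oa_positions)
    pos = np.vstack([gt.bb_positions, gt.oa_positions])
    df = pd.DataFrame({
        "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
        "row_id": np.concatenate([gt.row_id, np.full(m, -1)]),
        "order_in_row": np.concatenate([gt.order_in_row, np.full(m, -1)]),
        "is_oa": np.concatenate([np.zeros(n, bool), np.ones(m, bool)]),
        "is_daughter": np.concatenate([gt.daughter_flags, np.zeros(m, bool)]),
    })
    inten = np.vstack([gt.intensities, gt.oa_intensities])
    for ch, name in enumerate(gt.channel_names):
        df[f"intensity_{name}"] = inten[:, ch]
    df.to_csv(path, index=False)
    return df
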