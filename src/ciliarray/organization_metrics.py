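"""Spacing, orientation, spatial domains, densities and daughter-BB calls.

All metrics operate on a reconstructed cell: the cortical BB table, the
anterior-partner row graph and the cell model (poles, OA, hull).  Spacing is
the 3D Euclidean link length, so cellular curvature is preserved.  The cell
is divided into 16 spatial domains: four longitudinal quadrants (IV anterior
… I posterior, from the normalized Euclidean distance to the anterior pole)
crossed with four rotational bins (azimuth about the anteroposterior axis
relative to the oral apparatus, folded to [0°, 180°] by mirror symmetry and
binned at 45°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import PipelineConfig, logger
from .polarity_rows import CellModel, RowGraph, _plane_distances, hull_geometry

QUADRANT_LABELS = ["IV", "III", "II", "I"]          # anterior → posterior
ROTATION_LABELS = [0, 45, 90, 135]


def angular_deviation(bb: np.ndarray, partner: np.ndarray,
                      pole_anterior: np.ndarray, pole_posterior: np.ndarray) -> float:
    """Angle (degrees) between the link to the anterior partner and the
    plane through the BB and the two cell poles.

    0° for a perfectly aligned row; 90° when the partner is displaced
    perpendicular to the plane by the full link length.  Returns NaN when the
    BB is collinear with the pole axis (plane undefined).
    """
    bb = np.asarray(bb, dtype=float)
    partner = np.asarray(partner, dtype=float)
    link = np.linalg.norm(partner - bb)
    if link == 0:
        return np.nan
    d = _plane_distances(partner[None], bb, np.asarray(pole_anterior, float),
                         np.asarray(pole_posterior, float))[0]
    if not np.isfinite(d):
        return np.nan
    return float(np.degrees(np.arcsin(min(1.0, d / link))))


@dataclass
class SpacingStats:
    """Per-link spacing summary for one cell."""

    lengths_um: np.ndarray
    hist_counts: np.ndarray
    hist_edges_um: np.ndarray
    mean_um: float
    sd_um: float
    gap_frequency: float      # links > gap threshold / all links
    close_fraction: float     # links < close threshold / all links
    n_links: int


def spacing_stats(row_graph: RowGraph, cfg: PipelineConfig | None = None) -> SpacingStats:
    """Spacing distribution, large-gap frequency (> 3 µm) and close-pair
    fraction (< 1 µm) over all anterior-partner links."""
    cfg = cfg or PipelineConfig()
    lengths = row_graph.linked["length_um"].to_numpy(dtype=float)
    if len(lengths) == 0:
        logger.warning("spacing_stats: no links")
        return SpacingStats(lengths, np.array([]), np.array([]),
                            np.nan, np.nan, np.nan, np.nan, 0)
    top = max(cfg.spacing_bin_um, lengths.max())
    edges = np.arange(0.0, top + cfg.spacing_bin_um, cfg.spacing_bin_um)
    counts, edges = np.histogram(lengths, bins=edges)
    return SpacingStats(
        lengths_um=lengths, hist_counts=counts, hist_edges_um=edges,
        mean_um=float(lengths.mean()), sd_um=float(lengths.std()),
        gap_frequency=float((lengths > cfg.gap_um).mean()),
        close_fraction=float((lengths < cfg.close_um).mean()),
        n_links=len(lengths),
    )


def assign_domains(cell: CellModel) -> pd.DataFrame:
    """Assign each cortical BB a (longitudinal quadrant, rotational bin).

    Longitudinal quadrants use the Euclidean distance from the anterior pole
    normalized by the pole-to-pole distance: IV [0, 0.25), III [0.25, 0.5),
    II [0.5, 0.75), I [0.75, 1].  Rotational bins need the OA: the azimuth
    about the axis relative to the OA meridian is folded to [0°, 180°] and
    binned at 45°; without an OA the rotational bin is left missing.

    Returns a copy of the BB table with ``quadrant`` and ``rot_bin`` columns.
    """
    bbs = cell.bbs.copy()
    pos = cell.positions
    D = np.linalg.norm(cell.pole_anterior - cell.pole_posterior)
    d = np.linalg.norm(pos - cell.pole_anterior, axis=1)
    frac = np.clip(d / D, 0.0, 1.0)
    q_idx = np.minimum((frac * 4).astype(int), 3)
    bbs["quadrant"] = [QUADRANT_LABELS[i] for i in q_idx]

    if cell.oa_centroid is not None:
        axis = cell.axis
        mid = 0.5 * (cell.pole_anterior + cell.pole_posterior)
        # orthonormal frame with the OA meridian at azimuth 0
        oa_lat = cell.oa_centroid - mid
        oa_lat = oa_lat - (oa_lat @ axis) * axis
        nrm = np.linalg.norm(oa_lat)
        if nrm < 1e-9:
            logger.warning("assign_domains: OA on the axis; rotational bins skipped")
            bbs["rot_bin"] = np.nan
            return bbs
        ey = oa_lat / nrm
        ez = np.cross(axis, ey)
        rel = pos - mid
        az = np.degrees(np.arctan2(rel @ ez, rel @ ey))
        folded = np.abs(az)  # mirror symmetry about the OA meridian
        folded = np.where(folded > 180.0, 360.0 - folded, folded)
        r_idx = np.minimum((folded / 45.0).astype(int), 3)
        bbs["rot_bin"] = [ROTATION_LABELS[i] for i in r_idx]
    else:
        logger.warning("assign_domains: no OA; rotational bins unavailable")
        bbs["rot_bin"] = np.nan
    return bbs


def hull_metrics(positions: np.ndarray, row_graph: RowGraph | None = None) -> dict:
    """Convex-hull surface area, volume and BB densities.

    ``area_density`` is cortical BBs per µm² of hull surface;
    ``linear_density`` (per µm within rows) is the linked-BB count divided by
    the summed link length, when a row graph is supplied.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 4 or np.linalg.matrix_rank(pos - pos.mean(axis=0)) < 3:
        raise ValueError("hull_metrics needs >= 4 non-coplanar points")
    area, volume = hull_geometry(pos)
    out = {
        "surface_area_um2": area,
        "volume_um3": volume,
        "n_bbs": len(pos),
        "area_density_per_um2": len(pos) / area,
    }
    if row_graph is not None and len(row_graph.linked):
        total = float(row_graph.linked["length_um"].sum())
        out["linear_density_per_um"] = len(row_graph.linked) / total if total > 0 else np.nan
    return out


def call_daughters(row_graph: RowGraph, bbs: pd.DataFrame,
                   channel: str = "poc1",
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Mother/daughter calls from the age-graded marker intensity ratio.

    For each link posterior ``p`` → anterior ``a``: when the marker intensity
    of ``p`` is at least ``daughter_ratio`` (2-fold) that of ``a``, ``a`` is
    called a daughter (newly assembled) and ``p`` its mother.  A
    non-positive anterior intensity makes the ratio infinite: the daughter is
    still called but flagged.  Returns the BB table with ``is_daughter``,
    ``is_mother`` and ``ratio_flagged`` columns.
    """
    cfg = cfg or PipelineConfig()
    col = f"intensity_{channel}"
    if col not in bbs.columns:
        raise KeyError(f"missing intensity column {col!r}")
    out = bbs.copy()
    out["is_daughter"] = False
    out["is_mother"] = False
    out["ratio_flagged"] = False
    inten = out[col].to_numpy(dtype=float)
    for p, a in zip(row_graph.linked["bb_id"], row_graph.linked["anterior_id"]):
        ia, ip = inten[a], inten[p]
        if ia <= 0:
            ratio, flagged = np.inf, True
        else:
            ratio, flagged = ip / ia, False
        if ratio >= cfg.daughter_ratio:
            out.loc[a, "is_daughter"] = True
            out.loc[p, "is_mother"] = True
            out.loc[a, "ratio_flagged"] = flagged
    return out


def intensity_ratio_histogram(row_graph: RowGraph, bbs: pd.DataFrame,
                              channel: str, bins: int = 50):
    """Distribution of anterior/posterior intensity ratios over all links.

    A uniformly incorporating marker (centrin-like) concentrates near 1; an
    age-graded marker (Poc1-like) spreads to low ratios at daughter BBs.
    Returns ``(ratios, hist_counts, hist_edges)``.
    """
    col = f"intensity_{channel}"
    inten = bbs[col].to_numpy(dtype=float)
    linked = row_graph.linked
    if len(linked) == 0:
        return np.array([]), np.array([]), np.array([])
    p = linked["bb_id"].to_numpy()
    a = linked["anterior_id"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = inten[a] / inten[p]
    ratios = ratios[np.isfinite(ratios)]
    counts, edges = np.histogram(ratios, bins=bins)
    return ratios, counts, edges


# ---------------------------------------------------------------------------
# 16-domain table
# ---------------------------------------------------------------------------

@dataclass
class DomainTable:
    """Per-domain statistics over the 16 (quadrant × rotation) domains."""

    table: pd.DataFrame

    def heatmap(self, metric: str, path=None):
        """Render a 4×4 heat map (rows = quadrants IV→I top to bottom,
        columns = rotational bins 0°→135°) of one metric."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = np.full((4, 4), np.nan)
        for _, r in self.table.iterrows():
            if pd.isna(r["rot_bin"]):
                continue
            qi = QUADRANT_LABELS.index(r["quadrant"])
            ri = ROTATION_LABELS.index(int(r["rot_bin"]))
            grid[qi, ri] = r[metric]
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(grid, cmap="viridis")
        ax.set_xticks(range(4), [f"{r}°" for r in ROTATION_LABELS])
        ax.set_yticks(range(4), QUADRANT_LABELS)
        ax.set_xlabel("rotation from OA")
        ax.set_ylabel("longitudinal quadrant")
        fig.colorbar(im, ax=ax, label=metric)
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def domain_table(bbs_with_domains: pd.DataFrame, row_graph: RowGraph) -> DomainTable:
    """Aggregate spacing, orientation and daughter fraction per domain.

    Spacing and angular deviation are attributed to the posterior BB of each
    link (the BB whose anterior partner defines the measurement).  Counts
    over all 16 domains sum to the number of linked BBs.
    """
    bbs = bbs_with_domains.copy()
    links = row_graph.links.set_index("bb_id")
    bbs["spacing_um"] = links["length_um"].reindex(bbs.index).to_numpy()
    bbs["angdev_deg"] = links["angdev_deg"].reindex(bbs.index).to_numpy()

    rows = []
    for q in QUADRANT_LABELS:
        for r in ROTATION_LABELS:
            sel = bbs[(bbs["quadrant"] == q) & (bbs["rot_bin"] == r)]
            linked = sel[np.isfinite(sel["spacing_um"])]
            rows.append({
                "quadrant": q,
                "rot_bin": r,
                "n_bbs": len(sel),
                "n_links": len(linked),
                "spacing_mean_um": linked["spacing_um"].mean(),
                "spacing_sd_um": linked["spacing_um"].std(ddof=0),
                "angdev_mean_deg": linked["angdev_deg"].mean(),
                "angdev_sd_deg": linked["angdev_deg"].std(ddof=0),
                "daughter_fraction": (
                    sel["is_daughter"].mean() if "is_daughter" in sel else np.nan
                ),
            })
    return DomainTable(table=pd.DataFrame(rows))
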