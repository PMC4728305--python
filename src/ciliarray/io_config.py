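"""Calibrated image-stack IO, pipeline configuration and result tables.

Unit conventions used across the whole package:

* Physical coordinates are in micrometres (µm), stored as ``(x, y, z)``
  triples with ``z`` increasing away from the coverslip.
* Voxel arrays are indexed ``[channel, z, y, x]`` (single-channel stacks are
  carried with a length-1 channel axis) and ``voxel_size`` is given in the
  matching axis order ``(dz, dy, dx)``.
* Voxel↔µm conversion happens only here (``ImageStack.um_to_index`` /
  ``index_to_um``); downstream modules work in µm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("ciliarray")
if not logger.handlers:  # library default: info-level messages to stderr
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class CalibrationError(ValueError):
    """Raised when a stack has no usable voxel calibration."""


@dataclass
class ImageStack:
    """A calibrated multi-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Intensity grid, shape ``(n_channels, nz, ny, nx)``.  A 3D array is
        promoted to a single channel.
    voxel_size
        ``(dz, dy, dx)`` in µm.
    channel_names
        One name per channel (defaults to ``ch0, ch1, ...``).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim == 3:
            v = v[None]
        if v.ndim != 4:
            raise ValueError(f"expected 3D or 4D voxel grid, got ndim={v.ndim}")
        self.voxels = v
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(v.shape[0])]
        if len(self.channel_names) != v.shape[0]:
            raise ValueError("channel_names length does not match channel axis")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, key) -> np.ndarray:
        """Return one channel's 3D grid by index or name."""
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.voxels[key]

    # -- µm ↔ voxel conversion --------------------------------------------
    def um_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map µm points (x, y, z) to fractional voxel indices (z, y, x)."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        dz, dy, dx = self.voxel_size
        return np.column_stack([p[:, 2] / dz, p[:, 1] / dy, p[:, 0] / dx])

    def index_to_um(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map voxel indices (z, y, x) to µm points (x, y, z)."""
        i = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        dz, dy, dx = self.voxel_size
        return np.column_stack([i[:, 2] * dx, i[:, 1] * dy, i[:, 0] * dz])

    def extent_um(self) -> np.ndarray:
        """Physical size of the grid, (x, y, z) in µm."""
        nz, ny, nx = self.shape_zyx
        dz, dy, dx = self.voxel_size
        return np.array([nx * dx, ny * dy, nz * dz])


@dataclass
class PipelineConfig:
    """All tunables of the reconstruction pipeline, lengths in µm.

    Defaults are the values the analysis routine was designed around: kernel
    radii for the cell mask (1 µm blur, 0.12 µm Laplacian-of-Gaussian), the
    shape gates (2000 µm² area, 60 µm Feret, 0.85 circularity), the 5 µm mask
    enlargement, the BB detection scales (0.12 µm smoothing, 0.25 µm xy /
    0.6 µm z maxima search, 1.5 µm rolling-z window, sensitivity 6), the
    2.25 µm interior cut, the 1 µm² box and skew+kurtosis cutoff 1 for
    oral-apparatus rejection, the 5 µm fallback link, the 3 µm gap threshold
    and the 2-fold daughter intensity ratio.
    """

    # cell extraction
    blur_large_um: float = 1.0
    log_radius_um: float = 0.12
    triangle_bins: int = 256
    area_min_um2: float = 200.0   # smaller blobs are noise/debris, not cells
    area_max_um2: float = 2000.0
    feret_max_um: float = 60.0
    circularity_min: float = 0.85
    mask_dilate_um: float = 5.0
    # BB detection
    detect_sigma_um: float = 0.12
    maxima_xy_um: float = 0.25
    maxima_z_um: float = 0.6
    rolling_z_um: float = 1.5
    sensitivity: float = 6.0
    interior_depth_um: float = 2.25
    shape_box_um2: float = 1.0
    skewkurt_cutoff: float = 1.0
    intensity_radius_um: float = 0.5
    bb_channel: int = 0
    # polarity and row linking
    pole_sphere_um: float = 8.0
    plane_weight: float = 1.0
    fallback_link_um: float = 5.0
    # organization metrics
    gap_um: float = 3.0
    close_um: float = 1.0
    spacing_bin_um: float = 0.1
    daughter_ratio: float = 2.0

    def __post_init__(self):
        lengths = [
            self.blur_large_um, self.log_radius_um, self.area_max_um2,
            self.feret_max_um, self.circularity_min, self.detect_sigma_um,
            self.maxima_xy_um, self.maxima_z_um, self.rolling_z_um,
            self.interior_depth_um, self.shape_box_um2, self.pole_sphere_um,
            self.fallback_link_um, self.gap_um, self.close_um,
            self.spacing_bin_um, self.intensity_radius_um,
        ]
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths and scales must be > 0")
        if self.mask_dilate_um < 0:
            raise ValueError("mask_dilate_um must be >= 0")
        if self.daughter_ratio <= 1:
            raise ValueError("daughter_ratio must be > 1")
        if self.triangle_bins < 2:
            raise ValueError("triangle_bins must be >= 2")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        """Load a flat key→value JSON config; unknown keys are an error."""
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# TIFF IO
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an ImageJ-compatible TIFF with µm calibration.

    Channels and z interleave as ZCYX pages; z spacing goes in the ImageJ
    metadata and xy size in the resolution tags.
    """
    dz, dy, dx = stack.voxel_size
    data = np.ascontiguousarray(np.swapaxes(stack.voxels, 0, 1))  # (Z,C,Y,X)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
            "Labels": list(stack.channel_names),
        },
    )


def read_stack(path, voxel_size=None, channel_names=None) -> ImageStack:
    """Read a calibrated z-stack from TIFF.

    Calibration comes from the file's ImageJ metadata / resolution tags; a
    ``voxel_size`` override ``(dz, dy, dx)`` takes precedence.  A stack
    without any calibration and no override raises :class:`CalibrationError`
    rather than assuming a default.  2D images are rejected: the pipeline is
    3D throughout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes
        data = series.asarray()
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        res = {}
        for tag in ("XResolution", "YResolution"):
            if tag in page.tags:
                num, den = page.tags[tag].value
                if num:
                    res[tag] = den / num  # µm per pixel when unit is µm

    # plain (non-ImageJ) 3D TIFFs come back with an anonymous leading axis
    # (series "I", sample "S" or unknown "Q"): treat it as Z
    if "Z" not in axes and data.ndim == 3 and axes[0] in "ISQT":
        axes = "Z" + axes[1:]
    if "Z" not in axes:
        raise ValueError(f"not a z-stack: axes={axes!r} in {path.name}")

    # normalize axis order to (C, Z, Y, X)
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    if sorted(order) != list(range(data.ndim)):
        raise ValueError(f"unsupported axes {axes!r} in {path.name}")
    data = np.transpose(data, order)

    if voxel_size is not None:
        vs = tuple(float(s) for s in voxel_size)
    else:
        spacing = meta.get("spacing")
        if spacing is None or "XResolution" not in res or "YResolution" not in res:
            raise CalibrationError(
                f"{path.name}: no voxel calibration in metadata and no override given"
            )
        vs = (float(spacing), float(res["YResolution"]), float(res["XResolution"]))

    if channel_names is None:
        labels = meta.get("Labels")
        if labels and len(labels) >= data.shape[0]:
            channel_names = [str(x) for x in labels[: data.shape[0]]]
    return ImageStack(voxels=data, voxel_size=vs, channel_names=channel_names or [])


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

BB_COLUMNS = [
    "bb_id", "x_um", "y_um", "z_um", "quadrant", "rot_bin",
    "anterior_id", "spacing_um", "angdev_deg", "provenance", "is_daughter",
]


def write_results(cell_model, row_graph, domain_table, out_dir) -> dict:
    """Write the per-BB CSV, per-cell JSON summary and per-domain CSV.

    ``cell_model``/``row_graph``/``domain_table`` are the objects produced by
    :mod:`ciliarray.polarity_rows` and :mod:`ciliarray.organization_metrics`
    for a single cell.  Column order is deterministic.  Returns the summary
    dict that was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bbs = cell_model.bbs.reset_index(drop=True).copy()
    bbs["bb_id"] = np.arange(len(bbs), dtype=int)
    links = row_graph.links if row_graph is not None else None
    if links is not None and len(bbs):
        bbs = bbs.merge(
            links[["bb_id", "anterior_id", "length_um", "angdev_deg", "provenance"]],
            on="bb_id", how="left",
        ).rename(columns={"length_um": "spacing_um"})
    else:
        for col in ("anterior_id", "spacing_um", "angdev_deg"):
            bbs[col] = np.nan
        bbs["provenance"] = "unlinked"
    cols = [c for c in BB_COLUMNS if c in bbs.columns]
    extra = [c for c in bbs.columns if c.startswith("intensity_")]
    bbs[cols + sorted(extra)].to_csv(out_dir / "bbs.csv", index=False)

    if domain_table is not None:
        domain_table.table.to_csv(out_dir / "domains.csv", index=False)

    summary = {
        "n_cortical_bbs": int(len(cell_model.bbs)),
        "pole_anterior_um": [float(v) for v in cell_model.pole_anterior],
        "pole_posterior_um": [float(v) for v in cell_model.pole_posterior],
        "oa_centroid_um": (
            None if cell_model.oa_centroid is None
            else [float(v) for v in cell_model.oa_centroid]
        ),
        "hull_surface_area_um2": float(cell_model.hull_surface_area),
        "hull_volume_um3": float(cell_model.hull_volume),
        "n_links": int(len(links)) if links is not None else 0,
    }
    with open(out_dir / "cell_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_bb_table(path) -> pd.DataFrame:
    """Read back a per-BB CSV written by :func:`write_results`."""
    return pd.read_csv(path)
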