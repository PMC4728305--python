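"""Locate one complete cell in a contaminated field and crop the stack to it.

The cell outline is extracted from the maximum-intensity projection (MIP) of
the BB-marker channel: mean-subtract, blur with a large (1 µm) Gaussian to
merge individual BB spots into cell-scale features, sharpen feature borders
with a small (0.12 µm) Laplacian-of-Gaussian, smooth again, Triangle-threshold
the histogram, then filter connected components by shape.  Debris and partial
cells fail the shape gates (area > 2000 µm², max Feret diameter > 60 µm or
circularity < 0.85); the largest survivor is the cell of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_triangle
from skimage.measure import label, regionprops


from .io_config import ImageStack, PipelineConfig, logger


class NoCellFoundError(RuntimeError):
    """No object in the field survived the shape filter."""


@dataclass
class CellMask:
    """A 2D cell silhouette in MIP space with its shape descriptors."""

    mask: np.ndarray          # 2D bool, (y, x)
    area_um2: float
    feret_um: float
    circularity: float
    bbox: tuple[int, int, int, int]   # (y0, x0, y1, x1)
    n_discarded_survivors: int = 0


def shape_filter(area_um2: float, feret_um: float, circularity: float,
                 cfg: PipelineConfig | None = None) -> tuple[bool, str]:
    """Gate one segmented object on its 2D shape.

    Returns ``(keep, reason)`` where ``reason`` names the first failing test
    (``area`` / ``feret`` / ``circularity``) or is ``"ok"``.
    """
    cfg = cfg or PipelineConfig()
    if area_um2 > cfg.area_max_um2:
        return False, "area"
    if feret_um > cfg.feret_max_um:
        return False, "feret"
    if circularity < cfg.circularity_min:
        return False, "circularity"
    return True, "ok"


def _region_descriptors(region, dx: float, dy: float):
    """Physical area, max Feret diameter and circularity of a region.

    Circularity is 4π·area/perimeter²; the perimeter uses the Crofton
    formula, which is unbiased on digitized smooth shapes (the naive contour
    staircase inflates the perimeter of a 2:1 ellipse by ~5%, enough to push
    a genuine cell below the 0.85 gate).  Feret is the 2D max caliper.
    """
    area = region.area * dx * dy
    feret = region.feret_diameter_max * dx
    perim = region.perimeter_crofton * dx
    circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    return area, feret, circ


def make_cell_mask(stack: ImageStack, cfg: PipelineConfig | None = None) -> CellMask:
    """Segment the single complete cell from the BB-channel MIP.

    Raises :class:`NoCellFoundError` when nothing passes the shape filter.
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    if abs(dx - dy) > 1e-9:
        raise ValueError("cell extraction assumes square xy pixels")

    # unsigned-image arithmetic throughout (negative results clip to zero),
    # so the Triangle histogram keeps its background peak at the origin
    mip = stack.channel(cfg.bb_channel).max(axis=0).astype(np.float64)
    mip = np.clip(mip - mip.mean(), 0.0, None)
    smooth = ndi.gaussian_filter(mip, cfg.blur_large_um / dx)
    # Laplacian-of-Gaussian sharpening (image minus scale-normalized LoG
    # response): deepens the valleys that separate touching large features
    # while keeping the cell blob itself above background
    sigma_px = cfg.log_radius_um / dx
    edges = np.clip(
        smooth - sigma_px**2 * ndi.gaussian_laplace(smooth, sigma_px), 0.0, None
    )
    final = ndi.gaussian_filter(edges, cfg.blur_large_um / dx)

    thr = threshold_triangle(final, nbins=cfg.triangle_bins)
    binary = final > thr
    labels = label(binary)

    survivors = []
    for region in regionprops(labels):
        # sub-cellular specks (noise, debris fragments) are not candidate
        # cells; the shape gates below only bound objects from above
        if region.area * dx * dy < cfg.area_min_um2:
            continue
        area, feret, circ = _region_descriptors(region, dx, dy)
        keep, reason = shape_filter(area, feret, circ, cfg)
        logger.debug(
            "object %d: area=%.1f feret=%.1f circ=%.3f -> %s",
            region.label, area, feret, circ, reason if not keep else "keep",
        )
        if keep:
            survivors.append((area, feret, circ, region))
    if not survivors:
        raise NoCellFoundError("no cell found: all objects rejected by shape filter")

    survivors.sort(key=lambda s: s[0], reverse=True)
    area, feret, circ, region = survivors[0]
    if len(survivors) > 1:
        logger.info("kept largest of %d surviving objects", len(survivors))
    mask = labels == region.label
    y0, x0, y1, x1 = region.bbox
    return CellMask(
        mask=mask, area_um2=area, feret_um=feret, circularity=circ,
        bbox=(y0, x0, y1, x1), n_discarded_survivors=len(survivors) - 1,
    )


def crop_to_mask(stack: ImageStack, cell_mask: CellMask,
                 cfg: PipelineConfig | None = None) -> tuple[ImageStack, np.ndarray]:
    """Dilate the mask (default 5 µm disc), zero voxels outside it and crop.

    The crop is the dilated mask's bounding box clamped to the image; the z
    range is kept whole.  Returns the cropped stack and the µm offset
    ``(x, y, z)`` of the crop origin in the original frame.
    """
    cfg = cfg or PipelineConfig()
    dz, dy, dx = stack.voxel_size
    r_px = cfg.mask_dilate_um / dx
    if r_px >= 1.0:
        # disc dilation via the Euclidean distance transform (fast for the
        # large 5 µm default radius)
        dilated = ndi.distance_transform_edt(~cell_mask.mask) <= r_px
    else:
        dilated = cell_mask.mask
    ys, xs = np.nonzero(dilated)
    if ys.size == 0:
        raise ValueError("empty cell mask")
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1

    voxels = stack.voxels[:, :, y0:y1, x0:x1].copy()
    voxels *= dilated[None, None, y0:y1, x0:x1]
    offset_um = np.array([x0 * dx, y0 * dy, 0.0])
    cropped = ImageStack(
        voxels=voxels, voxel_size=stack.voxel_size,
        channel_names=list(stack.channel_names),
    )
    return cropped, offset_um


def extract_cell(stack: ImageStack, cfg: PipelineConfig | None = None):
    """Full extraction: mask, then crop.  Returns (stack, offset_um, mask)."""
    cfg = cfg or PipelineConfig()
    mask = make_cell_mask(stack, cfg)
    cropped, offset = crop_to_mask(stack, mask, cfg)
    return cropped, offset, mask
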