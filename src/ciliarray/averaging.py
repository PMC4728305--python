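"""Polarity-aligned 3D fluorescence averaging of BB subvolumes.

Because the reconstruction knows every BB position and the cell's polarity,
subvolumes around BBs can be resampled into a common oriented frame (cube
x-axis along the posterior→anterior cell axis, cube z along the local
outward surface normal) and averaged voxelwise.  Averaging many aligned BBs
builds sub-resolution composite images; flanking peaks in the average
linescan reproduce the mean spacing of within-row neighbours, and two
datasets sharing a fiducial channel can be registered by translation into a
multi-channel composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from skimage.registration import phase_cross_correlation

from .io_config import ImageStack, logger
from .polarity_rows import CellModel


@dataclass
class AverageVolume:
    """Mean-intensity cube centred on the BB, axes in the canonical frame
    (array index 0 = anteroposterior x, 1 = lateral y, 2 = surface normal z);
    odd dimensions so a centre voxel exists."""

    data: np.ndarray
    n: int
    channel: str
    sampling_um: float

    @property
    def half(self) -> int:
        return self.data.shape[0] // 2

    def axis_coords_um(self) -> np.ndarray:
        """Physical coordinate of each sample along one cube axis (0 centre)."""
        k = self.data.shape[0]
        return (np.arange(k) - k // 2) * self.sampling_um


def extract_subvolumes(stack: ImageStack, cell: CellModel, channel,
                       selection: np.ndarray | None = None,
                       size_um: float = 4.0,
                       sampling_um: float = 0.125):
    """Resample an oriented cube around each selected BB.

    The cube's x-axis points along the cell's posterior→anterior axis and
    its z-axis along the local outward surface normal (the BB's radial
    direction from the axis), so averages from differently oriented cells
    align.  Trilinear interpolation; cubes clipped by the stack border are
    dropped.

    Returns ``(subvolumes (m, k, k, k), kept_indices, n_dropped)``.
    """
    if size_um < 1e-6:
        raise ValueError("cube size must be positive")
    if size_um > min(stack.extent_um()):
        raise ValueError(
            "no usable BBs: cube larger than the stack, every cube clipped"
        )
    n_samp = int(round(size_um / sampling_um))
    n_samp += (n_samp + 1) % 2  # odd so a centre voxel exists
    half = n_samp // 2

    pos = cell.positions
    if selection is None:
        selection = np.arange(len(pos))
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("no BBs selected for averaging")

    ex = cell.axis
    mid = 0.5 * (cell.pole_anterior + cell.pole_posterior)
    img = stack.channel(channel).astype(np.float64)
    dz, dy, dx = stack.voxel_size
    nzyx = np.array(img.shape)

    offsets = (np.arange(n_samp) - half) * sampling_um
    oi, oj, ok = np.meshgrid(offsets, offsets, offsets, indexing="ij")

    subs, kept, dropped = [], [], 0
    for i in selection:
        p = pos[i]
        lat = (p - mid) - ((p - mid) @ ex) * ex
        nl = np.linalg.norm(lat)
        if nl < 1e-9:
            dropped += 1
            continue
        ez = lat / nl               # outward surface normal (radial)
        ey = np.cross(ez, ex)
        world = (p[None, None, None, :]
                 + oi[..., None] * ex + oj[..., None] * ey + ok[..., None] * ez)
        coords = np.stack([
            world[..., 2] / dz, world[..., 1] / dy, world[..., 0] / dx,
        ])
        if (coords.min() < 0
                or np.any(coords.max(axis=(1, 2, 3)) > nzyx - 1)):
            dropped += 1
            continue
        subs.append(ndi.map_coordinates(img, coords.reshape(3, -1), order=1)
                    .reshape(n_samp, n_samp, n_samp))
        kept.append(i)
    if not subs:
        raise ValueError("no usable BBs: all cubes clipped by the stack border")
    logger.info("extract_subvolumes: %d kept, %d dropped", len(subs), dropped)
    return np.stack(subs), np.array(kept), dropped


def average_volumes(subvolumes: np.ndarray, channel: str = "",
                    sampling_um: float = 0.125) -> AverageVolume:
    """Voxelwise mean of aligned subvolumes."""
    subs = np.asarray(subvolumes, dtype=float)
    if subs.ndim != 4 or len(subs) < 1:
        raise ValueError("expected a non-empty (m, k, k, k) subvolume array")
    return AverageVolume(data=subs.mean(axis=0), n=len(subs),
                         channel=channel, sampling_um=sampling_um)


def _gauss(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


@dataclass
class LinescanFit:
    """Gaussian fit of the central peak of the average linescan plus the
    positions/spacings of the flanking neighbour peaks."""

    converged: bool
    amplitude: float = np.nan
    center_um: float = np.nan
    sigma_um: float = np.nan
    offset: float = np.nan
    r_squared: float = np.nan
    linescan: np.ndarray = field(default_factory=lambda: np.array([]))
    coords_um: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_positions_um: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_spacings_um: np.ndarray = field(default_factory=lambda: np.array([]))


def linescan_fit(avg: AverageVolume, n_fit: int = 9) -> LinescanFit:
    """Fit a Gaussian to the central points of the anteroposterior linescan.

    The linescan is the x profile through the centre of the 2D maximum
    projection (projected along the cube's surface-normal axis).  The central
    ``n_fit`` points are fit to ``A·exp(−(x−µ)²/2σ²) + c`` and R² is reported
    for those points.  Flanking peaks (average anterior/posterior partners)
    are detected on the full profile with sub-sample parabolic refinement;
    ``peak_spacings_um`` are the centre-to-centre distances of consecutive
    peaks.
    """
    proj = avg.data.max(axis=2)          # project along local z
    c = avg.half
    profile = proj[:, c].astype(float)
    x = avg.axis_coords_um()

    lo, hi = c - n_fit // 2, c + n_fit // 2 + 1
    xs, ys = x[lo:hi], profile[lo:hi]
    if np.ptp(ys) <= 0:
        logger.warning("linescan_fit: flat profile, fit skipped")
        return LinescanFit(converged=False, linescan=profile, coords_um=x)
    p0 = [float(ys.max() - ys.min()), 0.0, 2 * avg.sampling_um, float(ys.min())]
    try:
        popt, _ = curve_fit(_gauss, xs, ys, p0=p0, maxfev=5000)
    except RuntimeError:
        logger.warning("linescan_fit: fit did not converge")
        return LinescanFit(converged=False, linescan=profile, coords_um=x)
    resid = ys - _gauss(xs, *popt)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan

    # flanking peaks with parabolic sub-sample refinement; peaks closer than
    # half the diffraction-limited BB spacing are one structure
    min_dist = max(2, int(round(0.5 / avg.sampling_um)))
    idx, _ = find_peaks(profile, prominence=0.1 * np.ptp(profile),
                        distance=min_dist)
    peaks = []
    for i in idx:
        if 0 < i < len(profile) - 1:
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            peaks.append(x[i] + delta * avg.sampling_um)
        else:
            peaks.append(x[i])
    peaks = np.sort(np.asarray(peaks))
    spacings = np.diff(peaks) if len(peaks) > 1 else np.array([])

    return LinescanFit(
        converged=True, amplitude=float(popt[0]), center_um=float(popt[1]),
        sigma_um=float(abs(popt[2])), offset=float(popt[3]), r_squared=r2,
        linescan=profile, coords_um=x,
        peak_positions_um=peaks, peak_spacings_um=spacings,
    )


def register_channels(avg_a_fiducial: AverageVolume, avg_a_other: AverageVolume,
                      avg_b_fiducial: AverageVolume, avg_b_other: AverageVolume,
                      upsample: int = 20):
    """Merge two datasets that share a fiducial channel.

    The rigid translation aligning dataset B's fiducial average onto dataset
    A's is found by phase correlation (sub-sample precision) and applied to
    B's other channel; geometry within each dataset is untouched.  Returns
    ``(channels dict, shift_um)`` where the dict holds the fiducial (mean of
    both aligned fiducials), A's other channel, and B's shifted other
    channel.
    """
    a, b = avg_a_fiducial.data, avg_b_fiducial.data
    if a.shape != b.shape:
        raise ValueError("fiducial averages must share one grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("fiducial correlation ambiguous: flat fiducial channel")
    shift, error, _ = phase_cross_correlation(a, b, upsample_factor=upsample)
    shift_um = np.asarray(shift, dtype=float) * avg_a_fiducial.sampling_um

    b_fid = ndi.shift(b, shift, order=1, mode="nearest")
    b_other = ndi.shift(avg_b_other.data, shift, order=1, mode="nearest")
    channels = {
        avg_a_fiducial.channel or "fiducial": 0.5 * (a + b_fid),
        avg_a_other.channel or "other_a": avg_a_other.data,
        (avg_b_other.channel or "other_b") + "_registered": b_other,
    }
    return channels, shift_um
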