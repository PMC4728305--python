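"""Shared fixtures: synthetic cells rendered once per session."""

import logging

import numpy as np
import pytest
from scipy.spatial import cKDTree

import ciliarray as ca

logging.getLogger("ciliarray").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_cell():
    """Default wild-type-like preset with camera noise (fixed seed)."""
    spec = ca.tetrahymena_preset(seed=11)
    gt, stack = ca.make_cell(spec)
    return spec, gt, stack


@pytest.fixture(scope="session")
def analyzed_default(default_cell):
    _, gt, stack = default_cell
    return gt, ca.analyze_stack(stack)


@pytest.fixture(scope="session")
def clean_cell():
    """Noise-free, gap-free cell for round-trip recovery properties."""
    spec = ca.tetrahymena_preset(seed=12, noise_model=(0.0, 0.0))
    gt, stack = ca.make_cell(spec)
    return spec, gt, stack


@pytest.fixture(scope="session")
def analyzed_clean(clean_cell):
    _, gt, stack = clean_cell
    return gt, ca.analyze_stack(stack)


@pytest.fixture(scope="session")
def const2_cell():
    """Smaller cell with constant 2 µm within-row spacing (for closed-form
    spacing and averaging checks)."""
    # aspect ratio < 2 so the projected silhouette clears the 0.85
    # circularity gate; OA spot count scaled down with the cell
    spec = ca.tetrahymena_preset(
        seed=13, semi_axes=(14.0, 8.0, 8.0), n_rows=12, oa_bb_count=60,
        bb_spacing_profile=lambda t: 2.0 + 0.0 * np.asarray(t),
    )
    gt, stack = ca.make_cell(spec)
    return spec, gt, stack


@pytest.fixture(scope="session")
def analyzed_const2(const2_cell):
    _, gt, stack = const2_cell
    return gt, ca.analyze_stack(stack)


def match_to_ground_truth(gt, analysis, radius_um=0.5):
    """Match detected cortical BBs to ground truth within a radius.

    Returns (recall, precision, det_positions, gt_index_of_each_detection).
    """
    det = analysis.cell_stack.positions + analysis.crop_offset_um
    d_gt, _ = cKDTree(det).query(gt.bb_positions, k=1,
                                 distance_upper_bound=radius_um)
    d_det, gt_idx = cKDTree(gt.bb_positions).query(det, k=1)
    recall = float(np.isfinite(d_gt).mean())
    precision = float((d_det <= radius_um).mean())
    return recall, precision, det, gt_idx


def link_accuracy(gt, analysis, radius_um=0.5):
    """Fraction of pipeline links matching ground-truth row successors."""
    _, _, det, gt_idx = match_to_ground_truth(gt, analysis, radius_um)
    d_det, _ = cKDTree(gt.bb_positions).query(det, k=1)
    gt_ant = gt.anterior_partner_ids()
    linked = analysis.row_graph.linked
    good = total = 0
    for b, a in zip(linked["bb_id"], linked["anterior_id"]):
        total += 1
        if (d_det[b] <= radius_um and d_det[a] <= radius_um
                and gt_ant[gt_idx[b]] == gt_idx[a]):
            good += 1
    return good / total if total else np.nan
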