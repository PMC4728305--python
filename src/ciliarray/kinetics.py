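"""Cell-cycle kinetics: stage durations, per-stage rates and predicted counts.

Cells are staged I–IV by the morphology of the developing oral apparatus (an
input label, not computed here).  Durations follow from an asynchronous
exponentially growing population: the time spent in a stage is its relative
frequency times the population doubling time.  Rates divide the change of a
parameter (cortical BB count, surface area, mean spacing) across a stage by
that stage's duration; the 0-minute baseline is the mean over the quartile
of Stage I cells with the fewest cortical BBs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ["I", "II", "III", "IV"]


@dataclass
class CellCycleTimeline:
    doubling_time_min: float
    frequencies: dict[str, float]
    durations_min: dict[str, float]


def stage_durations(stage_counts: dict[str, int] | pd.Series,
                    doubling_time_min: float) -> CellCycleTimeline:
    """Stage durations from population frequencies.

    ``duration_s = (n_s / Σn) · doubling_time``; durations sum to the
    doubling time by construction.
    """
    counts = {s: float(stage_counts[s]) for s in stage_counts}
    if any(v < 0 for v in counts.values()):
        raise ValueError("stage counts must be >= 0")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no staged cells")
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be > 0")
    freqs = {s: v / total for s, v in counts.items()}
    durs = {s: f * doubling_time_min for s, f in freqs.items()}
    return CellCycleTimeline(doubling_time_min, freqs, durs)


def summarize_stages(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean ± s.d. of the per-cell parameters.

    ``cells`` columns: ``stage``, ``bb_count``, and optionally
    ``surface_area``, ``mean_spacing``, ``daughter_count``.
    """
    agg = {}
    for col in ("bb_count", "surface_area", "mean_spacing", "daughter_count"):
        if col in cells.columns:
            agg[f"{col}_mean"] = (col, "mean")
            agg[f"{col}_sd"] = (col, lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    out = cells.groupby("stage").agg(n_cells=("stage", "size"), **agg)
    return out.reindex([s for s in STAGES if s in out.index])


def stage_i_baseline(cells: pd.DataFrame, parameter: str = "bb_count") -> float:
    """Mean parameter value of the Stage I quartile with fewest cortical BBs
    (the 0-minute point of the cell cycle)."""
    stage1 = cells[cells["stage"] == "I"].sort_values("bb_count")
    if len(stage1) == 0:
        raise ValueError("no Stage I cells")
    q = max(1, len(stage1) // 4)
    return float(stage1.head(q)[parameter].mean())


def stage_rates(stage_means: dict[str, float], timeline: CellCycleTimeline,
                baseline: float) -> pd.DataFrame:
    """Per-stage and whole-cycle rates of change of one parameter.

    The change across Stage I is measured from the baseline (earliest Stage I
    cells); each later stage changes from the previous stage's mean.  Rates
    are the change divided by the stage duration; the whole-cycle rate is the
    total change over the doubling time.  ``rate_rounded`` reports one
    decimal, the convention used for presenting BB-addition rates.
    """
    rows = []
    prev = baseline
    for s in STAGES:
        if s not in stage_means:
            continue
        dur = timeline.durations_min[s]
        if dur <= 0:
            raise ZeroDivisionError(f"stage {s} has zero duration")
        change = stage_means[s] - prev
        rows.append({
            "stage": s, "change": change, "duration_min": dur,
            "rate_per_min": change / dur,
            "rate_rounded": round(change / dur, 1),
        })
        prev = stage_means[s]
    total_change = prev - baseline
    rows.append({
        "stage": "cycle", "change": total_change,
        "duration_min": timeline.doubling_time_min,
        "rate_per_min": total_change / timeline.doubling_time_min,
        "rate_rounded": round(total_change / timeline.doubling_time_min, 1),
    })
    return pd.DataFrame(rows)


def predicted_counts(stage_means: dict[str, float],
                     stage_daughters: dict[str, float]) -> pd.DataFrame:
    """Predicted vs observed cortical BB counts through the cycle.

    Division halves the Stage IV count; each stage then adds its observed
    mean number of newly assembled daughter BBs.  The discrepancy is
    observed − predicted, also expressed as a percentage of the observed
    count.  Pure arithmetic, exact to double precision.
    """
    rows = []
    predicted = stage_means["IV"] / 2.0
    for s in STAGES:
        if s not in stage_means:
            continue
        predicted_after = predicted + stage_daughters.get(s, 0.0)
        observed = stage_means[s]
        disc = observed - predicted_after
        rows.append({
            "stage": s,
            "post_division": predicted,
            "predicted": predicted_after,
            "observed": observed,
            "discrepancy": disc,
            "discrepancy_pct": 100.0 * disc / observed if observed else 0.0,
        })
        predicted = predicted_after
    return pd.DataFrame(rows)


def starved_new_bb_fraction(cells: pd.DataFrame) -> float:
    """Population mean of the per-cell daughter fraction.

    ``cells`` columns: ``bb_count``, ``daughter_count``.  Non-cycling
    (starved) populations should stay below a few percent.
    """
    frac = cells["daughter_count"] / cells["bb_count"]
    if (frac >= 1.0).any():
        import warnings
        warnings.warn("cell with 100% daughters: implausible daughter calls")
    return float(frac.mean())
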