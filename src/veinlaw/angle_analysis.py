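"""Bifurcation-angle analyses.

Murray's optimality argument extends beyond diameters: at an asymmetric
fork the wider child should leave the parent at the smaller angle.  We
test this by pairing every child vein with its parent — each fully
angled fork yields two (delta_angle, d_child/d0) pairs — and measuring
the rank correlation between the parent-child angular difference and the
child/parent diameter ratio.  A negative correlation supports the
prediction; a correlation near zero means no trend.

The child-child angle analyses (deviation from Murray's Law binned by
the angle between the two children) reuse ``dataset_variants.bin_means``
with ``sort_key='angle_children'``; there is no separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ParentChildPair", "build_pairs", "angle_summary", "murray_angle_test"]

# fixed histogram grid for the summary heatmap
ANGLE_GRID = (0.0, 60.0)
RATIO_GRID = (0.4, 1.4)
GRID_CELLS = 30


@dataclass(frozen=True)
class ParentChildPair:
    """One parent-child vein pair: angular difference (degrees) and the
    child/parent diameter ratio (dimensionless)."""

    record_index: int
    delta_angle: float
    child_over_parent: float

    def __post_init__(self):
        if not (0.0 <= self.delta_angle < 180.0):
            raise ValueError(f"delta_angle must lie in [0, 180), got {self.delta_angle}")
        if self.child_over_parent <= 0:
            raise ValueError("child_over_parent must be positive")


def build_pairs(records) -> tuple[list[ParentChildPair], int]:
    """Two pairs per fully angled record; records missing either
    parent-child angle are skipped and counted.

    Accepts a DataFrame with canonical columns or an iterable of objects
    with ``d0``, ``d1``, ``d2``, ``angle_parent_child1/2`` attributes.
    Returns ``(pairs, n_skipped)``.
    """
    if isinstance(records, pd.DataFrame):
        it = records.itertuples(index=True)
        def fields(r):
            return (r.Index, r.d0, r.d1, r.d2, r.angle_parent_child1, r.angle_parent_child2)
    else:
        it = enumerate(records)
        def fields(t):
            i, r = t
            return (i, r.d0, r.d1, r.d2, r.angle_parent_child1, r.angle_parent_child2)

    pairs: list[ParentChildPair] = []
    skipped = 0
    for item in it:
        idx, d0, d1, d2, a1, a2 = fields(item)
        if a1 is None or a2 is None or (isinstance(a1, float) and np.isnan(a1)) or (
            isinstance(a2, float) and np.isnan(a2)
        ):
            skipped += 1
            continue
        pairs.append(ParentChildPair(idx, float(a1), float(d1) / float(d0)))
        pairs.append(ParentChildPair(idx, float(a2), float(d2) / float(d0)))
    return pairs, skipped


def _as_arrays(pairs: Sequence[ParentChildPair]) -> tuple[np.ndarray, np.ndarray]:
    angles = np.array([p.delta_angle for p in pairs], dtype=float)
    ratios = np.array([p.child_over_parent for p in pairs], dtype=float)
    return angles, ratios


def angle_summary(pairs: Sequence[ParentChildPair]) -> dict:
    """Mean/population-sd of both pair coordinates plus a fixed-grid 2-D
    histogram (angle 0-60 degrees x ratio 0.4-1.4, 30x30 cells)."""
    if not pairs:
        raise ValueError("no pairs to summarize")
    angles, ratios = _as_arrays(pairs)
    hist, aedges, redges = np.histogram2d(
        angles,
        ratios,
        bins=GRID_CELLS,
        range=[ANGLE_GRID, RATIO_GRID],
    )
    return {
        "n_pairs": len(pairs),
        "mean_delta_angle": float(angles.mean()),
        "sd_delta_angle": float(angles.std()),      # population sd
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std()),
        "histogram": hist,
        "angle_edges": aedges,
        "ratio_edges": redges,
    }


def murray_angle_test(pairs: Sequence[ParentChildPair]) -> dict:
    """Spearman rank correlation between delta-angle and diameter ratio.

    Murray's prediction (wider child at the smaller angle) implies a
    negative correlation; rank-based, so invariant under any monotone
    rescaling of either axis.  Requires at least 10 pairs.
    """
    if len(pairs) < 10:
        raise ValueError(f"need at least 10 pairs, got {len(pairs)}")
    angles, ratios = _as_arrays(pairs)
    if np.ptp(angles) == 0 or np.ptp(ratios) == 0:
        raise ValueError("correlation undefined: an axis is constant (all tied)")
    rho, p = stats.spearmanr(angles, ratios)
    return {"rho": float(rho), "p_value": float(p), "n": len(pairs)}
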