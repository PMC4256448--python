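"""Data-driven count filtering by between-replicate Jaccard similarity.

Weakly abundant features contribute noise but no reproducible signal.  For
a candidate threshold s, normalized counts are binarized (> s) and the
Jaccard similarity of the presence/absence vectors is averaged over all
within-group replicate pairs; the retained threshold s* maximizes that
average, and features never exceeding s* in any sample are removed.  This
reproduces the global-Jaccard strategy of data-based filters for RNA-seq
(a fixed-CPM cutoff is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .normalization import normalized_counts, tmm_factors

__all__ = ["FilterResult", "jaccard_index", "jaccard_filter", "cpm_filter"]

GRID_CAP = 500
GRID_PERCENTILE = 95.0


@dataclass
class FilterResult:
    s_star: float
    grid: list[tuple[float, float]]  # (threshold, mean Jaccard)
    retained: list
    removed: list

    def summary(self) -> dict:
        return {
            "s_star": self.s_star,
            "n_retained": len(self.retained),
            "n_removed": len(self.removed),
            "grid": [[float(s), float(j)] for s, j in self.grid],
        }


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for boolean vectors; empty union -> 0."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _mean_jaccard(B: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    return float(np.mean([jaccard_index(B[:, i], B[:, j]) for i, j in pairs]))


def jaccard_filter(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    factors: pd.Series | None = None,
    grid: np.ndarray | None = None,
) -> FilterResult:
    """Choose the presence threshold maximizing within-group Jaccard
    similarity and drop features below it everywhere.

    ``groups`` maps sample -> replicate group (canonically the four
    line x condition combinations); every group needs >= 2 replicates to
    contribute pairs.  Ties on the grid go to the smallest threshold.
    """
    groups = pd.Series(groups).reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a replicate group")
    pairs: list[tuple[int, int]] = []
    for _, idx in groups.groupby(groups).groups.items():
        cols = [counts.columns.get_loc(c) for c in idx]
        pairs.extend(combinations(cols, 2))
    if not pairs:
        raise ValueError("no within-group replicate pairs (need >= 2 per group)")

    norm = normalized_counts(counts, tmm_factors(counts) if factors is None else factors)
    X = norm.to_numpy(dtype=float)
    if grid is None:
        vals = np.unique(X[X > 0])
        if vals.size:
            vals = vals[vals <= np.percentile(vals, GRID_PERCENTILE)]
        if vals.size > GRID_CAP:
            vals = vals[np.linspace(0, vals.size - 1, GRID_CAP).astype(int)]
        grid = np.concatenate([[0.0], vals])
    grid = np.unique(np.asarray(grid, dtype=float))

    curve = [(float(s), _mean_jaccard(X > s, pairs)) for s in grid]
    best = max(curve, key=lambda sj: (sj[1], -sj[0]))
    s_star = best[0]
    keep_mask = (X > s_star).any(axis=1)
    retained = list(counts.index[keep_mask])
    removed = list(counts.index[~keep_mask])
    if not retained:
        raise ValueError(
            "filter removed every feature; supply a smaller threshold grid"
        )
    return FilterResult(s_star=s_star, grid=curve, retained=retained, removed=removed)


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 1):
    """Fixed-threshold alternative: keep features with CPM > min_cpm in at
    least ``min_samples`` samples."""
    cpm = counts / counts.sum(axis=0) * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return list(counts.index[keep]), list(counts.index[~keep])
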