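"""Curvature-plus-topography dissimilarity metric and its salience fit.

Perceived dissimilarity between samples i and j is modelled as the
Euclidean distance in a space spanned by the difference in rms curvature
and a perpendicular offset of length alpha applied when the two samples
have different topographic structure:

    D_ij = sqrt( (kappa_i - kappa_j)^2 + (alpha * [topo_i != topo_j])^2 )

alpha (mm^-1) measures the salience of a topography change relative to a
curvature change.  It is estimated by maximizing the Pearson correlation
between D_ij and the inter-sample distances of a perceptual embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetricFit",
    "metric_D",
    "linear_metric",
    "dissimilarity_table",
    "pair_vector",
    "fit_alpha",
    "compare_metrics",
]


@dataclass(frozen=True)
class MetricFit:
    """Result of fitting the topography-salience parameter alpha."""

    alpha: float
    pearson_rho: float
    variant: str  # "euclidean" | "linear"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not -1.0 <= self.pearson_rho <= 1.0 + 1e-12:
            raise ValueError("pearson_rho outside [-1, 1]")


def metric_D(kappa_i: float, kappa_j: float, same_topo: bool, alpha: float) -> float:
    """Euclidean dissimilarity between two samples (mm^-1)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    dk = kappa_i - kappa_j
    if same_topo:
        return abs(dk)
    return float(np.hypot(dk, alpha))


def linear_metric(kappa_i: float, kappa_j: float, same_topo: bool, alpha: float) -> float:
    """Alternative one-parameter metric: |d kappa| + alpha * [topographies differ]."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return abs(kappa_i - kappa_j) + (0.0 if same_topo else alpha)


_VARIANTS = {"euclidean": metric_D, "linear": linear_metric}


def dissimilarity_table(summary: pd.DataFrame, alpha: float, variant: str = "euclidean") -> pd.DataFrame:
    """Full symmetric dissimilarity table from a roughness summary.

    ``summary`` must be indexed by sample id with columns ``kappa`` and
    ``topo_id`` (as produced by :func:`tactsurf.roughness.roughness_summary`).
    """
    fn = _VARIANTS[variant]
    ids = list(summary.index)
    kappa = summary["kappa"].to_numpy(dtype=float)
    topo = summary["topo_id"].to_numpy()
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(kappa[i], kappa[j], topo[i] == topo[j], alpha)
    return pd.DataFrame(D, index=ids, columns=ids)


def pair_vector(table: pd.DataFrame) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Unordered sample pairs and their values, in a fixed order."""
    ids = list(table.index)
    pairs = list(combinations(ids, 2))
    vals = np.array([table.loc[i, j] for i, j in pairs], dtype=float)
    return pairs, vals


def _pair_metric_values(
    kappas: np.ndarray, topo_labels: np.ndarray, alpha: float, variant: str
) -> np.ndarray:
    fn = _VARIANTS[variant]
    n = len(kappas)
    return np.array(
        [
            fn(kappas[i], kappas[j], topo_labels[i] == topo_labels[j], alpha)
            for i, j in combinations(range(n), 2)
        ]
    )


def fit_alpha(
    embed_distances: np.ndarray,
    kappas: np.ndarray,
    topo_labels: np.ndarray,
    variant: str = "euclidean",
    grid_points: int = 1000,
) -> MetricFit:
    """Fit alpha by maximizing Pearson correlation with embedding distances.

    ``embed_distances`` must hold one value per unordered sample pair, in
    the order of ``itertools.combinations`` over the sample indices (as
    returned by :func:`pair_vector`).  A dense grid scan over
    [0, 10 * max |d kappa|] is refined by bounded scalar optimization; ties
    are broken toward smaller alpha.
    """
    embed_distances = np.asarray(embed_distances, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    topo_labels = np.asarray(topo_labels)
    n_pairs = len(kappas) * (len(kappas) - 1) // 2
    if len(embed_distances) != n_pairs:
        raise ValueError(f"expected {n_pairs} pair distances, got {len(embed_distances)}")
    if np.std(embed_distances) == 0:
        raise ValueError("embedding distances have zero variance")

    def neg_rho(alpha: float) -> float:
        dvals = _pair_metric_values(kappas, topo_labels, alpha, variant)
        if np.std(dvals) == 0:
            return 1.0
        return -stats.pearsonr(dvals, embed_distances)[0]

    hi = 10.0 * float(np.max(np.abs(np.subtract.outer(kappas, kappas))))
    if hi == 0:
        hi = 10.0
    grid = np.linspace(0.0, hi, grid_points)
    scores = np.array([neg_rho(a) for a in grid])
    best = int(np.argmin(scores))  # argmin takes the first (smallest alpha) on ties
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid_points - 1)]
    res = optimize.minimize_scalar(neg_rho, bounds=(lo_b, hi_b), method="bounded")
    alpha = float(res.x) if res.fun <= scores[best] else float(grid[best])
    return MetricFit(alpha=max(alpha, 0.0), pearson_rho=float(-neg_rho(alpha)), variant=variant)


def compare_metrics(
    embed_distances: np.ndarray, kappas: np.ndarray, topo_labels: np.ndarray
) -> dict[str, MetricFit]:
    """Fit both metric variants and report their correlations."""
    return {
        v: fit_alpha(embed_distances, kappas, topo_labels, variant=v) for v in _VARIANTS
    }
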