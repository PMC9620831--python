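"""Neighboring cell-type scores.

For a receiver cell *i* and a neighbor cell type *f*, the raw score is the
sum over every other cell *j* of type *f* of a distance-decay kernel

    x'_{i,f} = sum_{j != i, label_j = f} exp(-d(i, j) / dist0)

where ``dist0`` is the minimum positive pairwise Euclidean distance over the
whole coordinate matrix, setting the decay length scale of the tissue.  The
scores are then z-scored per neighbor type within the rows of each receiver
cell type before entering the regression as explanatory variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborScoreMatrix",
    "min_pairwise_distance",
    "raw_neighbor_scores",
    "zscore_columns",
    "neighbor_scores_for_type",
]


@dataclass
class NeighborScoreMatrix:
    """Raw and z-scored neighbor scores for one receiver cell type."""

    receiver_type: str
    raw: np.ndarray  # (N_m, M)
    scored: np.ndarray  # (N_m, M)
    neighbor_types: list[str]
    dist0: float
    degenerate: np.ndarray  # (M,) bool — zero-variance columns, zeroed out


def min_pairwise_distance(coords: np.ndarray) -> float:
    """Minimum positive Euclidean distance over all unordered cell pairs.

    Zero-distance pairs (duplicated coordinates) are excluded from the
    minimum; if every pair coincides the geometry is degenerate and a
    ``ValueError`` is raised.  Computed once on the full coordinate matrix,
    never per cell type.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least two cells with 2-D coordinates")
    d = pdist(coords)
    positive = d[d > 0]
    if positive.size == 0:
        raise ValueError("all pairwise distances are zero: degenerate geometry")
    if positive.size < d.size:
        logger.warning(
            "%d duplicated coordinate pair(s) excluded from dist0",
            d.size - positive.size,
        )
    return float(positive.min())


def raw_neighbor_scores(
    coords: np.ndarray,
    labels: np.ndarray,
    dist0: float,
    *,
    kernel: str = "exponential",
    cell_types: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Raw neighbor-type scores for every cell.

    Entry ``(i, f)`` sums the kernel over all cells ``j != i`` carrying label
    ``f``; the sum runs over *all* cells regardless of the receiver's own
    type, and the receiver's own type is itself a valid neighbor type.
    Zero-distance pairs contribute ``exp(0) = 1`` (guarded, logged).

    Parameters
    ----------
    kernel:
        ``"exponential"`` for ``exp(-d / dist0)`` (default) or
        ``"gaussian"`` for ``exp(-(d / dist0)**2)``.

    Returns
    -------
    (scores, cell_types)
        ``(N, M)`` raw score matrix and the neighbor-type column order.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if dist0 <= 0:
        raise ValueError("dist0 must be positive")
    n = coords.shape[0]
    if cell_types is None:
        cell_types = sorted(np.unique(labels).tolist())

    D = squareform(pdist(coords))
    if np.any(D[np.triu_indices(n, k=1)] == 0):
        logger.warning("zero-distance cell pairs present; kernel contributes 1.0")
    if kernel == "exponential":
        K = np.exp(-D / dist0)
    elif kernel == "gaussian":
        K = np.exp(-((D / dist0) ** 2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(K, 0.0)  # j != i

    scores = np.empty((n, len(cell_types)))
    for fi, f in enumerate(cell_types):
        scores[:, fi] = K[:, labels == f].sum(axis=1)
    return scores, list(cell_types)


def zscore_columns(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-score; zero-variance columns become all-zero and flagged.

    Returns ``(scored, degenerate)`` where ``degenerate`` marks columns with
    no variance (neighbor type equidistant from all receivers), which must be
    excluded as predictors downstream.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("need at least two rows to z-score")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} neighbor-score column(s) have zero "
            "variance and are zeroed out",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scored = (raw - mean) / sd
    scored[:, degenerate] = 0.0
    return scored, degenerate


def neighbor_scores_for_type(
    coords: np.ndarray,
    labels: np.ndarray,
    receiver_type: str,
    *,
    dist0: float | None = None,
    kernel: str = "exponential",
    cell_types: list[str] | None = None,
) -> NeighborScoreMatrix:
    """Full Step-(ii) pipeline for one receiver cell type.

    ``dist0`` defaults to the minimum pairwise distance of the full
    coordinate matrix; the z-score is taken within the receiver type's rows.
    """
    labels = np.asarray(labels)
    if dist0 is None:
        dist0 = min_pairwise_distance(coords)
    raw_all, types = raw_neighbor_scores(
        coords, labels, dist0, kernel=kernel, cell_types=cell_types
    )
    rows = labels == receiver_type
    if rows.sum() < 2:
        raise ValueError(
            f"receiver type {receiver_type!r} has fewer than 2 cells"
        )
    raw = raw_all[rows]
    scored, degenerate = zscore_columns(raw)
    return NeighborScoreMatrix(
        receiver_type=receiver_type,
        raw=raw,
        scored=scored,
        neighbor_types=types,
        dist0=float(dist0),
        degenerate=degenerate,
    )
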