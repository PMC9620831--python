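"""Per-cell-type expression preprocessing and highly variable gene selection.

The pipeline splits the expression matrix by cell-type label, drops genes
that are zero in every cell of the type, normalises (per-cell scaling to the
median library size followed by log1p), z-scores each gene, and extracts the
cell-type-specific HVG set that the regression models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeExpression",
    "split_by_cell_type",
    "drop_all_zero_genes",
    "normalize_log_zscore",
    "select_hvgs",
    "hvg_overlap_ratio",
    "prepare_cell_type",
]


@dataclass
class CellTypeExpression:
    """Processed expression block for one receiver cell type."""

    cell_type: str
    cell_ids: list[str]
    raw: pd.DataFrame  # N(m) x G' after the zero filter
    processed: pd.DataFrame  # N(m) x H z-scored HVG matrix
    hvg_ids: list[str]


def split_by_cell_type(
    expression: pd.DataFrame, labels: pd.Series
) -> dict[str, pd.DataFrame]:
    """Partition the cells-by-genes matrix into one block per label value.

    The blocks cover all cells with no overlap; the union of row counts
    equals the input row count.
    """
    labels = labels.reindex(expression.index)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    return {
        str(m): expression.loc[labels == m]
        for m in sorted(labels.unique().astype(str))
    }


def drop_all_zero_genes(mat: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero expression in every cell of this type.

    Column order is preserved. An empty result signals the cell type should
    be skipped (handled by the caller, not fatal).
    """
    if (mat.values < 0).any():
        raise ValueError("expression values must be non-negative")
    keep = (mat.values > 0).any(axis=0)
    return mat.loc[:, keep]


def normalize_log_zscore(
    mat: pd.DataFrame, *, normalize: str = "median_log1p"
) -> pd.DataFrame:
    """Normalise and z-score a zero-filtered expression block.

    ``median_log1p`` scales each cell to the median per-cell total count,
    applies ``log(1 + x)``, then z-scores each gene; ``none`` only z-scores
    (for data already on a processed scale).  Genes that are constant after
    transformation carry no signal and are dropped with a warning.
    """
    X = mat.values.astype(float)
    if normalize == "median_log1p":
        totals = X.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cells with zero total count cannot be scaled")
        X = np.log1p(X * (np.median(totals) / totals)[:, None])
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "dropping %d constant gene(s) after transform in z-scoring",
            int(constant.sum()),
        )
    X = (X[:, ~constant] - X[:, ~constant].mean(axis=0)) / sd[~constant]
    return pd.DataFrame(X, index=mat.index, columns=mat.columns[~constant])


def select_hvgs(
    mat: pd.DataFrame,
    *,
    method: str = "cv_residual",
    quantile: float = 0.90,
    top_n: int | None = None,
) -> list[str]:
    """Select highly variable genes from a raw (count-scale) block.

    ``cv_residual`` regresses log CV^2 on log mean across genes and selects
    genes whose residual exceeds the given quantile — genes more variable
    than their expression level predicts.  ``top_n`` simply takes the *n*
    genes with the highest CV^2.  Both are deterministic.
    """
    if mat.shape[1] < 2 or mat.shape[0] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells for HVG selection")
    X = mat.values.astype(float)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    ok = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(ok, var / mean**2, 0.0)

    if method == "top_n":
        if top_n is None:
            raise ValueError("top_n method requires a gene count")
        order = np.argsort(-cv2, kind="stable")[: int(top_n)]
        keep = np.zeros(mat.shape[1], dtype=bool)
        keep[order] = True
        return mat.columns[keep].tolist()
    if method != "cv_residual":
        raise ValueError(f"unknown HVG method {method!r}")

    usable = ok & (cv2 > 0)
    logm = np.log(mean[usable])
    logcv2 = np.log(cv2[usable])
    slope, intercept = np.polyfit(logm, logcv2, 1)
    resid = logcv2 - (slope * logm + intercept)
    cut = np.quantile(resid, quantile)
    keep = np.zeros(mat.shape[1], dtype=bool)
    keep[np.flatnonzero(usable)[resid > cut]] = True
    return mat.columns[keep].tolist()


def hvg_overlap_ratio(hvg_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise HVG overlap between cell types.

    Entry ``(a, b)`` is ``|HVG(a) & HVG(b)| / min(|HVG(a)|, |HVG(b)|)``,
    the overlap normalised by the smaller set; diagonal entries are 1.
    """
    types = list(hvg_sets)
    sets = {t: set(v) for t, v in hvg_sets.items()}
    out = pd.DataFrame(np.ones((len(types), len(types))), index=types, columns=types)
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            denom = min(len(sets[a]), len(sets[b]))
            r = len(sets[a] & sets[b]) / denom if denom else np.nan
            out.loc[a, b] = out.loc[b, a] = r
    return out


def prepare_cell_type(
    cell_type: str,
    raw_block: pd.DataFrame,
    *,
    normalize: str = "median_log1p",
    hvg_method: str = "cv_residual",
    hvg_quantile: float = 0.90,
    hvg_top_n: int | None = None,
    min_hvgs: int = 1,
) -> CellTypeExpression | str:
    """Full Step-(i) pipeline for one cell type.

    Returns a :class:`CellTypeExpression`, or a string reason when the cell
    type must be skipped (all genes zero, or too few HVGs survive).
    ``hvg_method='all'`` bypasses selection and treats every surviving gene
    as an HVG — the path for data simulated directly on the processed scale.
    """
    if normalize == "center":
        # already processed scale (may be negative): zero filter not meaningful
        filtered = raw_block
    else:
        filtered = drop_all_zero_genes(raw_block)
    if filtered.shape[1] == 0:
        return "all genes zero within cell type"
    if hvg_method == "all":
        hvgs = filtered.columns.tolist()
    else:
        try:
            hvgs = select_hvgs(
                filtered,
                method=hvg_method,
                quantile=hvg_quantile,
                top_n=hvg_top_n,
            )
        except ValueError as exc:
            return f"HVG selection failed: {exc}"
    if len(hvgs) < max(min_hvgs, 1):
        return f"only {len(hvgs)} HVGs survive (floor {min_hvgs})"
    if normalize == "center":
        # data already on processed scale: center columns without rescaling
        sub = filtered[hvgs].astype(float)
        processed = sub - sub.mean(axis=0)
    else:
        processed = normalize_log_zscore(filtered[hvgs], normalize=normalize)
    if processed.shape[1] < max(min_hvgs, 1):
        return "too few non-constant HVGs after normalization"
    return CellTypeExpression(
        cell_type=cell_type,
        cell_ids=raw_block.index.tolist(),
        raw=filtered,
        processed=processed,
        hvg_ids=processed.columns.tolist(),
    )
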