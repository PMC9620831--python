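"""Two-step statistical filtering of PLS coefficients.

Step 1 tests, for every (gene, component) pair, the factor loading — the
Pearson correlation between the gene's expression and the component score —
with a t-test; per-component coefficients of non-significant pairs are
zeroed before summation.  Step 2 tests the surviving summed coefficients
against a permutation null built by shuffling the rows of the neighbor-score
matrix (breaking each cell's link to its own neighborhood) and refitting the
model at the already-selected component count.  Both steps control the false
discovery rate by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pls import PLSFit, fit_pls

__all__ = [
    "FilteredCoefficients",
    "bh_adjust",
    "loading_significance_test",
    "coefficient_significance_test",
    "filter_coefficients",
]


@dataclass
class FilteredCoefficients:
    """Coefficients surviving the two-step FDR filter (zeros elsewhere)."""

    W_filtered: np.ndarray  # (L, H)
    step1_q: np.ndarray  # (H, C)
    step1_mask: np.ndarray  # (H, C) bool, True = retained
    step2_q: np.ndarray  # (L, H)
    step2_mask: np.ndarray  # (L, H) bool
    alpha1: float
    alpha2: float


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    return multipletests(flat, method="fdr_bh")[1].reshape(p.shape)


def loading_significance_test(
    fit: PLSFit, Y: np.ndarray, *, alpha1: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: t-test of factor loadings with BH adjustment.

    The factor loading of gene ``h`` on component ``c`` is the Pearson
    correlation between ``Y[:, h]`` and the score ``t_c``; its null
    distribution gives the statistic ``r * sqrt((n-2) / (1-r^2))`` with
    ``n-2`` degrees of freedom.  Returns the ``(H, C)`` q-matrix and the
    boolean retained mask (``q < alpha1``).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 cells for the loading t-test")
    Yc = Y - Y.mean(axis=0)
    y_sd = Yc.std(axis=0, ddof=0)
    Tc = fit.T - fit.T.mean(axis=0)
    t_sd = Tc.std(axis=0, ddof=0)
    denom = np.outer(y_sd, t_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc.T @ Tc) / (n * denom)
    r = np.where(denom == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(
        np.isfinite(tstat), 2.0 * stats.t.sf(np.abs(tstat), df=n - 2), 0.0
    )
    q = bh_adjust(p)
    return q, q < alpha1


def coefficient_significance_test(
    W_candidate: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    *,
    n_perm: int = 999,
    seed: int | None = None,
    alpha2: float = 0.05,
    return_null: bool = False,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step 2: permutation test of the summed coefficients.

    For each permutation round the rows of ``X`` are shuffled, the model is
    refit at the fixed component count, and the summed coefficients are
    recorded.  The two-sided p-value for entry ``(f, h)`` is
    ``(1 + #{|w_perm| >= |w_obs|}) / (1 + n_perm)``, BH-adjusted across all
    entries; the retained mask is ``q < alpha2``.  With ``return_null`` the
    stacked ``(n_perm, L, H)`` null coefficients are returned as well, so
    the counting rule can be audited against the recorded permutations.
    """
    if n_perm < 99:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution (min "
            f"{1 / (1 + n_perm):.3g})",
            stacklevel=2,
        )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(W_candidate)
    exceed = np.zeros_like(abs_obs, dtype=np.int64)
    n = X.shape[0]
    null_stack = np.empty((n_perm, *abs_obs.shape)) if return_null else None
    for i in range(n_perm):
        Xp = X[rng.permutation(n)]
        Xp = Xp - Xp.mean(axis=0)
        try:
            perm_fit = fit_pls(Xp, Y, n_components, check_centered=False)
            w_perm = perm_fit.W_sum
        except Exception:
            # degenerate permutation: coefficients undefined, count as tie
            w_perm = np.full_like(abs_obs, np.inf)
        exceed += np.abs(w_perm) >= abs_obs
        if return_null:
            null_stack[i] = w_perm
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = bh_adjust(p)
    if return_null:
        return q, q < alpha2, null_stack
    return q, q < alpha2


def filter_coefficients(
    fit: PLSFit,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    step1_scope: str = "gene",
) -> FilteredCoefficients:
    """Run both filtering steps and assemble the final coefficient matrix.

    An entry of ``W_filtered`` is nonzero only when its gene passed the
    loading test for at least one component *and* the (type, gene) pair
    passed the permutation test; all other entries are exactly zero.

    ``step1_scope`` controls how the loading test acts on the coefficients.
    With ``"gene"`` (default) a gene significant on at least one component
    keeps its full summed coefficient; with ``"component"`` the
    per-component increments of non-significant (gene, component) pairs
    are zeroed before summation.  The gene scope keeps surviving
    coefficients unbiased — component-wise zeroing clips real but
    individually sub-threshold contributions, which visibly distorts
    coefficient blocks when the receiver type has few cells — while the
    component scope prunes more aggressively.
    """
    step1_q, step1_mask = loading_significance_test(fit, Y, alpha1=alpha1)
    if step1_scope == "gene":
        gene_keep = step1_mask.any(axis=1).astype(float)  # (H,)
        W_candidate = fit.W_sum * gene_keep[None, :]
    elif step1_scope == "component":
        W_candidate = np.einsum(
            "lhc,hc->lh", fit.W_comp, step1_mask.astype(float)
        )
    else:
        raise ValueError(f"unknown step1_scope {step1_scope!r}")
    step2_q, step2_mask = coefficient_significance_test(
        W_candidate, X, Y, fit.n_components,
        n_perm=n_perm, seed=seed, alpha2=alpha2,
    )
    W_filtered = np.where(step2_mask, W_candidate, 0.0)
    return FilteredCoefficients(
        W_filtered=W_filtered,
        step1_q=step1_q,
        step1_mask=step1_mask,
        step2_q=step2_q,
        step2_mask=step2_mask,
        alpha1=alpha1,
        alpha2=alpha2,
    )
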