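"""Recovery evaluation against simulated ground truth.

Estimated HVG clusters are matched one-to-one to the planted clusters by
maximum total overlap (Hungarian assignment on the contingency table);
estimated clusters left unmatched, and genes reported in no cluster, map to
"others".  Ten indexes summarise a run: the adjusted Rand index over all
genes, the Pearson correlation between estimated and true coefficients over
every (neighbor type, gene) pair, and precision and recall of each planted
cluster (including "others").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from .pipeline import CellTypeResult, RunResult
from .simulate import SimulatedTruth

__all__ = ["EvaluationReport", "match_clusters", "evaluate_recovery", "OTHERS"]

OTHERS = "others"


@dataclass
class EvaluationReport:
    """Cluster mapping plus the ten performance indexes."""

    mapping: dict  # estimated cluster id -> "1"/"2"/... or "others"
    ari: float
    pearson_r: float
    precision: dict[str, float | None]  # per planted cluster; None = undefined
    recall: dict[str, float | None]
    vp: float | None = None

    def indexes(self) -> dict[str, float | None]:
        out = {"ARI": self.ari, "pearson_r": self.pearson_r}
        for q in self.precision:
            out[f"precision_{q}"] = self.precision[q]
        for q in self.recall:
            out[f"recall_{q}"] = self.recall[q]
        return out

    def min_index(self) -> float:
        vals = [v for v in self.indexes().values() if v is not None]
        return float(min(vals))


def match_clusters(
    est_labels: pd.Series, true_labels: pd.Series, *, n_signal_clusters: int = 3
) -> dict:
    """Assign estimated clusters to planted signal clusters 1..n.

    ``est_labels`` holds the estimated cluster id per reported gene (genes
    missing from its index are treated as unreported); ``true_labels`` holds
    the planted cluster per gene, with the unaffected cluster being any id
    above ``n_signal_clusters``.  The assignment maximises total overlap;
    the maximum is exact (Hungarian algorithm on the negated contingency
    table).  Unmatched estimated clusters map to ``"others"``.
    """
    est_ids = sorted(pd.unique(est_labels).tolist())
    signal = [str(q) for q in range(1, n_signal_clusters + 1)]
    cont = np.zeros((len(est_ids), len(signal)))
    for i, e in enumerate(est_ids):
        genes_e = est_labels.index[est_labels == e]
        tl = true_labels.loc[genes_e]
        for j, q in enumerate(signal):
            cont[i, j] = int((tl.astype(str) == q).sum())
    rows, cols = linear_sum_assignment(-cont)
    mapping = {e: OTHERS for e in est_ids}
    for i, j in zip(rows, cols):
        if cont[i, j] > 0:
            mapping[est_ids[i]] = signal[j]
    return mapping


def _extract_estimates(
    run: RunResult | CellTypeResult, cell_type: str | None
) -> CellTypeResult:
    if not hasattr(run, "results"):
        # anything exposing .coefficients and .cluster_table is acceptable
        return run
    if cell_type is None:
        if len(run.results) != 1:
            raise ValueError("specify cell_type when several types were run")
        cell_type = next(iter(run.results))
    if cell_type not in run.results:
        raise ValueError(f"no results for cell type {cell_type!r} "
                         f"(skipped: {run.skipped.get(cell_type)})")
    return run.results[cell_type]


def evaluate_recovery(
    run: RunResult | CellTypeResult,
    truth: SimulatedTruth,
    *,
    cell_type: str | None = None,
    n_signal_clusters: int = 3,
) -> EvaluationReport:
    """Compute the ten recovery indexes for one receiver cell type.

    Unreported genes count as members of "others" on the estimated side;
    their estimated coefficients contribute zeros to the Pearson
    correlation.  An empty estimated cluster leaves that cluster's
    precision undefined (``None``), never zero.
    """
    res = _extract_estimates(run, cell_type)
    genes = truth.W_true.columns.tolist()
    true_num = truth.cluster_labels.loc[genes].astype(int)
    true_lab = true_num.astype(str).where(
        true_num <= n_signal_clusters, OTHERS
    )

    ct = res.cluster_table.set_index("gene")["cluster"] if len(
        res.cluster_table
    ) else pd.Series(dtype=int)
    ct = ct[ct.index.isin(genes)]
    mapping = match_clusters(ct, true_num, n_signal_clusters=n_signal_clusters) \
        if len(ct) else {}
    est_lab = pd.Series(OTHERS, index=genes)
    if len(ct):
        est_lab.loc[ct.index] = ct.map(mapping).values

    ari = float(adjusted_rand_score(true_lab.values, est_lab.values))

    # coefficients: align estimated matrix onto the truth's (type, gene) grid
    W_est = pd.DataFrame(
        0.0, index=truth.W_true.index, columns=truth.W_true.columns
    )
    common_t = [t for t in res.coefficients.index if t in W_est.index]
    common_g = [g for g in res.coefficients.columns if g in W_est.columns]
    W_est.loc[common_t, common_g] = res.coefficients.loc[common_t, common_g]
    r = float(pearsonr(W_est.values.ravel(), truth.W_true.values.ravel())[0])

    classes = [str(q) for q in range(1, n_signal_clusters + 1)] + [OTHERS]
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for q in classes:
        est_q = est_lab == q
        true_q = true_lab == q
        inter = int((est_q & true_q).sum())
        precision[q] = inter / int(est_q.sum()) if est_q.any() else None
        recall[q] = inter / int(true_q.sum()) if true_q.any() else None

    return EvaluationReport(
        mapping=mapping,
        ari=ari,
        pearson_r=r,
        precision=precision,
        recall=recall,
        vp=truth.vp,
    )
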