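"""End-to-end pipeline orchestrator.

For each receiver cell type the six steps run in order: HVG extraction,
neighbor-score computation, PLS regression with CV-selected component
count, two-step coefficient filtering, HVG clustering, and report-table
construction.  Failures or guard conditions are recorded per cell type and
never abort the other types.  A single run seed is split deterministically
into per-type, per-step substreams so repeated runs are bitwise identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (
    ContributorMap,
    HVGClustering,
    assign_contributors,
    build_report,
    cluster_hvgs,
)
from .config import Config
from .datasets import SpatialDataset
from .filtering import FilteredCoefficients, filter_coefficients
from .neighbor import min_pairwise_distance, neighbor_scores_for_type
from .pls import CVSelection, PLSFit, fit_pls, select_num_components
from .preprocess import prepare_cell_type, split_by_cell_type

logger = logging.getLogger(__name__)

__all__ = ["CellTypeResult", "RunResult", "run_ccpls", "write_run_result"]


@dataclass
class CellTypeResult:
    """Pipeline outputs for one receiver cell type."""

    cell_type: str
    hvg_ids: list[str]
    neighbor_types: list[str]
    cv: CVSelection
    fit: PLSFit
    filtered: FilteredCoefficients
    coefficients: pd.DataFrame  # M x H filtered coefficients (zeros kept)
    clustering: HVGClustering | None
    contributors: ContributorMap | None
    heatmap: pd.DataFrame | None
    edges: pd.DataFrame | None
    log: dict = field(default_factory=dict)

    @property
    def reported_genes(self) -> list[str]:
        """HVGs with at least one surviving (nonzero) coefficient."""
        return [] if self.clustering is None else self.clustering.gene_ids

    @property
    def cluster_table(self) -> pd.DataFrame:
        if self.clustering is None:
            return pd.DataFrame(columns=["gene", "cluster"])
        return pd.DataFrame(
            {"gene": self.clustering.gene_ids, "cluster": self.clustering.labels}
        )


@dataclass
class RunResult:
    """Per-cell-type results plus run metadata."""

    results: dict[str, CellTypeResult]
    skipped: dict[str, str]  # cell type -> reason
    seed: int
    config: Config
    dist0: float
    log: list[dict] = field(default_factory=list)

    @property
    def attempted(self) -> list[str]:
        return sorted(set(self.results) | set(self.skipped))


def _step_seeds(seed: int, type_index: int) -> dict[str, int]:
    ss = np.random.SeedSequence([int(seed), int(type_index)])
    cv, perm, km = (int(s) % (2**31 - 1) for s in ss.generate_state(3))
    return {"cv": cv, "perm": perm, "kmeans": km}


def run_ccpls(ds: SpatialDataset, config: Config | None = None) -> RunResult:
    """Run the full pipeline on every (requested) receiver cell type."""
    config = config or Config()
    all_types = ds.cell_types
    wanted = config.cell_types or all_types
    unknown = [t for t in wanted if t not in all_types]
    if unknown:
        raise ValueError(f"requested cell types not in dataset: {unknown}")

    if config.dist0 == "auto_min":
        dist0 = min_pairwise_distance(ds.coordinates.values)
    else:
        dist0 = float(config.dist0)

    labels = ds.labels.astype(str)
    blocks = split_by_cell_type(ds.expression, labels)
    results: dict[str, CellTypeResult] = {}
    skipped: dict[str, str] = {}
    run_log: list[dict] = []

    for m in wanted:
        t_start = time.perf_counter()
        seeds = _step_seeds(config.seed, all_types.index(m))
        entry: dict = {"cell_type": m, "n_cells": int(len(blocks[m]))}
        try:
            res = _run_one_type(
                m, blocks[m], ds, labels, dist0, config, seeds, entry
            )
        except Exception as exc:  # captured per cell type, never fatal
            logger.exception("cell type %s failed", m)
            skipped[m] = f"error: {exc}"
            entry["status"] = "error"
            entry["reason"] = str(exc)
        else:
            if isinstance(res, str):
                skipped[m] = res
                entry["status"] = "skipped"
                entry["reason"] = res
                logger.info("skipping cell type %s: %s", m, res)
            else:
                results[m] = res
                entry["status"] = "ok"
        entry["seconds"] = round(time.perf_counter() - t_start, 3)
        run_log.append(entry)

    return RunResult(
        results=results,
        skipped=skipped,
        seed=config.seed,
        config=config,
        dist0=float(dist0),
        log=run_log,
    )


def _run_one_type(
    m: str,
    block: pd.DataFrame,
    ds: SpatialDataset,
    labels: pd.Series,
    dist0: float,
    config: Config,
    seeds: dict[str, int],
    entry: dict,
) -> CellTypeResult | str:
    n_m = len(block)
    if n_m < config.min_cells:
        return f"{n_m} cells below minimum {config.min_cells}"

    # Step (i): preprocessing and HVG extraction
    prep = prepare_cell_type(
        m,
        block,
        normalize=config.normalize,
        hvg_method=config.hvg.method,
        hvg_quantile=config.hvg.quantile,
        hvg_top_n=config.hvg.top_n,
        min_hvgs=config.hvg.min_hvgs,
    )
    if isinstance(prep, str):
        return prep
    Y = prep.processed.values
    if n_m <= 2:
        return "too few cells for the loading test"
    entry["n_hvgs"] = len(prep.hvg_ids)

    # Step (ii): neighbor scores, z-scored within the receiver type
    nbr = neighbor_scores_for_type(
        ds.coordinates.values,
        labels.values,
        m,
        dist0=dist0,
        kernel=config.kernel,
        cell_types=ds.cell_types,
    )
    usable = ~nbr.degenerate
    if not usable.any():
        return "all neighbor-score columns degenerate"
    X = nbr.scored[:, usable]

    # Step (iii): PLS with CV-selected component count
    cv = select_num_components(
        X, Y,
        folds=config.pls.folds,
        c_max=config.pls.c_max,
        seed=seeds["cv"],
    )
    fit = fit_pls(X, Y, cv.chosen, check_centered=False)
    entry["n_components"] = cv.chosen

    # Step (iv): two-step filtering
    filt = filter_coefficients(
        fit, X, Y,
        alpha1=config.filter.alpha1,
        alpha2=config.filter.alpha2,
        n_perm=config.filter.n_perm,
        seed=seeds["perm"],
        step1_scope=config.filter.step1_scope,
    )
    # expand back to all M neighbor types (zeros for degenerate columns)
    W_full = np.zeros((len(nbr.neighbor_types), Y.shape[1]))
    W_full[np.flatnonzero(usable)] = filt.W_filtered
    coefficients = pd.DataFrame(
        W_full, index=nbr.neighbor_types, columns=prep.hvg_ids
    )
    entry["n_reported_genes"] = int((W_full != 0).any(axis=0).sum())

    # Steps (v)-(vi): clustering and report
    clustering = cluster_hvgs(
        W_full,
        prep.hvg_ids,
        nbr.neighbor_types,
        kmin=config.cluster.kmin,
        kmax=config.cluster.kmax,
        n_restarts=config.cluster.n_restarts,
        seed=seeds["kmeans"],
    )
    contributors = heat = edges = None
    if clustering is not None:
        contributors = assign_contributors(
            clustering, W_full, prep.hvg_ids,
            support_threshold=config.cluster.support_threshold,
        )
        heat, edges = build_report(clustering, W_full, prep.hvg_ids)
        entry["k"] = clustering.k

    return CellTypeResult(
        cell_type=m,
        hvg_ids=prep.hvg_ids,
        neighbor_types=nbr.neighbor_types,
        cv=cv,
        fit=fit,
        filtered=filt,
        coefficients=coefficients,
        clustering=clustering,
        contributors=contributors,
        heatmap=heat,
        edges=edges,
        log=dict(entry),
    )


def write_run_result(run: RunResult, out_dir: str | Path) -> Path:
    """Serialise a run: per-type TSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m, res in run.results.items():
        d = out / f"cell_type_{m}"
        d.mkdir(exist_ok=True)
        res.coefficients.to_csv(d / "coefficients.tsv", sep="\t",
                                index_label="neighbor_type")
        res.cluster_table.to_csv(d / "clusters.tsv", sep="\t", index=False)
        if res.edges is not None:
            res.edges.to_csv(d / "bipartite_edges.tsv", sep="\t", index=False)
        if res.heatmap is not None:
            res.heatmap.to_csv(d / "heatmap.tsv", sep="\t",
                               index_label="neighbor_type")
    summary = {
        "seed": run.seed,
        "dist0": run.dist0,
        "config": run.config.to_dict(),
        "skipped": run.skipped,
        "completed": sorted(run.results),
        "log": run.log,
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return out
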