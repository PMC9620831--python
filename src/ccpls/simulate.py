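"""Simulated spatial transcriptome datasets with planted neighbor effects.

The generator emulates a single-cell-resolution tissue: cells are scattered
on a square with a minimum-separation rule (cell bodies cannot overlap),
labels are drawn i.i.d. over the cell types, and processed-scale expression
is built directly as

    y_{i,h} = sum_f x_{i,f} w_{f,h} + alpha * e_{i,h}

where x are z-scored neighbor-type scores, W carries the planted coefficient
block pattern (four gene clusters: a two-input cluster, two one-input
clusters and an unaffected cluster), and the noise is either Gaussian with
per-gene standard deviations from a mean-CV dispersion curve, or gamma-
derived (log-scaled and z-scored per gene).  No count sampling is performed;
the data are simulated on the processed scale throughout.

The variance proportion VP — the fraction of an affected gene's variance
explained by the planted model term — quantifies how hard a configuration
is: low VP means neighbor effects are buried in noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SpatialDataset
from .neighbor import min_pairwise_distance, raw_neighbor_scores, zscore_columns

__all__ = [
    "SimulationSpec",
    "SimulatedTruth",
    "generate_coordinates",
    "simulate_expression",
    "simulate_dataset",
    "compute_vp",
    "DEFAULT_COEFFICIENT_PATTERN",
]

# planted block pattern: rows = cell types A-D, columns = gene clusters 1-4.
# Cluster 1 is the multiple-input case (types A and C), clusters 2 and 3 are
# single-input (B and C), cluster 4 is unaffected.
DEFAULT_COEFFICIENT_PATTERN = np.array(
    [
        [1, 0, 0, 0],
        [0, 1, 0, 0],
        [1, 0, 1, 0],
        [0, 0, 0, 0],
    ],
    dtype=float,
)


@dataclass
class SimulationSpec:
    """Configuration of one simulated dataset."""

    n_cells: int = 523
    n_types: int = 4
    genes_per_cluster: int = 500
    w_max: float = 1.0
    alpha: float = 1.0
    noise_model: str = "gaussian"  # or "gamma"
    coefficient_pattern: np.ndarray = field(
        default_factory=lambda: DEFAULT_COEFFICIENT_PATTERN.copy()
    )
    # mean-CV dispersion curve CV^2 = a / mu + b; gene means are log-normal
    sigma_a: float = 1.0
    sigma_b: float = 0.1
    mean_log_mu: float = 1.0
    mean_log_sd: float = 0.5
    # gamma-noise parameters
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    # geometry
    coordinate_mode: str = "uniform"  # or "provided"
    min_separation: float = 0.5
    kernel: str = "exponential"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coefficient_pattern = np.asarray(self.coefficient_pattern, float)
        if self.coefficient_pattern.shape[0] != self.n_types:
            raise ValueError("coefficient pattern rows must equal n_types")
        if not np.isin(self.coefficient_pattern, [0.0, 1.0]).all():
            raise ValueError("coefficient pattern entries must be 0 or 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.genes_per_cluster < 1:
            raise ValueError("genes_per_cluster must be >= 1")

    @property
    def n_clusters(self) -> int:
        return self.coefficient_pattern.shape[1]

    @property
    def type_names(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_types)]


@dataclass
class SimulatedTruth:
    """Ground truth accompanying one simulated dataset."""

    W_true: pd.DataFrame  # types x genes
    cluster_labels: pd.Series  # gene -> predefined cluster 1..n_clusters
    sigma: pd.Series  # per-gene noise sd (before alpha)
    noise: np.ndarray  # realized N x G noise matrix (before alpha)
    alpha: float
    vp: float
    scores: dict[str, pd.DataFrame]  # receiver type -> z-scored X(m)


def generate_coordinates(
    n_cells: int,
    *,
    n_types: int = 4,
    mode: str = "uniform",
    min_separation: float = 0.5,
    type_frequencies: np.ndarray | None = None,
    seed: int | None = None,
    coords: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    max_attempts_factor: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell coordinates and labels for a simulated tissue.

    ``uniform`` scatters points on a square of side ``sqrt(n_cells)`` (unit
    mean density) by dart-throwing, rejecting any point closer than
    ``min_separation`` to an accepted one, so no two cells overlap and the
    minimum pairwise distance — the kernel's decay scale — is of the same
    order as the typical cell spacing, as in packed tissue.  Labels are
    drawn i.i.d. with the given type frequencies (equal by default).
    ``provided`` passes through user coordinates and labels.
    """
    if mode == "provided":
        if coords is None or labels is None:
            raise ValueError("provided mode requires coords and labels")
        return np.asarray(coords, float), np.asarray(labels)
    if mode != "uniform":
        raise ValueError(f"unknown coordinate mode {mode!r}")
    if n_cells < 2 * n_types:
        raise ValueError("need at least 2 cells per type")

    rng = np.random.default_rng(seed)
    side = float(np.sqrt(n_cells))
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_cells
    while len(pts) < n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                "rejection sampling failed: lower min_separation or density"
            )
        cand = rng.uniform(0.0, side, size=2)
        attempts += 1
        if pts:
            arr = np.asarray(pts)
            if np.min(np.sum((arr - cand) ** 2, axis=1)) < min_separation**2:
                continue
        pts.append(cand)
    coords_out = np.asarray(pts)

    if type_frequencies is None:
        type_frequencies = np.full(n_types, 1.0 / n_types)
    type_names = [chr(ord("A") + i) for i in range(n_types)]
    labels_out = rng.choice(type_names, size=n_cells, p=type_frequencies)
    # guarantee every type occurs (i.i.d. draws may miss one at small n)
    for i, t in enumerate(type_names):
        if t not in labels_out:
            labels_out[rng.integers(n_cells)] = t
    return coords_out, labels_out


def _per_type_scores(
    coords: np.ndarray,
    labels: np.ndarray,
    type_names: list[str],
    kernel: str,
) -> tuple[np.ndarray, dict[str, pd.DataFrame], float]:
    """Assemble the N x M z-scored score matrix, z-scoring within each
    receiver type's rows (each cell's row uses its own type's statistics)."""
    dist0 = min_pairwise_distance(coords)
    raw, _ = raw_neighbor_scores(
        coords, labels, dist0, kernel=kernel, cell_types=type_names
    )
    X = np.zeros_like(raw)
    per_type: dict[str, pd.DataFrame] = {}
    for m in type_names:
        rows = labels == m
        scored, _ = zscore_columns(raw[rows])
        X[rows] = scored
        per_type[m] = pd.DataFrame(scored, columns=type_names)
    return X, per_type, dist0


def simulate_expression(
    spec: SimulationSpec,
    coords: np.ndarray,
    labels: np.ndarray,
) -> tuple[SpatialDataset, SimulatedTruth]:
    """Simulate processed-scale expression on the given geometry."""
    rng = np.random.default_rng(spec.seed)
    type_names = spec.type_names
    n = coords.shape[0]
    G = spec.n_clusters * spec.genes_per_cluster

    X, per_type, _ = _per_type_scores(coords, labels, type_names, spec.kernel)

    gene_ids = [f"gene_{g + 1}" for g in range(G)]
    cluster_labels = np.repeat(
        np.arange(1, spec.n_clusters + 1), spec.genes_per_cluster
    )
    W = spec.w_max * spec.coefficient_pattern[:, cluster_labels - 1]  # M x G

    if spec.noise_model == "gaussian":
        mu = rng.lognormal(spec.mean_log_mu, spec.mean_log_sd, size=G)
        sigma = np.sqrt(spec.sigma_a / mu + spec.sigma_b)
        E = rng.normal(size=(n, G)) * sigma
    elif spec.noise_model == "gamma":
        raw = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=(n, G))
        lg = np.log(raw)
        E = (lg - lg.mean(axis=0)) / lg.std(axis=0, ddof=0)
        sigma = np.ones(G)
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")

    model_term = X @ W
    Y = model_term + spec.alpha * E

    cell_ids = [f"cell_{i + 1}" for i in range(n)]
    ds = SpatialDataset(
        expression=pd.DataFrame(Y, index=cell_ids, columns=gene_ids),
        coordinates=pd.DataFrame(coords, index=cell_ids, columns=["x", "y"]),
        labels=pd.Series(labels, index=cell_ids, name="cell_type"),
        allow_negative=True,  # processed-scale values
    )
    truth = SimulatedTruth(
        W_true=pd.DataFrame(W, index=type_names, columns=gene_ids),
        cluster_labels=pd.Series(cluster_labels, index=gene_ids, name="cluster"),
        sigma=pd.Series(sigma, index=gene_ids, name="sigma"),
        noise=E,
        alpha=spec.alpha,
        vp=np.nan,
        scores=per_type,
    )
    if (W != 0).any():
        truth.vp = compute_vp(truth, X, Y)
    return ds, truth


def simulate_dataset(spec: SimulationSpec) -> tuple[SpatialDataset, SimulatedTruth]:
    """Generate geometry and expression in one call (seeded end to end)."""
    geo_seed = None if spec.seed is None else spec.seed + 104729
    coords, labels = generate_coordinates(
        spec.n_cells,
        n_types=spec.n_types,
        mode=spec.coordinate_mode,
        min_separation=spec.min_separation,
        seed=geo_seed,
    )
    return simulate_expression(spec, coords, labels)


def compute_vp(truth: SimulatedTruth, X: np.ndarray, Y: np.ndarray) -> float:
    """Variance proportion of the planted model term.

    For each affected gene (true coefficients not all zero),
    ``vp_h = Var_i(sum_f x_{i,f} w_{f,h}) / Var_i(y_{i,h})``; VP is the mean
    over affected genes.  Raises when no gene is affected.
    """
    W = truth.W_true.values
    affected = (W != 0).any(axis=0)
    if not affected.any():
        raise ValueError("VP undefined: no gene has a nonzero true coefficient")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    model = X @ W[:, affected]
    vp_h = model.var(axis=0, ddof=0) / Y[:, affected].var(axis=0, ddof=0)
    return float(vp_h.mean())
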