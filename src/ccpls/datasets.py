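"""Spatial transcriptome dataset container and file IO.

A dataset at single-cell resolution is the triple of an expression matrix
(cells x genes), a 2-D coordinate table and a cell-type label table, joined
on a shared cell identifier.  Expression is read either from a dense
CSV/TSV (first column ``cell_id``, header row of gene ids) or from a
MatrixMarket sparse file with gene/cell id sidecars; coordinates and labels
are CSV/TSV with ``cell_id,x,y`` and ``cell_id,cell_type`` headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["SpatialDataset", "load_dataset", "write_dataset"]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".txt"} else ","


@dataclass
class SpatialDataset:
    """Validated spatial transcriptome dataset.

    Rows of ``expression``, ``coordinates`` and ``labels`` share one index
    of unique cell ids in identical order.
    """

    expression: pd.DataFrame
    coordinates: pd.DataFrame
    labels: pd.Series
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- properties ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.labels.astype(str).unique().tolist())

    @property
    def cell_ids(self) -> list[str]:
        return self.expression.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.columns.tolist()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        expr, coords, labels = self.expression, self.coordinates, self.labels
        if not (len(expr) == len(coords) == len(labels)):
            raise ValueError(
                f"row counts differ: expression {len(expr)}, "
                f"coordinates {len(coords)}, labels {len(labels)}"
            )
        if not (expr.index.equals(coords.index) and expr.index.equals(labels.index)):
            raise ValueError("cell id order differs between fields")
        if expr.index.has_duplicates:
            dup = expr.index[expr.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicated cell ids: {dup}")
        if expr.columns.has_duplicates:
            dup = expr.columns[expr.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicated gene ids: {dup}")
        if coords.shape[1] != 2:
            raise ValueError("coordinates must have exactly two columns")
        if not np.isfinite(coords.values).all():
            raise ValueError("coordinates contain non-finite values")
        if not self.allow_negative and (expr.values < 0).any():
            raise ValueError("expression contains negative values")
        if labels.isna().any():
            raise ValueError("labels contain missing values")


def _read_expression_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def _read_expression_mtx(
    path: Path, *, cells_as: str = "rows"
) -> pd.DataFrame:
    """MatrixMarket expression with ``genes.tsv``/``cells.tsv`` sidecars.

    Sidecars live next to the matrix file, one id per line; ``cells_as``
    declares whether matrix rows or columns are cells.
    """
    path = Path(path)
    mat = spio.mmread(path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    genes = (
        pd.read_csv(path.parent / "genes.tsv", header=None)[0].astype(str).tolist()
    )
    cells = (
        pd.read_csv(path.parent / "cells.tsv", header=None)[0].astype(str).tolist()
    )
    if cells_as == "columns":
        mat = mat.T
    elif cells_as != "rows":
        raise ValueError("cells_as must be 'rows' or 'columns'")
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(cells)} cells x "
            f"{len(genes)} genes"
        )
    return pd.DataFrame(np.asarray(mat, dtype=float), index=cells, columns=genes)


def load_dataset(
    expr_path: str | Path,
    coord_path: str | Path,
    label_path: str | Path,
    *,
    format: str = "csv",
    cells_as: str = "rows",
    allow_negative: bool = False,
) -> SpatialDataset:
    """Load and cross-validate the three input files.

    Cells are joined on the ``cell_id`` string across files — row order may
    differ between files; any cell present in one file but missing from
    another is a hard error naming the offending ids.
    """
    expr_path, coord_path, label_path = map(Path, (expr_path, coord_path, label_path))
    for p in (expr_path, coord_path, label_path):
        if not p.exists():
            raise FileNotFoundError(p)
    if format == "csv":
        expr = _read_expression_csv(expr_path)
    elif format == "mtx":
        expr = _read_expression_mtx(expr_path, cells_as=cells_as)
    else:
        raise ValueError(f"unknown format {format!r}")

    coords = pd.read_csv(coord_path, sep=_sep(coord_path))
    labels = pd.read_csv(label_path, sep=_sep(label_path))
    for df, cols, name in (
        (coords, {"cell_id", "x", "y"}, coord_path),
        (labels, {"cell_id", "cell_type"}, label_path),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name}: missing columns {sorted(missing)}")
    coords = coords.astype({"cell_id": str}).set_index("cell_id")[["x", "y"]]
    labels = labels.astype({"cell_id": str}).set_index("cell_id")["cell_type"]

    ids = set(expr.index)
    for other, name in ((set(coords.index), "coordinates"),
                        (set(labels.index), "labels")):
        if other != ids:
            offending = sorted(ids ^ other)[:10]
            raise ValueError(
                f"cell ids inconsistent between expression and {name}: "
                f"{offending}"
            )
    order = expr.index
    return SpatialDataset(
        expression=expr,
        coordinates=coords.loc[order],
        labels=labels.loc[order],
        allow_negative=allow_negative,
    )


def write_dataset(
    ds: SpatialDataset, out_dir: str | Path, *, format: str = "csv"
) -> dict[str, Path]:
    """Write the three standard input files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if format == "csv":
        p = out / "expression.csv"
        ds.expression.to_csv(p, index_label="cell_id")
        paths["expression"] = p
    elif format == "mtx":
        p = out / "expression.mtx"
        spio.mmwrite(p, sparse.coo_matrix(ds.expression.values))
        pd.Series(ds.gene_ids).to_csv(out / "genes.tsv", index=False, header=False)
        pd.Series(ds.cell_ids).to_csv(out / "cells.tsv", index=False, header=False)
        paths["expression"] = p
    else:
        raise ValueError(f"unknown format {format!r}")
    cp = out / "coordinates.csv"
    ds.coordinates.to_csv(cp, index_label="cell_id")
    paths["coordinates"] = cp
    lp = out / "labels.csv"
    ds.labels.to_frame("cell_type").to_csv(lp, index_label="cell_id")
    paths["labels"] = lp
    return paths
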