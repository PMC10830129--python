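"""Per-tissue preferential expression of genes in cell types.

The pipeline mirrors standard single-cell practice: cell-wise log
normalisation of UMI counts, an expressed-gene filter, averaging per cell
type, retention of genes whose peak average exceeds the matrix-wide median,
and finally a per-gene Z-score across the tissue's cell types,

    P_gc = (e_gc - mean_c e_g) / SD_c e_g,

where e_gc is the mean normalised expression of gene g in cell type c.
P_gc > 0 marks preferential expression of g in c relative to the other cell
types of the same tissue.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1e4
DEFAULT_MIN_VALUE = 0.05
DEFAULT_MIN_FRAC = 0.10


@dataclass
class CellTypeExpression:
    """Mean normalised expression per gene per cell type for one tissue."""

    tissue: str
    values: pd.DataFrame  # genes x cell types
    n_cells: pd.Series    # per cell type

    def __post_init__(self):
        self.values = self.values.sort_index(axis=0).sort_index(axis=1)
        self.n_cells = self.n_cells.reindex(self.values.columns)


@dataclass
class PreferentialExpression:
    """Z-scores of mean expression across the cell types of one tissue.

    ``z`` is genes x cell types; every row is centred (mean 0) and scaled
    (SD 1 under ``ddof``). Genes with zero cross-cell-type SD are dropped and
    listed in ``dropped_genes``.
    """

    tissue: str
    z: pd.DataFrame
    ddof: int = 0
    dropped_genes: list = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.z.index

    @property
    def cell_types(self) -> pd.Index:
        return self.z.columns

    def to_tsv(self, path: str) -> None:
        long = self.z.stack().rename("z").reset_index()
        long.columns = ["gene", "cell_type", "z"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, tissue: Optional[str] = None,
                 ddof: int = 0) -> "PreferentialExpression":
        long = pd.read_csv(path, sep="\t")
        z = long.pivot(index="gene", columns="cell_type", values="z")
        z = z.sort_index(axis=0).sort_index(axis=1)
        if tissue is None:
            tissue = os.path.basename(path).split(".")[0]
        return cls(tissue=tissue, z=z, ddof=ddof)


def _dense(matrix) -> np.ndarray:
    return matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)


def normalize_counts(counts, scale: float = DEFAULT_SCALE,
                     cell_ids: Optional[Sequence[str]] = None,
                     drop_zero_cells: bool = False):
    """Cell-wise log normalisation: log(1 + count * scale / cell_total).

    Parameters
    ----------
    counts
        Cells x genes raw counts.
    scale
        Size-factor target (counts per ``scale`` total).
    drop_zero_cells
        If True, cells with zero total counts are removed; otherwise such a
        cell raises a ValueError naming it.

    Returns
    -------
    (normalized, kept_mask)
        ``normalized`` is a dense float array over the kept cells;
        ``kept_mask`` is a boolean array over the input cells.
    """
    X = _dense(counts)
    totals = X.sum(axis=1)
    zero = totals == 0
    kept = ~zero
    if zero.any():
        if not drop_zero_cells:
            ids = (np.asarray(cell_ids)[zero] if cell_ids is not None
                   else np.flatnonzero(zero))
            raise ValueError(f"cells with zero total counts: {list(ids[:5])}")
        X = X[kept]
        totals = totals[kept]
    norm = np.log1p(X * (scale / totals[:, None]))
    return norm, kept


def filter_expressed_genes(norm: np.ndarray, cell_types: Sequence[str],
                           gene_ids: Sequence[str],
                           min_value: float = DEFAULT_MIN_VALUE,
                           min_frac: float = DEFAULT_MIN_FRAC) -> pd.Index:
    """Genes with normalised value >= ``min_value`` in >= ``min_frac`` of the
    cells of at least one cell type (both bounds inclusive)."""
    cell_types = pd.Series(list(cell_types))
    gene_ids = pd.Index(gene_ids)
    keep = np.zeros(norm.shape[1], dtype=bool)
    for ct, idx in cell_types.groupby(cell_types).groups.items():
        rows = norm[np.asarray(idx)]
        if rows.shape[0] == 0:
            raise ValueError(f"cell type {ct!r} has zero cells")
        frac = (rows >= min_value).mean(axis=0)
        keep |= frac >= min_frac
    return gene_ids[keep].sort_values()


def average_by_celltype(norm: np.ndarray, cell_types: Sequence[str],
                        gene_ids: Sequence[str], tissue: str) -> CellTypeExpression:
    """Arithmetic mean of normalised expression per gene per cell type."""
    df = pd.DataFrame(norm, columns=pd.Index(gene_ids, name="gene"))
    df["__ct"] = list(cell_types)
    grouped = df.groupby("__ct")
    means = grouped.mean().T  # genes x cell types
    means.columns.name = "cell_type"
    n_cells = grouped.size()
    n_cells.index.name = "cell_type"
    small = n_cells[n_cells < 10]
    if len(small):
        logger.warning("tissue %s: cell types with <10 cells: %s",
                       tissue, dict(small))
    return CellTypeExpression(tissue=tissue, values=means, n_cells=n_cells)


def retain_above_median(avg: CellTypeExpression) -> pd.Index:
    """Genes whose maximum average expression strictly exceeds the median over
    all entries of the average matrix. Ties at the median are dropped."""
    if avg.values.empty:
        raise ValueError("empty average-expression matrix")
    med = np.median(avg.values.to_numpy())
    keep = avg.values.max(axis=1) > med
    return avg.values.index[keep]


def preferential_expression(avg: CellTypeExpression, ddof: int = 0) -> PreferentialExpression:
    """Row-wise Z-score of average expression across cell types.

    Genes with zero SD across cell types are dropped (recorded in
    ``dropped_genes``). A single-cell-type tissue has no defined Z.
    """
    vals = avg.values
    if vals.shape[1] < 2:
        raise ValueError(
            f"tissue {avg.tissue!r} has {vals.shape[1]} cell type(s); "
            "preferential expression needs at least 2"
        )
    arr = vals.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    nz = sd[:, 0] > 0
    z = pd.DataFrame((arr[nz] - mean[nz]) / sd[nz],
                     index=vals.index[nz], columns=vals.columns)
    dropped = vals.index[~nz].tolist()
    if dropped:
        logger.info("tissue %s: dropped %d zero-variance genes",
                    avg.tissue, len(dropped))
    return PreferentialExpression(tissue=avg.tissue, z=z, ddof=ddof,
                                  dropped_genes=dropped)


def tissue_preferential_expression(
    data: ExpressionDataset,
    scale: float = DEFAULT_SCALE,
    min_value: float = DEFAULT_MIN_VALUE,
    min_frac: float = DEFAULT_MIN_FRAC,
    ddof: int = 0,
    drop_zero_cells: bool = False,
) -> dict[str, PreferentialExpression]:
    """Full pipeline per tissue: normalise, filter, average, retain, Z-score."""
    out: dict[str, PreferentialExpression] = {}
    for tissue in data.tissues:
        sub = data.subset_tissue(tissue)
        norm, kept = normalize_counts(sub.adata.X, scale=scale,
                                      cell_ids=sub.cell_ids,
                                      drop_zero_cells=drop_zero_cells)
        cts = sub.cell_type.to_numpy()[kept]
        expressed = filter_expressed_genes(norm, cts, sub.gene_ids,
                                           min_value=min_value, min_frac=min_frac)
        col_idx = sub.gene_ids.get_indexer(expressed)
        avg = average_by_celltype(norm[:, col_idx], cts, expressed, tissue)
        retained = retain_above_median(avg)
        avg_ret = CellTypeExpression(tissue=tissue,
                                     values=avg.values.loc[retained],
                                     n_cells=avg.n_cells)
        out[tissue] = preferential_expression(avg_ret, ddof=ddof)
    return out


def write_preferential_expression(pe: dict[str, PreferentialExpression],
                                  outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for tissue, p in sorted(pe.items()):
        p.to_tsv(os.path.join(outdir, f"{tissue}.preferential_expression.tsv"))


def read_preferential_expression(indir: str, ddof: int = 0) -> dict[str, PreferentialExpression]:
    out = {}
    for name in sorted(os.listdir(indir)):
        if name.endswith(".preferential_expression.tsv"):
            tissue = name[: -len(".preferential_expression.tsv")]
            out[tissue] = PreferentialExpression.from_tsv(
                os.path.join(indir, name), tissue=tissue, ddof=ddof
            )
    return out
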