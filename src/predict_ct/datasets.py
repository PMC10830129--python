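"""Containers for annotated single-cell expression data and disease catalogs.

The raw-count container wraps an :class:`anndata.AnnData` (cells x genes) whose
``obs`` carries the per-cell ``tissue``, ``cell_type`` and ``sample`` labels and
whose ``uns['species']`` names the organism. Readers accept Matrix Market
(MTX + genes.tsv + cells.tsv) or a dense genes-x-cells TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

OBS_COLUMNS = ("tissue", "cell_type", "sample")


class ExpressionDataset:
    """Raw UMI counts over cells x genes with per-cell annotations for one species.

    Parameters
    ----------
    counts
        Non-negative matrix, cells x genes (dense or sparse).
    cells
        DataFrame indexed by cell id with columns ``tissue``, ``cell_type``,
        ``sample``.
    gene_ids
        Unique gene identifiers, one per column of ``counts``.
    species
        Organism label, e.g. ``"human"``.
    """

    def __init__(self, counts, cells: pd.DataFrame, gene_ids: Sequence[str],
                 species: str = "unknown"):
        gene_ids = pd.Index(gene_ids, name="gene")
        if gene_ids.has_duplicates:
            dups = gene_ids[gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        missing = [c for c in OBS_COLUMNS if c not in cells.columns]
        if missing:
            raise ValueError(f"cells table lacks columns {missing}")
        if sp.issparse(counts):
            if counts.min() < 0:
                raise ValueError("counts must be non-negative")
        elif np.asarray(counts).min() < 0:
            raise ValueError("counts must be non-negative")
        obs = cells.loc[:, list(OBS_COLUMNS)].astype(str)
        X = counts if sp.issparse(counts) else np.asarray(counts, dtype=np.float64)
        self.adata = ad.AnnData(
            X=X, obs=obs, var=pd.DataFrame(index=gene_ids), uns={"species": species}
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        X = self.adata.X
        return X.toarray() if sp.issparse(X) else np.asarray(X)

    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_tissue(self) -> pd.Series:
        return self.adata.obs["tissue"]

    @property
    def cell_type(self) -> pd.Series:
        return self.adata.obs["cell_type"]

    @property
    def cell_sample(self) -> pd.Series:
        return self.adata.obs["sample"]

    @property
    def species(self) -> str:
        return self.adata.uns["species"]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.adata.obs["tissue"].unique())

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    def subset_tissue(self, tissue: str) -> "ExpressionDataset":
        mask = (self.adata.obs["tissue"] == tissue).to_numpy()
        if not mask.any():
            raise KeyError(f"no cells annotated to tissue {tissue!r}")
        sub = self.adata[mask]
        return ExpressionDataset(
            sub.X.copy(), sub.obs.copy(), sub.var_names, species=self.species
        )

    # -- I/O -------------------------------------------------------------------
    @classmethod
    def from_mtx_dir(cls, path: str, species: str = "unknown") -> "ExpressionDataset":
        """Read ``matrix.mtx`` (genes x cells) + ``genes.tsv`` + ``cells.tsv``.

        ``cells.tsv`` must have columns cell_id, tissue, cell_type, sample.
        Gzipped ``matrix.mtx.gz`` is accepted.
        """
        mtx = os.path.join(path, "matrix.mtx")
        if not os.path.exists(mtx):
            mtx = mtx + ".gz"
        counts = scipy.io.mmread(mtx).T.tocsr()  # stored genes x cells
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0]
        cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t").set_index("cell_id")
        return cls(counts, cells, genes, species=species)

    @classmethod
    def from_dense_tsv(cls, matrix_tsv: str, cells_tsv: str,
                       species: str = "unknown") -> "ExpressionDataset":
        """Read a dense genes x cells TSV (first column = gene id)."""
        mat = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
        cells = pd.read_csv(cells_tsv, sep="\t").set_index("cell_id")
        mat = mat.loc[:, cells.index]
        return cls(mat.T.to_numpy(), cells, mat.index, species=species)

    def to_mtx_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        X = self.adata.X
        mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), mat)
        pd.Series(self.gene_ids).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", index=False, header=False
        )
        cells = self.adata.obs.copy()
        cells.insert(0, "cell_id", cells.index)
        cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)


@dataclass(frozen=True)
class DiseaseCatalog:
    """Disease -> gene set with affected tissues and optional gene-function labels.

    ``table`` rows: disease_id, gene_id, tissue, function_label (optional,
    NaN/empty allowed). (disease_id, gene_id, tissue) must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("disease_id", "gene_id", "tissue"):
            if col not in t.columns:
                raise ValueError(f"catalog lacks column {col!r}")
        if "function_label" not in t.columns:
            object.__setattr__(self, "table", t.assign(function_label=pd.NA))
        key = self.table[["disease_id", "gene_id", "tissue"]]
        if key.duplicated().any():
            raise ValueError("duplicate (disease_id, gene_id, tissue) entries")

    @classmethod
    def from_tsv(cls, path: str) -> "DiseaseCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.table["disease_id"].unique())

    def tissues_of(self, disease_id: str) -> list[str]:
        sub = self.table.loc[self.table["disease_id"] == disease_id, "tissue"]
        if sub.empty:
            raise KeyError(f"unknown disease {disease_id!r}")
        return sorted(sub.unique())

    def genes_of(self, disease_id: str, tissue: Optional[str] = None,
                 function_label: Optional[str] = None) -> set[str]:
        t = self.table
        mask = t["disease_id"] == disease_id
        if tissue is not None:
            mask &= t["tissue"] == tissue
        if function_label is not None:
            mask &= t["function_label"] == function_label
        return set(t.loc[mask, "gene_id"])

    def function_labels(self) -> list[str]:
        lab = self.table["function_label"].dropna()
        return sorted(x for x in lab.unique() if x != "")


@dataclass(frozen=True)
class CellClassMap:
    """Cell type -> cell class (fibroblasts, stem cells, myocytes, endothelia,
    epithelia, immunocytes, other)."""

    mapping: Mapping[str, str]

    @classmethod
    def from_tsv(cls, path: str) -> "CellClassMap":
        t = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(t["cell_type"], t["cell_class"])))

    def __getitem__(self, cell_type: str) -> str:
        return self.mapping[cell_type]

    def classes(self) -> list[str]:
        return sorted(set(self.mapping.values()))
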