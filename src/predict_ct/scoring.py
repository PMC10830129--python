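"""Disease scores per cell type with an empirical permutation null.

The score of disease D in cell type c is the median preferential expression
of D's genes in c (the PrEDiCT score),

    score_D(c) = median(P_{g1,c}, ..., P_{gn,c}).

Significance is assessed against random gene sets of the same size n drawn
without replacement from the tissue's retained gene universe: each draw is
scored in *all* cell types of the tissue (preserving the cross-cell-type
correlation of the null), and p(c) is the fraction of draws whose score in c
is at least as high as the observed one. P-values are Benjamini-Hochberg
adjusted within each disease-tissue group, and a pair is called "likely"
when score >= 1 and FDR < 0.1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datasets import DiseaseCatalog, ExpressionDataset
from .expr import PreferentialExpression, tissue_preferential_expression

DEFAULT_REPS = 1000
DEFAULT_SCORE_MIN = 1.0
DEFAULT_FDR_MAX = 0.1
EXHAUSTIVE_CAP = 2_000_000  # refuse enumeration beyond this many gene sets

RESULT_COLUMNS = ["disease_id", "tissue", "cell_type", "score",
                  "n_genes_used", "p_value", "fdr", "likely"]


def predict_score(z: PreferentialExpression, genes: Iterable[str]) -> tuple[pd.Series, int]:
    """Median preferential expression of ``genes`` per cell type.

    Genes absent from ``z`` are dropped; the effective count is returned.
    With no retained gene the scores are NaN.
    """
    present = z.genes.intersection(pd.Index(set(genes)))
    if len(present) == 0:
        return pd.Series(np.nan, index=z.cell_types), 0
    scores = z.z.loc[present].median(axis=0)
    return scores, len(present)


def _null_scores(z: PreferentialExpression, n: int, reps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """reps x cell-types matrix of scores of random gene sets of size n.

    One gene set per repeat, shared across all cell types of the tissue.
    """
    universe = len(z.genes)
    if n > universe:
        raise ValueError(f"gene-set size {n} exceeds universe of {universe}")
    arr = z.z.to_numpy()
    # without-replacement draws via random sort keys; order within a set is
    # irrelevant to the median, so a partial partition suffices
    keys = rng.random((reps, universe))
    idx = np.argpartition(keys, min(n, universe - 1), axis=1)[:, :n]
    return np.median(arr[idx], axis=1)


def _exhaustive_scores(z: PreferentialExpression, n: int) -> np.ndarray:
    universe = len(z.genes)
    total = math.comb(universe, n)
    if total > EXHAUSTIVE_CAP:
        raise ValueError(f"C({universe},{n})={total} gene sets exceed the "
                         f"enumeration cap of {EXHAUSTIVE_CAP}")
    arr = z.z.to_numpy()
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(universe), n)),
        dtype=np.intp, count=total * n,
    ).reshape(total, n)
    return np.median(arr[combos], axis=1)


def permutation_pvalues(z: PreferentialExpression, observed: pd.Series, n: int,
                        reps: int = DEFAULT_REPS,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None,
                        exhaustive: bool = False,
                        plus_one: bool = False) -> pd.Series:
    """Empirical p per cell type: fraction of random scores >= observed.

    ``exhaustive=True`` replaces sampling by enumeration of every gene set of
    size ``n`` (small universes only). ``plus_one`` switches to the
    (k+1)/(reps+1) estimator; the plain fraction k/reps is the default.
    """
    if exhaustive:
        null = _exhaustive_scores(z, n)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        null = _null_scores(z, n, reps, rng)
    obs = observed.reindex(z.cell_types).to_numpy()
    k = (null >= obs[None, :]).sum(axis=0).astype(float)
    m = null.shape[0]
    p = (k + 1) / (m + 1) if plus_one else k / m
    return pd.Series(p, index=z.cell_types)


def adjust_fdr(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up within one disease-tissue group."""
    mask = p_values.notna()
    out = pd.Series(np.nan, index=p_values.index)
    if mask.any():
        out[mask] = multipletests(p_values[mask].to_numpy(), method="fdr_bh")[1]
    return out


def call_likely(table: pd.DataFrame, score_threshold: float = DEFAULT_SCORE_MIN,
                fdr_threshold: float = DEFAULT_FDR_MAX) -> pd.DataFrame:
    """Flag likely associations: score >= threshold (inclusive) AND
    fdr < threshold (strict)."""
    table = table.copy()
    table["likely"] = ((table["score"] >= score_threshold)
                       & (table["fdr"] < fdr_threshold)).fillna(False)
    return table


class PredictModel:
    """Disease / cell-type association model over preferential expression.

    Parameters
    ----------
    expression
        Mapping tissue -> :class:`PreferentialExpression` (or a single
        instance, taken as its own tissue).
    catalog
        :class:`DiseaseCatalog` of disease gene sets and affected tissues.

    Examples
    --------
    >>> model = PredictModel(pe, catalog)
    >>> res = model.fit(reps=1000, seed=17)
    >>> res.likely  # doctest: +SKIP
    """

    def __init__(self,
                 expression: Union[PreferentialExpression, Mapping[str, PreferentialExpression]],
                 catalog: DiseaseCatalog):
        if isinstance(expression, PreferentialExpression):
            expression = {expression.tissue: expression}
        self.expression = dict(expression)
        self.catalog = catalog

    @classmethod
    def from_dataset(cls, data: ExpressionDataset, catalog: DiseaseCatalog,
                     **pipeline_kwargs) -> "PredictModel":
        """Build from raw counts by running the preferential-expression pipeline."""
        return cls(tissue_preferential_expression(data, **pipeline_kwargs), catalog)

    def fit(self, reps: int = DEFAULT_REPS, seed: Optional[int] = None,
            exhaustive: bool = False, plus_one: bool = False,
            score_threshold: float = DEFAULT_SCORE_MIN,
            fdr_threshold: float = DEFAULT_FDR_MAX,
            subset_by: Optional[str] = None) -> "PredictResults":
        """Score every disease in every cell type of its affected tissues.

        ``subset_by="function_label"`` runs the full scheme independently per
        gene-function subset (e.g. ligand vs receptor, oncogene vs TSG), each
        with its own permutation null of matching size.
        """
        if subset_by is not None and subset_by != "function_label":
            raise ValueError("subset_by supports only 'function_label'")
        rng = np.random.default_rng(seed)
        rows = []
        for disease in self.catalog.diseases:
            for tissue in self.catalog.tissues_of(disease):
                if tissue not in self.expression:
                    continue
                z = self.expression[tissue]
                if subset_by is None:
                    subsets = [(None, self.catalog.genes_of(disease, tissue))]
                else:
                    labels = sorted(
                        self.catalog.table.loc[
                            (self.catalog.table["disease_id"] == disease)
                            & (self.catalog.table["tissue"] == tissue),
                            "function_label"].dropna().unique()
                    )
                    if not labels:
                        raise ValueError(
                            f"disease {disease!r} has no function labels; "
                            f"valid labels in catalog: {self.catalog.function_labels()}"
                        )
                    subsets = [(lab, self.catalog.genes_of(disease, tissue, lab))
                               for lab in labels]
                for label, genes in subsets:
                    rows.append(self._fit_one(disease, tissue, z, genes, label,
                                              reps, rng, exhaustive, plus_one))
        table = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=RESULT_COLUMNS))
        table = call_likely(table, score_threshold, fdr_threshold)
        if subset_by is None and "subset" in table.columns:
            table = table.drop(columns="subset")
        params = dict(reps=reps, seed=seed, exhaustive=exhaustive,
                      plus_one=plus_one, score_threshold=score_threshold,
                      fdr_threshold=fdr_threshold, subset_by=subset_by,
                      ddof={t: z.ddof for t, z in self.expression.items()})
        return PredictResults(model=self, table=table, params=params)

    def _fit_one(self, disease, tissue, z, genes, label, reps, rng,
                 exhaustive, plus_one) -> pd.DataFrame:
        scores, n_used = predict_score(z, genes)
        n_catalog = len(genes)
        if n_used == 0:
            p = pd.Series(np.nan, index=z.cell_types)
            reason = "no_expressed_genes"
        else:
            p = permutation_pvalues(z, scores, n_used, reps=reps, rng=rng,
                                    exhaustive=exhaustive, plus_one=plus_one)
            reason = ""
        fdr = adjust_fdr(p)
        out = pd.DataFrame({
            "disease_id": disease, "tissue": tissue,
            "cell_type": z.cell_types,
            "score": scores.reindex(z.cell_types).to_numpy(),
            "n_genes_used": n_used, "n_genes_catalog": n_catalog,
            "p_value": p.to_numpy(), "fdr": fdr.to_numpy(),
            "note": reason,
        })
        if label is not None:
            out.insert(1, "subset", label)
        return out


@dataclass
class PredictResults:
    """Fitted disease / cell-type associations.

    ``table`` columns: disease_id, [subset,] tissue, cell_type, score,
    n_genes_used, n_genes_catalog, p_value, fdr, note, likely.
    """

    model: PredictModel
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def likely(self) -> pd.DataFrame:
        """Rows called likely (score >= threshold and FDR below threshold)."""
        return self.table[self.table["likely"]]

    def likely_pairs(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.likely[["disease_id", "cell_type", "tissue"]]
                       .itertuples(index=False)))

    def summary(self) -> str:
        t = self.table
        n_assoc = len(t)
        n_likely = int(t["likely"].sum())
        n_dis = t["disease_id"].nunique()
        n_dis_likely = t.loc[t["likely"], "disease_id"].nunique()
        n_ct = t.groupby("tissue")["cell_type"].nunique().sum()
        lines = [
            "Disease / cell-type association results",
            "=" * 42,
            f"associations evaluated : {n_assoc}",
            f"likely associations    : {n_likely}"
            + (f" ({100 * n_likely / n_assoc:.1f}%)" if n_assoc else ""),
            f"diseases (with likely) : {n_dis} ({n_dis_likely})",
            f"cell types evaluated   : {int(n_ct)}",
            f"score threshold        : >= {self.params.get('score_threshold')}",
            f"FDR threshold          : < {self.params.get('fdr_threshold')}",
            f"permutations           : {self.params.get('reps')}"
            f" (seed={self.params.get('seed')})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")
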