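"""Which cell types and cell classes are likely affected by disease?

Susceptibility of a cell type = fraction of its tissue's diseases that
likely affect it. Prevalence = fraction of the tissue's cells it contains.
Class-level tests: one-way ANOVA of susceptibility across cell classes,
per-class Mann-Whitney U against all other cell types (BH-adjusted), and
the Pearson correlation of susceptibility with prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .datasets import CellClassMap, ExpressionDataset


def susceptibility(result: pd.DataFrame) -> pd.DataFrame:
    """Per (tissue, cell type): fraction of the tissue's diseases calling it
    likely affected. A tissue with zero diseases yields NaN."""
    if "likely" not in result.columns:
        raise ValueError("result table lacks the 'likely' flag")
    rows = []
    for tissue, sub in result.groupby("tissue"):
        n_dis = sub["disease_id"].nunique()
        for ct, ctsub in sub.groupby("cell_type"):
            n_likely = ctsub.loc[ctsub["likely"], "disease_id"].nunique()
            frac = n_likely / n_dis if n_dis else np.nan
            rows.append((tissue, ct, n_likely, n_dis, frac))
    return pd.DataFrame(rows, columns=["tissue", "cell_type", "n_likely_diseases",
                                       "n_tissue_diseases", "susceptibility"])


def prevalence(data: ExpressionDataset) -> pd.DataFrame:
    """Per (tissue, cell type): fraction of the tissue's cells; sums to 1
    within each tissue."""
    obs = data.adata.obs
    counts = obs.groupby(["tissue", "cell_type"], observed=True).size()
    totals = obs.groupby("tissue", observed=True).size()
    out = (counts / totals).rename("prevalence").reset_index()
    return out.sort_values(["tissue", "cell_type"]).reset_index(drop=True)


def prevalent_classes(classes: CellClassMap, susc: pd.DataFrame,
                      min_cell_types: int = 15, min_tissues: int = 4) -> list[str]:
    """Classes represented by >``min_cell_types`` cell types across
    >=``min_tissues`` tissues, recomputed from the input table."""
    tab = susc.assign(cell_class=[classes[ct] for ct in susc["cell_type"]])
    grp = tab.groupby("cell_class").agg(n_ct=("cell_type", "size"),
                                        n_tissues=("tissue", "nunique"))
    sel = grp[(grp["n_ct"] > min_cell_types) & (grp["n_tissues"] >= min_tissues)]
    return sorted(sel.index)


@dataclass
class ClassTestResults:
    anova_f: float
    anova_p: float
    mwu: pd.DataFrame           # cell_class, statistic, p_value, p_adjusted, n
    pearson_r: Optional[float]  # susceptibility vs prevalence
    pearson_p: Optional[float]


def class_tests(susc: pd.DataFrame, classes: CellClassMap,
                prevalent: Optional[Sequence[str]] = None,
                prev: Optional[pd.DataFrame] = None,
                min_cell_types: int = 15, min_tissues: int = 4) -> ClassTestResults:
    """ANOVA across classes, per-prevalent-class MWU vs the rest (BH), and the
    susceptibility-prevalence Pearson correlation (if ``prev`` given).

    Degenerate groups (fewer than 2 classes with >=2 cell types) yield NaN
    ANOVA statistics.
    """
    tab = susc.dropna(subset=["susceptibility"]).copy()
    tab["cell_class"] = [classes[ct] for ct in tab["cell_type"]]
    groups = [g["susceptibility"].to_numpy() for _, g in tab.groupby("cell_class")]
    if sum(len(g) >= 2 for g in groups) >= 2:
        if np.ptp(tab["susceptibility"].to_numpy()) == 0:
            anova_f, anova_p = 0.0, 1.0  # no variation anywhere
        else:
            anova_f, anova_p = st.f_oneway(*[g for g in groups if len(g)])
    else:
        anova_f = anova_p = np.nan
    if prevalent is None:
        prevalent = prevalent_classes(classes, tab, min_cell_types, min_tissues)
    rows = []
    for cls in prevalent:
        mask = tab["cell_class"] == cls
        x = tab.loc[mask, "susceptibility"].to_numpy()
        y = tab.loc[~mask, "susceptibility"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            rows.append((cls, np.nan, np.nan, len(x)))
            continue
        u, p = st.mannwhitneyu(x, y, alternative="two-sided")
        rows.append((cls, u, p, len(x)))
    mwu = pd.DataFrame(rows, columns=["cell_class", "statistic", "p_value", "n"])
    valid = mwu["p_value"].notna()
    mwu["p_adjusted"] = np.nan
    if valid.any():
        mwu.loc[valid, "p_adjusted"] = multipletests(
            mwu.loc[valid, "p_value"], method="fdr_bh")[1]
    pearson_r = pearson_p = None
    if prev is not None:
        merged = tab.merge(prev, on=["tissue", "cell_type"])
        if len(merged) >= 3:
            pearson_r, pearson_p = st.pearsonr(merged["susceptibility"],
                                               merged["prevalence"])
    return ClassTestResults(anova_f, anova_p, mwu, pearson_r, pearson_p)
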