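"""Corroboration statistics for disease / cell-type associations.

Covers: literature co-appearance support (exact test on shared record IDs
with Bonferroni control), enrichment of likely calls in a gold standard,
false-positive / false-negative rate curves over the FDR threshold,
correlation of scores between matched cell types of two datasets, and a
permutation test for whether the same disease hits matching cell types in
two tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_JOINT = 3
DEFAULT_COAPPEAR_ALPHA = 0.001


@dataclass
class RecordSets:
    """Literature record IDs per disease and per cell type, keyed by tissue.

    ``diseases[(tissue, disease_id)]`` and ``cell_types[(tissue, cell_type)]``
    are sets of record identifiers; sets may overlap across entities.
    """

    diseases: dict = field(default_factory=dict)
    cell_types: dict = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str) -> "RecordSets":
        t = pd.read_csv(path, sep="\t", dtype=str)
        rs = cls()
        for row in t.itertuples(index=False):
            target = rs.diseases if row.entity_type == "disease" else rs.cell_types
            target.setdefault((row.tissue, row.entity_id), set()).add(row.record_id)
        return rs

    def to_tsv(self, path: str) -> None:
        rows = [("disease", d, t, r)
                for (t, d), recs in sorted(self.diseases.items()) for r in sorted(recs)]
        rows += [("cell_type", c, t, r)
                 for (t, c), recs in sorted(self.cell_types.items()) for r in sorted(recs)]
        pd.DataFrame(rows, columns=["entity_type", "entity_id", "tissue", "record_id"]
                     ).to_csv(path, sep="\t", index=False)

    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.diseases} | {t for t, _ in self.cell_types})


@dataclass(frozen=True)
class GoldPairs:
    """Externally supported (disease_id, cell_type, tissue) triples."""

    pairs: frozenset

    @classmethod
    def from_triples(cls, triples: Iterable[tuple[str, str, str]]) -> "GoldPairs":
        return cls(frozenset(tuple(t) for t in triples))

    @classmethod
    def from_tsv(cls, path: str) -> "GoldPairs":
        t = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_triples(zip(t["disease_id"], t["cell_type"], t["tissue"]))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(sorted(self.pairs),
                     columns=["disease_id", "cell_type", "tissue"]
                     ).to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.pairs)


def coappearance_test(records: RecordSets,
                      min_joint: int = DEFAULT_MIN_JOINT,
                      alpha: float = DEFAULT_COAPPEAR_ALPHA,
                      method: str = "fisher",
                      drop_disease: bool = False) -> tuple[GoldPairs, pd.DataFrame]:
    """Which disease / cell-type pairs share literature records beyond chance?

    Per tissue, the record universe is the union of the record sets of all of
    that tissue's entities. A pair is tested one-sided (over-co-appearance) on
    the 2x2 of record membership; p-values are Bonferroni-adjusted across the
    tissue's tested pairs, and a pair is supported when adjusted p < ``alpha``.

    Filters applied before testing: pairs with fewer than ``min_joint`` shared
    records are excluded (with ``drop_disease=True``, a disease that shares
    < ``min_joint`` records with *every* cell type is dropped entirely, the
    alternative reading); cell types mentioned with no disease are excluded.

    Returns the supported pairs and a per-pair statistics table.
    """
    if method not in ("fisher", "chi2"):
        raise ValueError("method must be 'fisher' or 'chi2'")
    rows = []
    for tissue in records.tissues():
        dis = {d: r for (t, d), r in records.diseases.items() if t == tissue}
        cts = {c: r for (t, c), r in records.cell_types.items() if t == tissue}
        universe = set().union(*dis.values(), *cts.values()) if (dis or cts) else set()
        if not universe:
            raise ValueError(f"tissue {tissue!r} has an empty record universe")
        n_univ = len(universe)
        # cell types never co-mentioned with any disease are excluded
        cts = {c: r for c, r in cts.items()
               if any(r & dr for dr in dis.values())}
        if drop_disease:
            dis = {d: r for d, r in dis.items()
                   if any(len(r & cr) >= min_joint for cr in cts.values())}
        for d, drec in sorted(dis.items()):
            for c, crec in sorted(cts.items()):
                joint = len(drec & crec)
                if not drop_disease and joint < min_joint:
                    continue
                a = joint
                b = len(drec) - joint
                cc = len(crec) - joint
                dd = n_univ - a - b - cc
                if method == "fisher":
                    p = st.fisher_exact([[a, b], [cc, dd]], alternative="greater")[1]
                else:
                    p = st.chi2_contingency([[a, b], [cc, dd]])[1]
                rows.append((tissue, d, c, a, len(drec), len(crec), n_univ, p))
    stats = pd.DataFrame(rows, columns=["tissue", "disease_id", "cell_type",
                                        "n_joint", "n_disease", "n_cell_type",
                                        "n_universe", "p_value"])
    # Bonferroni within each tissue's tested pairs
    stats["p_adjusted"] = np.nan
    for tissue, idx in stats.groupby("tissue").groups.items():
        n_tests = len(idx)
        stats.loc[idx, "p_adjusted"] = np.minimum(
            stats.loc[idx, "p_value"] * n_tests, 1.0)
    stats["supported"] = stats["p_adjusted"] < alpha
    gold = GoldPairs.from_triples(
        (r.disease_id, r.cell_type, r.tissue)
        for r in stats[stats["supported"]].itertuples(index=False))
    return gold, stats


def enrichment_fisher_from_counts(n_overlap: int, n_predicted: int,
                                  n_gold: int, n_universe: int) -> tuple[float, float]:
    """One-sided Fisher's exact test from overlap counts.

    2x2: [[overlap, predicted-only], [gold-only, neither]].
    Returns (odds_ratio, p).
    """
    a = n_overlap
    b = n_predicted - n_overlap
    c = n_gold - n_overlap
    d = n_universe - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("universe smaller than the union of the sets")
    odds, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
    return odds, p


def enrichment_fisher(likely: set, gold: GoldPairs,
                      universe_size: int) -> tuple[float, float]:
    """Enrichment of the gold standard among likely associations."""
    overlap = len(likely & gold.pairs)
    return enrichment_fisher_from_counts(overlap, len(likely), len(gold),
                                         universe_size)


def error_rates_vs_threshold(result: pd.DataFrame, gold: GoldPairs,
                             thresholds: Sequence[float],
                             score_threshold: float = 1.0) -> pd.DataFrame:
    """FPR / FNR of likely calls against a gold standard over an FDR grid.

    At threshold t the prediction set is {score >= score_threshold, fdr < t};
    FPR = |pred \\ gold| / |universe \\ gold| and FNR = |gold \\ pred| / |gold|,
    where the universe is every evaluated association.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    key = ["disease_id", "cell_type", "tissue"]
    universe = set(map(tuple, result[key].itertuples(index=False)))
    n_neg = len(universe - gold.pairs)
    rows = []
    for t in thresholds:
        sel = (result["score"] >= score_threshold) & (result["fdr"] < t)
        pred = set(map(tuple, result.loc[sel, key].itertuples(index=False)))
        fpr = len(pred - gold.pairs) / n_neg if n_neg else np.nan
        fnr = len(gold.pairs - pred) / len(gold.pairs)
        rows.append((t, fpr, fnr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "fnr"])


def matched_score_correlation(result_a: pd.DataFrame, result_b: pd.DataFrame,
                              matches: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of disease scores across two datasets, split by
    whether the cell-type pair is matched.

    For every disease shared by both result tables and every cell-type pair
    (a, b) in ``matches``, the pair of scores (score_a, score_b) contributes
    one observation to the matched or non-matched stratum. Strata with fewer
    than 3 observations report r as NaN.
    """
    a = result_a.rename(columns={"cell_type": "cell_type_a", "score": "score_a"})
    b = result_b.rename(columns={"cell_type": "cell_type_b", "score": "score_b"})
    # honour a tissue column when present so tissues reusing cell-type names
    # are not cross-joined
    tis = ["tissue"] if "tissue" in matches.columns else []
    merged = (matches[tis + ["cell_type_a", "cell_type_b", "matched"]]
              .merge(a[["disease_id", "cell_type_a", "score_a"] + tis],
                     on=tis + ["cell_type_a"])
              .merge(b[["disease_id", "cell_type_b", "score_b"] + tis],
                     on=tis + ["disease_id", "cell_type_b"]))
    merged = merged.dropna(subset=["score_a", "score_b"])
    rows = []
    for flag, name in ((True, "matched"), (False, "non_matched")):
        sub = merged[merged["matched"] == flag]
        if len(sub) < 3:
            rows.append((name, np.nan, np.nan, len(sub)))
        else:
            r, p = st.spearmanr(sub["score_a"], sub["score_b"])
            rows.append((name, r, p, len(sub)))
    return pd.DataFrame(rows, columns=["stratum", "spearman_r", "p_value", "n"])


@dataclass
class MatchingPermutationResult:
    """Outcome of the shared-disease matching permutation test."""

    num_success: int
    n_diseases: int
    n_skipped: int
    null: np.ndarray  # null counts (sampled) or probabilities (exact)
    p_value: float
    exact: bool = False


def _success(ref_sets: Mapping[str, frozenset], test_sets: Mapping[str, frozenset],
             matched: set) -> int:
    n = 0
    for d, ref_cts in ref_sets.items():
        test_cts = test_sets[d]
        if any((a, b) in matched for a in ref_cts for b in test_cts):
            n += 1
    return n


def matching_permutation_test(likely_ref: Mapping[str, Iterable[str]],
                              likely_test: Mapping[str, Iterable[str]],
                              matches: pd.DataFrame,
                              celltypes_ref: Sequence[str],
                              reps: int = 1000,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None,
                              exhaustive: bool = False) -> MatchingPermutationResult:
    """Do shared diseases hit matching cell types in two tissues?

    ``likely_ref``/``likely_test`` map disease -> likely cell types in the
    reference tissue T_r and test tissue T_t; ``matches`` is the MatchTable
    between them (cell_type_a = T_r side). A disease is a success when any of
    its likely cell types in T_r matches any of its likely cell types in T_t.

    The null redraws, per disease, as many T_r cell types as it has likely
    ones, uniformly without replacement from ``celltypes_ref``, keeping the
    T_t side fixed; p is the fraction of repeats whose success count is >=
    the observed one. ``exhaustive=True`` computes p exactly by enumerating
    per-disease success probabilities and convolving the resulting
    Poisson-binomial distribution.

    Diseases with no likely cell type on either side are skipped and counted.
    """
    matched = set(map(tuple, matches.loc[matches["matched"],
                                         ["cell_type_a", "cell_type_b"]]
                      .itertuples(index=False)))
    shared = sorted(set(likely_ref) & set(likely_test))
    ref_sets, test_sets = {}, {}
    n_skipped = 0
    for d in shared:
        r, t = frozenset(likely_ref[d]), frozenset(likely_test[d])
        if not r or not t:
            n_skipped += 1
            continue
        ref_sets[d], test_sets[d] = r, t
    num_s = _success(ref_sets, test_sets, matched)
    cts = list(celltypes_ref)
    # per-disease success indicator for a random T_r set depends only on how
    # many of the drawn cell types match the disease's T_t likely set
    if exhaustive:
        probs = []
        for d in ref_sets:
            k = len(ref_sets[d])
            good = [a for a in cts
                    if any((a, b) in matched for b in test_sets[d])]
            m = len(good)
            n = len(cts)
            from math import comb
            p_none = comb(n - m, k) / comb(n, k) if n - m >= k else 0.0
            probs.append(1.0 - p_none)
        # Poisson-binomial tail by convolution
        dist = np.array([1.0])
        for q in probs:
            dist = np.convolve(dist, [1 - q, q])
        p = float(dist[num_s:].sum())
        return MatchingPermutationResult(num_s, len(ref_sets), n_skipped,
                                         dist, p, exact=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(reps, dtype=int)
    for r in range(reps):
        count = 0
        for d in ref_sets:
            draw = rng.choice(cts, size=len(ref_sets[d]), replace=False)
            if any((a, b) in matched for a in draw for b in test_sets[d]):
                count += 1
        null[r] = count
    p = float((null >= num_s).mean())
    return MatchingPermutationResult(num_s, len(ref_sets), n_skipped, null, p)


def matching_permutation_tests(likely_by_tissue: Mapping[str, Mapping[str, Iterable[str]]],
                               matches_by_pair: Mapping[tuple[str, str], pd.DataFrame],
                               celltypes_by_tissue: Mapping[str, Sequence[str]],
                               reps: int = 1000, seed: Optional[int] = None,
                               min_shared: int = 2) -> pd.DataFrame:
    """Run the matching permutation test over every tissue pair with at least
    ``min_shared`` shared diseases; BH-adjust p across tissue pairs."""
    rng = np.random.default_rng(seed)
    rows = []
    for (tr, tt), matches in sorted(matches_by_pair.items()):
        ref, test = likely_by_tissue.get(tr, {}), likely_by_tissue.get(tt, {})
        shared = set(ref) & set(test)
        if len(shared) < min_shared:
            continue
        res = matching_permutation_test(ref, test, matches,
                                        celltypes_by_tissue[tr],
                                        reps=reps, rng=rng)
        rows.append((tr, tt, res.num_success, res.n_diseases, res.p_value))
    out = pd.DataFrame(rows, columns=["tissue_ref", "tissue_test",
                                      "num_success", "n_diseases", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out
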