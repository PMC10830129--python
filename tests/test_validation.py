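"""Co-appearance support, enrichment, error-rate curves and permutation tests."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from predict_ct import (GoldPairs, RecordSets, coappearance_test,
                        enrichment_fisher, enrichment_fisher_from_counts,
                        error_rates_vs_threshold, matched_score_correlation,
                        matching_permutation_test)


def hypergeom_tail(a, b, c, d):
    """Exact one-sided Fisher p for [[a,b],[c,d]] as a tail sum of
    hypergeometric probabilities in exact rational arithmetic."""
    row1, col1, n = a + b, a + c, a + b + c + d
    total = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        total += Fraction(comb(col1, k) * comb(n - col1, row1 - k),
                          comb(n, row1))
    return float(total)


class TestCoappearance:
    def _records(self, dis, cts, tissue="t0"):
        rs = RecordSets()
        for name, recs in dis.items():
            rs.diseases[(tissue, name)] = set(recs)
        for name, recs in cts.items():
            rs.cell_types[(tissue, name)] = set(recs)
        return rs

    def test_identical_sets_supported(self):
        shared = {f"r{i}" for i in range(5)}
        filler = {f"x{i}" for i in range(200)}
        rs = self._records({"d1": shared, "d_bg": filler},
                           {"c1": shared, "c_bg": filler})
        gold, stats = coappearance_test(rs)
        assert ("d1", "c1", "t0") in gold.pairs

    def test_two_joint_records_excluded(self):
        rs = self._records({"d1": {"r1", "r2"}},
                           {"c1": {"r1", "r2", "r3"}})
        gold, stats = coappearance_test(rs)
        assert stats.empty and len(gold) == 0

    def test_unmentioned_cell_type_excluded(self):
        rs = self._records({"d1": {f"r{i}" for i in range(5)}},
                           {"c1": {f"r{i}" for i in range(5)},
                            "lonely": {"q1", "q2", "q3", "q4"}})
        _, stats = coappearance_test(rs)
        assert "lonely" not in set(stats["cell_type"])

    def test_p_equals_hypergeometric_oracle(self):
        rng = np.random.default_rng(40)
        univ = [f"r{i}" for i in range(50)]
        dis = {"d1": set(rng.choice(univ, 20, replace=False))}
        cts = {"c1": set(rng.choice(univ, 15, replace=False))}
        _, stats = coappearance_test(self._records(dis, cts), min_joint=1,
                                     alpha=0.5)
        a = len(dis["d1"] & cts["c1"])
        b = len(dis["d1"]) - a
        c = len(cts["c1"]) - a
        # universe is the union of all record sets of the tissue
        n_univ = len(dis["d1"] | cts["c1"])
        d = n_univ - a - b - c
        expected = hypergeom_tail(a, b, c, d)
        assert stats["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bonferroni_within_tissue(self):
        shared = {f"r{i}" for i in range(6)}
        filler = {f"x{i}" for i in range(100)}
        rs = self._records({"d1": shared, "d2": shared | {"x0", "x1", "x2"}},
                           {"c1": shared, "c2": shared})
        _, stats = coappearance_test(rs, alpha=1.1)
        n_tests = len(stats)
        np.testing.assert_allclose(
            stats["p_adjusted"], np.minimum(stats["p_value"] * n_tests, 1.0))

    def test_chi2_flag(self):
        shared = {f"r{i}" for i in range(10)}
        own_d = {f"x{i}" for i in range(40)}
        own_c = {f"y{i}" for i in range(30)}
        rest = {f"z{i}" for i in range(100)}
        rs = self._records({"d1": shared | own_d, "d2": rest},
                           {"c1": shared | own_c})
        _, fisher = coappearance_test(rs, method="fisher")
        _, chi2 = coappearance_test(rs, method="chi2")
        assert fisher["p_value"].iloc[0] != chi2["p_value"].iloc[0]


class TestEnrichmentFisher:
    def test_reported_overlap_is_extreme(self):
        # 41 of 489 likely calls in a 229-pair gold standard over 34,249
        _, p = enrichment_fisher_from_counts(41, 489, 229, 34249)
        assert p < 1e-15

    def test_small_table_matches_exact_oracle(self):
        _, p = enrichment_fisher_from_counts(5, 10, 10, 100)
        assert p == pytest.approx(hypergeom_tail(5, 5, 5, 85), abs=1e-12)

    def test_likely_equals_gold_is_minimal_p(self):
        gold = GoldPairs.from_triples([("d", f"c{i}", "t") for i in range(5)])
        likely = set(gold.pairs)
        _, p_full = enrichment_fisher(likely, gold, universe_size=50)
        _, p_partial = enrichment_fisher(set(list(likely)[:3]), gold, 50)
        assert p_full < p_partial

    def test_undersized_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_fisher_from_counts(5, 10, 10, 14)


class TestErrorRateCurve:
    def _toy(self):
        rng = np.random.default_rng(41)
        rows = []
        for d in range(5):
            for c in range(4):
                rows.append((f"d{d}", f"c{c}", "t0",
                             rng.uniform(0.5, 3), rng.uniform(0, 1)))
        table = pd.DataFrame(rows, columns=["disease_id", "cell_type", "tissue",
                                            "score", "fdr"])
        gold = GoldPairs.from_triples([("d0", "c0", "t0"), ("d1", "c1", "t0"),
                                       ("d2", "c2", "t0")])
        return table, gold

    def test_endpoints(self):
        table, gold = self._toy()
        curve = error_rates_vs_threshold(table, gold, [0.0, 1.01],
                                         score_threshold=0.0)
        assert curve.iloc[0]["fpr"] == 0.0 and curve.iloc[0]["fnr"] == 1.0
        assert curve.iloc[-1]["fnr"] == 0.0  # everything predicted

    def test_matches_set_arithmetic_oracle(self):
        table, gold = self._toy()
        grid = np.linspace(0, 1, 21)
        curve = error_rates_vs_threshold(table, gold, grid, score_threshold=1.0)
        univ = set(map(tuple, table[["disease_id", "cell_type", "tissue"]]
                       .itertuples(index=False)))
        for t, row in zip(grid, curve.itertuples(index=False)):
            pred = {(r.disease_id, r.cell_type, r.tissue)
                    for r in table.itertuples(index=False)
                    if r.score >= 1.0 and r.fdr < t}
            assert row.fpr == pytest.approx(
                len(pred - gold.pairs) / len(univ - gold.pairs))
            assert row.fnr == pytest.approx(
                len(gold.pairs - pred) / len(gold.pairs))

    def test_monotone_in_threshold(self):
        table, gold = self._toy()
        curve = error_rates_vs_threshold(table, gold, np.linspace(0, 1, 50))
        assert (np.diff(curve["fpr"]) >= 0).all()
        assert (np.diff(curve["fnr"]) <= 0).all()

    def test_empty_gold_errors(self):
        table, _ = self._toy()
        with pytest.raises(ValueError, match="empty"):
            error_rates_vs_threshold(table, GoldPairs(frozenset()), [0.1])


class TestMatchedScoreCorrelation:
    def _tables(self, scores_a, scores_b, diseases):
        rows_a, rows_b = [], []
        for d in diseases:
            for c, s in scores_a[d].items():
                rows_a.append((d, c, "t0", s))
            for c, s in scores_b[d].items():
                rows_b.append((d, c, "t0", s))
        cols = ["disease_id", "cell_type", "tissue", "score"]
        return pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols)

    def test_identical_scores_give_r_one(self):
        rng = np.random.default_rng(42)
        diseases = [f"d{i}" for i in range(10)]
        scores = {d: {"a1": rng.normal(), "a2": rng.normal()} for d in diseases}
        ta, tb = self._tables(scores, scores, diseases)
        tb = tb.replace({"a1": "b1", "a2": "b2"})
        matches = pd.DataFrame({"cell_type_a": ["a1", "a2"],
                                "cell_type_b": ["b1", "b2"],
                                "matched": [True, True]})
        out = matched_score_correlation(ta, tb, matches).set_index("stratum")
        assert out.loc["matched", "spearman_r"] == pytest.approx(1.0)

    def test_shuffled_scores_decorrelate(self):
        rng = np.random.default_rng(43)
        diseases = [f"d{i}" for i in range(200)]
        sa = {d: {"a1": rng.normal()} for d in diseases}
        sb = {d: {"b1": rng.normal()} for d in diseases}  # independent
        ta, tb = self._tables(sa, sb, diseases)
        matches = pd.DataFrame({"cell_type_a": ["a1"], "cell_type_b": ["b1"],
                                "matched": [True]})
        out = matched_score_correlation(ta, tb, matches).set_index("stratum")
        assert abs(out.loc["matched", "spearman_r"]) < 0.2
        assert out.loc["matched", "n"] == 200

    def test_tie_heavy_vectors_match_midrank_oracle(self):
        xs = [1.0, 1.0, 2.0, 2.0, 3.0]
        ys = [1.0, 2.0, 2.0, 3.0, 3.0]
        diseases = [f"d{i}" for i in range(5)]
        ta, tb = self._tables({d: {"a1": x} for d, x in zip(diseases, xs)},
                              {d: {"b1": y} for d, y in zip(diseases, ys)},
                              diseases)
        matches = pd.DataFrame({"cell_type_a": ["a1"], "cell_type_b": ["b1"],
                                "matched": [True]})
        out = matched_score_correlation(ta, tb, matches).set_index("stratum")
        # midrank oracle: Pearson correlation of average ranks
        rx = [1.5, 1.5, 3.5, 3.5, 5.0]
        ry = [1.0, 2.5, 2.5, 4.5, 4.5]
        expected = st.pearsonr(rx, ry)[0]
        assert out.loc["matched", "spearman_r"] == pytest.approx(expected)

    def test_small_stratum_is_nan(self):
        diseases = ["d0", "d1"]
        ta, tb = self._tables({d: {"a1": 1.0} for d in diseases},
                              {d: {"b1": 2.0} for d in diseases}, diseases)
        matches = pd.DataFrame({"cell_type_a": ["a1"], "cell_type_b": ["b1"],
                                "matched": [True]})
        out = matched_score_correlation(ta, tb, matches).set_index("stratum")
        assert np.isnan(out.loc["matched", "spearman_r"])


class TestMatchingPermutation:
    def _matches(self, pairs, all_a, all_b):
        rows = [(a, b, a + b in pairs or (a, b) in pairs)
                for a in all_a for b in all_b]
        return pd.DataFrame(rows, columns=["cell_type_a", "cell_type_b", "matched"])

    def test_no_matches_gives_p_one(self):
        cts = [f"c{i}" for i in range(4)]
        matches = self._matches(set(), cts, cts)
        res = matching_permutation_test({"d0": ["c0"], "d1": ["c1"]},
                                        {"d0": ["c2"], "d1": ["c3"]},
                                        matches, cts, reps=100, seed=0)
        assert res.num_success == 0 and res.p_value == 1.0

    def test_saturated_matches_give_p_one(self):
        cts = [f"c{i}" for i in range(4)]
        matches = self._matches({(a, b) for a in cts for b in cts}, cts, cts)
        res = matching_permutation_test({"d0": ["c0"], "d1": ["c1"]},
                                        {"d0": ["c2"], "d1": ["c3"]},
                                        matches, cts, reps=100, seed=0)
        assert res.num_success == 2 and res.p_value == 1.0

    def test_exhaustive_equals_direct_enumeration(self):
        cts = [f"c{i}" for i in range(4)]
        matched_pairs = {("c0", "c0"), ("c1", "c1"), ("c2", "c3")}
        matches = self._matches(matched_pairs, cts, cts)
        likely_ref = {"d0": ["c0"], "d1": ["c1", "c2"], "d2": ["c3"]}
        likely_test = {"d0": ["c0"], "d1": ["c1"], "d2": ["c3"]}
        res = matching_permutation_test(likely_ref, likely_test, matches, cts,
                                        exhaustive=True)
        # oracle: enumerate every per-disease draw combination
        num_s = res.num_success
        per_disease = []
        for d, ref in likely_ref.items():
            k = len(ref)
            succ = []
            for draw in itertools.combinations(cts, k):
                succ.append(any((a, b) in matched_pairs
                                for a in draw for b in likely_test[d]))
            per_disease.append(succ)
        total, hits = 0, 0
        for combo in itertools.product(*per_disease):
            total += 1
            hits += sum(combo) >= num_s
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)
        # sampled agrees within Monte-Carlo error
        res_s = matching_permutation_test(likely_ref, likely_test, matches, cts,
                                          reps=4000, seed=1)
        assert res_s.p_value == pytest.approx(res.p_value, abs=0.05)

    def test_disease_without_likely_types_skipped(self):
        cts = ["c0", "c1"]
        matches = self._matches({("c0", "c0")}, cts, cts)
        res = matching_permutation_test({"d0": ["c0"], "d1": []},
                                        {"d0": ["c0"], "d1": ["c1"]},
                                        matches, cts, reps=50, seed=0)
        assert res.n_skipped == 1 and res.n_diseases == 1

    def test_seed_reproducibility(self):
        cts = [f"c{i}" for i in range(5)]
        matches = self._matches({("c0", "c0")}, cts, cts)
        args = ({"d0": ["c0", "c1"]}, {"d0": ["c0"]}, matches, cts)
        r1 = matching_permutation_test(*args, reps=200, seed=5)
        r2 = matching_permutation_test(*args, reps=200, seed=5)
        assert np.array_equal(r1.null, r2.null) and r1.p_value == r2.p_value

    def test_null_p_superuniform(self):
        """Random likely sets: exact p-values are (super-)uniform over 200
        simulated datasets."""
        rng = np.random.default_rng(44)
        cts = [f"c{i}" for i in range(8)]
        matched_pairs = {(f"c{i}", f"c{j}") for i in range(8) for j in range(8)
                         if (3 * i + j) % 5 == 0}
        matches = self._matches(matched_pairs, cts, cts)
        pvals = []
        for _ in range(200):
            ref = {f"d{i}": list(rng.choice(cts, size=rng.integers(1, 3),
                                            replace=False))
                   for i in range(6)}
            test = {f"d{i}": list(rng.choice(cts, size=rng.integers(1, 3),
                                             replace=False))
                    for i in range(6)}
            res = matching_permutation_test(ref, test, matches, cts,
                                            exhaustive=True)
            pvals.append(res.p_value)
        ks = st.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01
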