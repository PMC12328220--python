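"""Correlations, group tests, enrichment, ROC/AUC, BH adjustment."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from structcons.exceptions import UndefinedStatisticError
from structcons.stats import (bh_adjust, cliffs_delta, correlate, group_compare,
                              phenotype_split, quartile_enrichment,
                              roc_enrichment)


class TestCorrelate:
    def test_perfect_monotone(self):
        r = correlate([1, 2, 3], [1, 2, 3], "spearman")
        assert r.estimate == pytest.approx(1.0)
        t = correlate([1, 2, 3], [1, 2, 3], "kendall")
        assert t.estimate == pytest.approx(1.0)

    def test_reversed(self):
        r = correlate([1, 2, 3], [3, 2, 1], "spearman")
        assert r.estimate == pytest.approx(-1.0)

    def test_kendall_ties_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 4, size=12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            got = correlate(x, y, "kendall").estimate
            # tau-b with tie correction from explicit pair counts
            conc = disc = tx = ty = 0
            for i, j in itertools.combinations(range(len(x)), 2):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
            denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
            assert got == pytest.approx((conc - disc) / denom, abs=1e-12)

    def test_missing_pairs_dropped_and_counted(self):
        r = correlate([1, 2, np.nan, 4, 5], [2, 3, 9, np.nan, 10], "spearman")
        assert r.n == 3
        assert r.meta["n_missing"] == 2

    def test_constant_input_flagged(self):
        r = correlate([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r.estimate)
        assert r.meta["constant_input"]

    def test_small_n_exact_p_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r = correlate(x, y, "spearman")
        obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(abs(sps.spearmanr(x, p).statistic) >= obs - 1e-12
                    for p in itertools.permutations(y))
        assert r.p_value == pytest.approx(count / 120)


class TestGroupCompare:
    def test_complete_separation_delta(self):
        r = group_compare([1, 2, 3], [4, 5, 6])
        assert r.effect_size == -1.0

    def test_identical_groups_signed_rank_flagged(self):
        r = group_compare([1.0, 2, 3], [1.0, 2, 3], test="wilcoxon_signed_rank")
        assert r.effect_size == 0.0
        assert np.isnan(r.p_value)
        assert r.meta["all_zero_differences"]

    @pytest.mark.parametrize("seed", range(6))
    def test_delta_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 12))
        b = rng.normal(size=rng.integers(3, 12))
        explicit = sum(int(x > y) - int(x < y)
                       for x in a for y in b) / (len(a) * len(b))
        assert cliffs_delta(a, b) == pytest.approx(explicit, abs=1e-12)

    def test_delta_antisymmetric(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=8), rng.normal(size=5)
        assert cliffs_delta(a, b) == pytest.approx(-cliffs_delta(b, a))

    def test_mann_whitney_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        alpha, n_runs = 0.05, 200
        rejections = sum(
            group_compare(rng.normal(size=12), rng.normal(size=12)).p_value < alpha
            for _ in range(n_runs))
        se = np.sqrt(alpha * (1 - alpha) / n_runs)
        assert rejections / n_runs <= alpha + 3 * se


class TestQuartileEnrichment:
    def _values(self, n=20):
        return pd.Series(np.linspace(0, 1, n), index=[f"og{i}" for i in range(n)])

    def test_set_equal_to_top_quartile_is_extreme(self):
        v = self._values(20)
        top = set(v.sort_values().index[-5:])
        res = quartile_enrichment(v, {"set": top}, tail="top25")
        assert res[0].estimate == np.inf
        # p is the minimal achievable for this table: hypergeometric point mass
        from scipy.stats import hypergeom
        assert res[0].p_value == pytest.approx(hypergeom.pmf(5, 20, 5, 5))

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # 2x2 table [[3,1],[1,3]]: two-sided p by summing tables as extreme
        from scipy.stats import fisher_exact, hypergeom
        odds, p = fisher_exact([[3, 1], [1, 3]])
        pm = [hypergeom.pmf(k, 8, 4, 4) for k in range(5)]
        p_manual = sum(x for x in pm if x <= pm[3] + 1e-12)
        assert p == pytest.approx(p_manual)

    def test_null_sets_bh_false_positive_rate(self):
        rng = np.random.default_rng(3)
        n_runs, hits, total = 60, 0, 0
        for _ in range(n_runs):
            v = pd.Series(rng.normal(size=40),
                          index=[f"og{i}" for i in range(40)])
            membership = {f"s{k}": set(rng.choice(v.index, size=8, replace=False))
                          for k in range(5)}
            res = quartile_enrichment(v, membership)
            hits += sum(r.p_adjusted < 0.05 for r in res)
            total += len(res)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se

    def test_boundary_ties_included(self):
        v = pd.Series([1.0, 1, 1, 2, 2, 2, 3, 3, 3, 3],
                      index=[f"og{i}" for i in range(10)])
        res = quartile_enrichment(v, {"all3": {f"og{i}" for i in range(6, 10)}},
                                  tail="top25")
        a = res[0].meta["table"][0][0]
        assert a == 4  # every tied value at the boundary is in the tail


class TestRoc:
    def test_perfect_ranking(self):
        _f, _t, auc = roc_enrichment([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_auc_equals_pair_count_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, size=20).astype(bool)
            if labels.all() or not labels.any():
                continue
            _f, _t, auc = roc_enrichment(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            pairs = np.mean([(p > n) + 0.5 * (p == n)
                             for p in pos for n in neg])
            assert auc == pytest.approx(pairs, abs=1e-12)

    def test_shuffled_labels_auc_centred(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        aucs = []
        for _ in range(500):
            labels = np.zeros(40, dtype=bool)
            labels[rng.choice(40, size=20, replace=False)] = True
            aucs.append(roc_enrichment(scores, labels)[2])
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_symmetry_under_negated_ranking(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=25)
        labels = rng.integers(0, 2, size=25).astype(bool)
        labels[0] = True
        labels[1] = False
        a1 = roc_enrichment(scores, labels)[2]
        a2 = roc_enrichment(-scores, labels)[2]
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            roc_enrichment([1.0, 2.0], [1, 1])


class TestBH:
    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.02, 0.02, 0.02]), 0.02)

    def test_hand_evaluated_step_up(self):
        p = [0.01, 0.04, 0.03, 0.005]
        # sorted: .005, .01, .03, .04 -> m/i scaled: .02, .02, .04, .04
        expected = [0.02, 0.04, 0.04, 0.02]
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_bounds_property(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()


class TestPhenotypeSplit:
    def _cr_table(self, rng, n_og=30, effect=0.0):
        rows = []
        species = [f"sp{i}" for i in range(8)]
        for og in range(n_og):
            base = rng.uniform(0.4, 0.8)
            for k, sp in enumerate(species):
                shift = effect if k < 4 else 0.0
                rows.append({"og_id": f"og{og}", "species": sp,
                             "cr": base + shift + rng.normal(scale=0.05)})
        pheno = {f"sp{i}": ("yes" if i < 4 else "no") for i in range(8)}
        return pd.DataFrame(rows), pheno

    def test_single_og_delta(self):
        df = pd.DataFrame({
            "og_id": ["og0"] * 4,
            "species": ["a", "b", "c", "d"],
            "cr": [0.8, 0.8, 0.6, 0.6]})
        pheno = {"a": "yes", "b": "yes", "c": "no", "d": "no"}
        table, _res = phenotype_split(df, pheno)
        assert table.loc[0, "delta_cr"] == pytest.approx(0.2)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            df, pheno = self._cr_table(rng, n_og=15)
            _t, res = phenotype_split(df, pheno)
            ps.append(res.p_value)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(13)
        detected = 0
        n_runs = 40
        for _ in range(n_runs):
            df, pheno = self._cr_table(rng, n_og=50, effect=0.05)
            _t, res = phenotype_split(df, pheno)
            detected += res.p_value < 0.05
        assert detected >= 0.95 * n_runs

    def test_variable_species_excluded(self):
        df = pd.DataFrame({"og_id": ["og0"] * 3, "species": ["a", "b", "c"],
                           "cr": [0.9, 0.5, 0.1]})
        pheno = {"a": "yes", "b": "no", "c": "variable"}
        with pytest.raises(UndefinedStatisticError):
            phenotype_split(df, pheno)  # <2 species per subgroup
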