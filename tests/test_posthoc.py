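import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from etiohet.posthoc import (
    GeneSetCollection,
    SurvivalData,
    align_labels,
    congruence_test,
    gsea_competitive,
    mutation_association,
    read_gmt,
    risk_profile_table,
    survival_summary,
)
from etiohet.prep import GenomicMatrix
from etiohet.riskmetrics import RiskFactorTable

from conftest import make_risk_table


class TestRiskProfileTable:
    def test_single_subtype_equals_marginals(self):
        risk = make_risk_table(30, seed=1)
        tab = risk_profile_table(np.zeros(30, dtype=int), risk)
        smoking = tab[tab.factor == "smoking"].set_index("level")["subtype_0"]
        marginal = risk.data["smoking"].value_counts(normalize=True) * 100
        for level in ["never", "former", "current"]:
            assert smoking[level] == pytest.approx(marginal.get(level, 0.0))

    def test_toy_counts_exact(self):
        df = pd.DataFrame({
            "hypertension": ["yes", "yes", "no", "no", "no", "yes"],
        }, index=[f"c{i}" for i in range(6)])
        risk = RiskFactorTable(df, {"hypertension": ["no", "yes"]})
        labels = np.array([0, 0, 0, 1, 1, 1])
        tab = risk_profile_table(labels, risk).set_index("level")
        assert tab.loc["yes", "subtype_0"] == pytest.approx(100 * 2 / 3)
        assert tab.loc["no", "subtype_1"] == pytest.approx(100 * 2 / 3)

    def test_percentages_sum_to_100(self):
        risk = make_risk_table(50, seed=2)
        labels = np.random.default_rng(0).integers(0, 3, 50)
        tab = risk_profile_table(labels, risk)
        for factor in risk.categorical:
            sub = tab[tab.factor == factor]
            for col in [c for c in tab.columns if c.startswith("subtype_")]:
                assert sub[col].sum() == pytest.approx(100.0)

    def test_continuous_summarized_by_median(self):
        risk = make_risk_table(40, seed=3)
        labels = np.repeat([0, 1], 20)
        tab = risk_profile_table(labels, risk).set_index("factor")
        age0 = np.median(risk.data["age"].to_numpy()[:20])
        assert tab.loc["age", "subtype_0"] == pytest.approx(age0)


class TestMutationAssociation:
    def test_identical_proportions_p_one(self):
        labels = np.repeat([0, 1], 4)
        muts = pd.DataFrame({"g": [1, 1, 0, 0, 1, 1, 0, 0]})
        tab = mutation_association(labels, muts)
        assert tab.p_value[0] == pytest.approx(1.0)
        assert tab.test[0] == "fisher"

    def test_perfect_separation_exact_p(self):
        # 2x2 table [[5,0],[0,5]] -> two-sided hypergeometric p = 2/252
        labels = np.repeat([0, 1], 5)
        muts = pd.DataFrame({"g": [1] * 5 + [0] * 5})
        tab = mutation_association(labels, muts)
        assert tab.p_value[0] == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        # brute-force two-sided Fisher by enumerating the hypergeometric support
        for _ in range(20):
            n0, n1 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            k = int(rng.integers(1, n0 + n1))
            a = int(rng.integers(max(0, k - n1), min(k, n0) + 1))
            table = np.array([[a, n0 - a], [k - a, n1 - (k - a)]])
            _, p_scipy = stats.fisher_exact(table)
            hg = stats.hypergeom(n0 + n1, n0, k)
            support = np.arange(max(0, k - n1), min(k, n0) + 1)
            probs = hg.pmf(support)
            p_brute = probs[probs <= hg.pmf(a) * (1 + 1e-9)].sum()
            assert p_scipy == pytest.approx(p_brute, rel=1e-7)

    def test_percentages_recompute_counts(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        muts = pd.DataFrame({"g": rng.integers(0, 2, 40)})
        tab = mutation_association(labels, muts)
        for cls in (0, 1):
            n_j = (labels == cls).sum()
            stored = muts["g"].to_numpy()[labels == cls].sum()
            assert round(tab[f"subtype_{cls}_pct"][0] * n_j / 100) == stored

    def test_all_zero_gene_untested(self):
        labels = np.repeat([0, 1], 5)
        muts = pd.DataFrame({"g": [0] * 10})
        tab = mutation_association(labels, muts)
        assert tab.test[0] == "untested"
        assert np.isnan(tab.p_value[0])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            mutation_association(np.array([0, 1]), pd.DataFrame({"g": [2, 0]}))


class TestAlignLabels:
    def test_identical_labelings(self, rng):
        labels = rng.integers(0, 4, 50)
        res = align_labels(labels, labels)
        np.testing.assert_array_equal(res.alignment, np.arange(4))
        assert res.congruent == 50

    def test_small_confusion_hand_example(self):
        # confusion [[5,0],[1,4]] -> identity alignment, congruent 9
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0] * 5 + [0] + [1] * 4)
        res = align_labels(a, b)
        np.testing.assert_array_equal(res.confusion, [[5, 0], [1, 4]])
        assert res.congruent == 9

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_matches_brute_force_over_permutations(self, m, rng):
        for _ in range(50):
            conf = rng.integers(0, 20, size=(m, m))
            # build label vectors realizing this confusion matrix
            a = np.repeat(np.arange(m), conf.sum(axis=1))
            b = np.concatenate([np.repeat(np.arange(m), conf[j]) for j in range(m)])
            if len(a) == 0:
                continue
            res = align_labels(a, b)
            brute = max(sum(conf[j, perm[j]] for j in range(m))
                        for perm in itertools.permutations(range(m)))
            assert res.congruent == brute

    def test_rectangular_padded_with_dummy_classes(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 0, 1, 1, 1, 1])
        res = align_labels(a, b)
        assert res.confusion.shape == (3, 3)
        # best achievable: classes 0 and one of {1, 2} matched
        assert res.congruent == 4


class TestCongruenceTest:
    def test_expected_random_hand_value(self):
        # marginals a=(5,5), b=(6,4): expected = (5*6 + 5*4)/10 = 5
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0] * 6 + [1] * 4)
        res = congruence_test(a, b, B=19, seed=0)
        assert res.expected_random == pytest.approx(5.0)

    def test_permuted_copy_gives_min_p(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 60)
        b = np.array([1, 2, 0])[a]  # a fixed relabeling of a
        res = congruence_test(a, b, B=99, seed=1)
        assert res.congruent == 60
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_p_valid(self):
        # independent labelings: p is a valid (possibly conservative due to
        # heavy discreteness of the congruence count) permutation p-value
        ps = []
        for rep in range(60):
            rng = np.random.default_rng(100 + rep)
            a = rng.integers(0, 3, 60)
            b = rng.integers(0, 3, 60)
            ps.append(congruence_test(a, b, B=39, seed=rep).p_value)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se
        assert ps.std() > 0.05  # not degenerate


def exact_ranksum_p(in_ranks, all_ranks):
    """Two-sided rank-sum p by full enumeration of subset rank sums."""
    k = len(in_ranks)
    observed = sum(in_ranks)
    sums = [sum(c) for c in itertools.combinations(all_ranks, k)]
    lo = sum(1 for s in sums if s <= observed)
    hi = sum(1 for s in sums if s >= observed)
    return min(1.0, 2 * min(lo, hi) / len(sums))


class TestGseaCompetitive:
    def _matrix(self, t_means, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per
        labels = np.repeat([0, 1], n_per)
        X = rng.normal(size=(n, len(t_means))) * 0.5
        for j, mu in enumerate(t_means):
            X[labels == 1, j] += mu
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                          columns=[f"g{j}" for j in range(len(t_means))])
        return GenomicMatrix(df, "expression"), labels

    def test_flat_gene_t_zero(self):
        X = pd.DataFrame({"g0": [1.0, 1.0, 1.0, 1.0], "g1": [0.0, 1.0, 2.0, 3.0]},
                         index=["a", "b", "c", "d"])
        M = GenomicMatrix(X, "expression")
        labels = np.array([0, 0, 1, 1])
        t, _ = stats.ttest_ind(X.to_numpy()[:2], X.to_numpy()[2:], axis=0)
        assert np.isnan(t[0]) or t[0] == 0  # constant gene

    def test_top2_of_5_exact_p(self):
        # set = the two most differential genes of 5 -> exact two-sided p
        M, labels = self._matrix([4.0, 3.5, 0.0, 0.0, 0.0], seed=1)
        sets = GeneSetCollection({"top": frozenset({"g0", "g1"})})
        tab = gsea_competitive(M, labels, sets)
        p = tab[tab.subtype == 1].p_value.iloc[0]
        assert p == pytest.approx(0.2, rel=1e-9)  # 2/C(5,2)

    def test_matches_exact_enumeration(self, rng):
        for rep in range(10):
            n_genes = int(rng.integers(6, 10))
            mus = rng.normal(0, 2, n_genes)
            M, labels = self._matrix(mus.tolist(), seed=200 + rep)
            members = rng.choice(n_genes, size=int(rng.integers(2, n_genes - 1)),
                                 replace=False)
            sets = GeneSetCollection({"s": frozenset(f"g{j}" for j in members)})
            tab = gsea_competitive(M, labels, sets)
            t, _ = stats.ttest_ind(M.to_array()[labels == 0],
                                   M.to_array()[~(labels == 0)], axis=0,
                                   equal_var=False)
            ranks = stats.rankdata(t)
            in_set = np.isin(np.arange(n_genes), members)
            p_exact = exact_ranksum_p(ranks[in_set].tolist(), ranks.tolist())
            p_pkg = tab[tab.subtype == 0].p_value.iloc[0]
            assert p_pkg == pytest.approx(p_exact, rel=1e-9)

    def test_invariant_to_gene_order(self, rng):
        M, labels = self._matrix([2.0, 1.0, 0.0, -1.0, 0.5], seed=3)
        perm = rng.permutation(5)
        M2 = GenomicMatrix(M.values.iloc[:, perm], "expression")
        sets = GeneSetCollection({"s": frozenset({"g0", "g3"})})
        t1 = gsea_competitive(M, labels, sets)
        t2 = gsea_competitive(M2, labels, sets)
        np.testing.assert_allclose(t1.p_value.to_numpy(), t2.p_value.to_numpy())

    def test_set_with_empty_complement_rejected(self):
        M, labels = self._matrix([1.0, 0.0], seed=4)
        sets = GeneSetCollection({"all": frozenset({"g0", "g1"})})
        with pytest.raises(ValueError, match="testable"):
            gsea_competitive(M, labels, sets)


class TestGmtReader:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg2\n")
        coll = read_gmt(path)
        assert coll.sets["SET_A"] == frozenset({"g1", "g2", "g3"})
        assert coll.sets["SET_B"] == frozenset({"g2"})

    def test_size_filter(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("A\td\tg1\nB\td\tg1\tg2\tg3\n")
        coll = read_gmt(path).filter_sizes(min_size=2)
        assert list(coll.sets) == ["B"]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("JUSTNAME\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)


class TestSurvivalSummary:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 20) + 0.01
        e = rng.integers(0, 2, 20)
        if e.sum() == 0:
            e[0] = 1
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        labels = np.repeat([0, 1], 20)
        res = survival_summary(labels, SurvivalData(time=time, event=event))
        assert res["logrank_stat"] == pytest.approx(0.0, abs=1e-9)
        assert res["logrank_p"] == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separation_c_index_one(self):
        time = np.concatenate([np.linspace(1, 2, 10), np.linspace(5, 6, 10)])
        event = np.ones(20, dtype=int)
        labels = np.repeat([0, 1], 20 // 2)
        res = survival_summary(labels, SurvivalData(time=time, event=event))
        assert res["c_index"] == pytest.approx(1.0)

    def test_single_group_convention(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])
        res = survival_summary(np.zeros(3, dtype=int),
                               SurvivalData(time=time, event=event))
        assert res["c_index"] == 0.5
        assert res["logrank_p"] == 1.0

    def test_km_curves_are_valid_step_functions(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(2, 30) + 0.01
        event = rng.integers(0, 2, 30)
        event[0] = 1
        labels = rng.integers(0, 2, 30)
        res = survival_summary(labels, SurvivalData(time=time, event=event))
        for curve in res["curves"].values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_requires_event(self):
        with pytest.raises(ValueError, match="event"):
            survival_summary(np.array([0, 1]),
                             SurvivalData(time=np.array([1.0, 2.0]),
                                          event=np.array([0, 0])))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalData(time=np.array([0.0, 1.0]), event=np.array([1, 1]))
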