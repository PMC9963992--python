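"""Rank-median features, F-ratio selection, metric kernel and both classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ictosig.ml import (
    DEFAULT_MODEL_GRID,
    FRatioSelector,
    SharedSignatureClassifier,
    classification_metrics,
    concordance_auc,
    f_value_select,
    f_values,
    loocv_shared_feature,
    ovr_nested_cv,
    rank_median_standardize,
    tool_sharing_feature,
)
from ictosig.types import Category

from conftest import make_set, random_gene_set

UNIVERSE = np.array([f"g{i}" for i in range(500)], dtype=object)


def random_counts(rng, genes, n_rep=4, lam=20):
    return pd.DataFrame(rng.poisson(lam, (len(genes), n_rep)), index=genes)


class TestRankMedianFeatures:
    def test_monotone_transform_of_a_sample_leaves_features_unchanged(self, rng):
        genes = [f"g{i}" for i in range(30)]
        c1 = random_counts(rng, genes)
        c2 = random_counts(rng, genes)
        fm_a = rank_median_standardize({"a": c1, "b": c2})
        fm_b = rank_median_standardize({"a": c1 ** 3, "b": c2})
        assert np.allclose(fm_a.values.to_numpy(), fm_b.values.to_numpy())

    def test_identical_compounds_have_identical_rows(self, rng):
        genes = [f"g{i}" for i in range(30)]
        c = random_counts(rng, genes)
        other = random_counts(rng, genes)
        fm = rank_median_standardize({"a": c, "b": c.copy(), "c": other})
        assert np.allclose(fm.values.loc["a"], fm.values.loc["b"])

    def test_matches_brute_force_rank_median_zscore(self, rng):
        genes = [f"g{i}" for i in range(50)]
        counts = {f"c{k}": random_counts(rng, genes, n_rep=3) for k in range(3)}
        fm = rank_median_standardize(counts)
        med = {}
        for cid, m in counts.items():
            ranks = np.column_stack(
                [stats.rankdata(m.iloc[:, j]) for j in range(m.shape[1])]
            )
            med[cid] = np.median(ranks, axis=1)
        raw = pd.DataFrame(med).T
        raw.columns = genes
        keep = raw.std(axis=0, ddof=0) > 0
        z = (raw.loc[:, keep] - raw.loc[:, keep].mean()) / raw.loc[:, keep].std(ddof=0)
        assert np.allclose(fm.values.to_numpy(), z.to_numpy())
        cols = fm.values.to_numpy()
        assert np.allclose(cols.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(cols.var(axis=0), 1, atol=1e-6)

    def test_inconsistent_gene_index_names_compound(self, rng):
        a = random_counts(rng, [f"g{i}" for i in range(10)])
        b = random_counts(rng, [f"h{i}" for i in range(10)])
        with pytest.raises(ValueError, match="bad"):
            rank_median_standardize({"ok": a, "bad": b})


class TestFRatio:
    def test_perfect_separation_is_infinite_and_ranked_first(self):
        X = np.array([[0, 5.0], [0, 6.0], [1, 7.0], [1, 8.0]])
        y = np.array(["a", "a", "b", "b"])
        F = f_values(X, y)
        assert np.isinf(F[0])
        sel = FRatioSelector(k=1).fit(X, y)
        assert sel.support_.tolist() == [True, False]

    def test_identical_group_means_score_zero(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        assert f_values(X, y)[0] == 0.0

    def test_matches_brute_force_definition(self, rng):
        X = rng.normal(0, 1, (12, 20))
        y = np.repeat(["a", "b", "c"], 4)
        F = f_values(X, y)
        for j in range(20):
            means = [X[y == g, j].mean() for g in "abc"]
            wvars = [X[y == g, j].var(ddof=1) for g in "abc"]
            expected = np.var(means, ddof=1) / np.mean(wvars)
            assert F[j] == pytest.approx(expected, rel=1e-12)
        from ictosig.ml import FeatureMatrix
        fm = FeatureMatrix(
            values=pd.DataFrame(X, columns=[f"f{j}" for j in range(20)]),
            provenance="test", labels=pd.Series(y),
        )
        top5 = f_value_select(fm, k=5)
        order = np.argsort(-F, kind="stable")[:5]
        assert set(top5.values.columns) == {f"f{j}" for j in order}

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(0, 1, (8, 4))
        y = np.repeat(["a", "b"], 4)
        with pytest.raises(ValueError, match="k="):
            FRatioSelector(k=9).fit(X, y)


class TestMetricKernel:
    def test_reported_confusion_arithmetic(self):
        y = [1] * 13 + [0] * 10
        pred = [1] * 10 + [0] * 3 + [0] * 10
        rep = classification_metrics(y, pred)
        assert rep.accuracy == pytest.approx(20 / 23)
        assert round(rep.accuracy, 2) == 0.87
        assert rep.sensitivity == pytest.approx(10 / 13)
        assert round(rep.sensitivity, 2) == 0.77
        assert rep.specificity == 1.0
        assert rep.nir == pytest.approx(13 / 23)
        assert round(rep.nir, 2) == 0.57

    def test_binomial_p_behaviour_at_and_above_nir(self):
        y = [1] * 13 + [0] * 10
        at_nir = classification_metrics(y, [1] * 13 + [1] * 10)
        assert at_nir.binom_p > 0.5
        perfect = classification_metrics(y, y)
        assert perfect.binom_p < 0.01

    def test_perfect_scores_give_auc_one(self):
        rep = classification_metrics([0, 0, 1, 1], [0, 0, 1, 1],
                                     scores=[0.1, 0.2, 0.8, 0.9])
        assert rep.auc == 1.0

    def test_concordance_equals_trapezoidal_roc(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(0, 1, 40)
            assert concordance_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_random_scores_have_mean_auc_half(self, rng):
        aucs = []
        y = np.array([1] * 10 + [0] * 10)
        for _ in range(1000):
            aucs.append(concordance_auc(rng.normal(0, 1, 20), y))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_flagged_degenerate(self):
        rep = classification_metrics([1, 1], [1, 0], scores=[0.9, 0.1])
        assert rep.degenerate and np.isnan(rep.auc)


class TestSharedFeature:
    def test_counts_tools_sharing_an_up_gene(self):
        tools = [make_set(f"t{i}", up={f"u{i}", "common"}) for i in range(11)]
        c = make_set("x", up={"common"})
        assert tool_sharing_feature(c, tools) == 11
        assert tool_sharing_feature(make_set("e"), tools) == 0

    def test_matches_brute_force_on_random_panel(self, rng):
        tools = [random_gene_set(rng, f"t{i}", UNIVERSE, 40, 40) for i in range(6)]
        for _ in range(10):
            c = random_gene_set(rng, "c", UNIVERSE, 40, 40)
            brute = sum(1 for t in tools if len(c.up & t.up) >= 1)
            assert tool_sharing_feature(c, tools) == brute

    def test_downregulated_sharing_does_not_count(self):
        tools = [make_set("t", up={"a"}, down={"b"})]
        assert tool_sharing_feature(make_set("x", down={"b"}), tools) == 0


class TestLoocvSharedFeature:
    def make_separable_panel(self):
        tools = [
            make_set(f"t{i}", up={f"sig{i}_{j}" for j in range(5)},
                     category=Category.TOOL)
            for i in range(6)
        ]
        positives = [
            make_set(f"p{i}", up={f"sig{k}_0" for k in range(6)} | {f"own{i}"},
                     category=Category.FAERS_POSITIVE)
            for i in range(4)
        ]
        negatives = [
            make_set(f"n{i}", up={f"noise{i}_{j}" for j in range(4)},
                     category=Category.FAERS_NEGATIVE)
            for i in range(4)
        ]
        return positives, negatives, tools

    def test_perfect_separation_gives_unit_accuracy_and_auc(self):
        pos, neg, tools = self.make_separable_panel()
        rep = loocv_shared_feature(pos, neg, tools)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_invariant_to_compound_ordering(self):
        pos, neg, tools = self.make_separable_panel()
        a = loocv_shared_feature(pos, neg, tools)
        b = loocv_shared_feature(pos[::-1], neg[::-1], tools[::-1])
        assert a.to_dict() == b.to_dict()

    def test_degenerate_identical_features_flagged(self):
        tools = [make_set("t", up={"z"}, category=Category.TOOL)]
        pos = [make_set(f"p{i}", up={f"a{i}"}, category=Category.FAERS_POSITIVE)
               for i in range(2)]
        neg = [make_set(f"n{i}", up={f"b{i}"}, category=Category.FAERS_NEGATIVE)
               for i in range(2)]
        rep = loocv_shared_feature(pos, neg, tools)
        assert rep.degenerate and rep.auc == 0.5

    def test_too_few_compounds_rejected(self):
        pos, neg, tools = self.make_separable_panel()
        with pytest.raises(ValueError, match=">= 2"):
            loocv_shared_feature(pos[:1], neg, tools)

    def test_estimator_probabilities_track_feature(self):
        pos, neg, tools = self.make_separable_panel()
        clf = SharedSignatureClassifier(tools=tools, negatives=neg)
        y = [1] * len(pos) + [0] * len(neg)
        clf.fit(pos + neg, y)
        proba = clf.predict_proba(pos + neg)[:, 1]
        assert proba[: len(pos)].min() > proba[len(pos):].max()


SMALL_GRID = (
    {"model": "lr", "penalty": "l2", "C": 1.0, "k": None},
    {"model": "svm", "kernel": "linear", "C": 1.0, "k": 10},
)


class TestOvrNestedCV:
    def planted_features(self, rng, n_signal=10):
        from ictosig.ml import FeatureMatrix

        n, d = 18, 40
        X = rng.normal(0, 1, (n, d))
        labels = np.array(["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        X[labels == "A", :n_signal] += 2.5
        return FeatureMatrix(
            values=pd.DataFrame(X, index=[f"c{i}" for i in range(n)]),
            provenance="test",
            labels=pd.Series(labels, index=[f"c{i}" for i in range(n)]),
        )

    def test_planted_target_signature_is_detected(self, rng):
        fm = self.planted_features(rng)
        rep = ovr_nested_cv(fm, "A", outer_reps=1, seed=0, model_grid=SMALL_GRID)
        assert rep.auc >= 0.9

    def test_same_seed_identical_report(self, rng):
        fm = self.planted_features(rng)
        a = ovr_nested_cv(fm, "A", seed=3, model_grid=SMALL_GRID)
        b = ovr_nested_cv(fm, "A", seed=3, model_grid=SMALL_GRID)
        assert a.to_dict() == b.to_dict()

    def test_label_permutation_collapses_auc(self):
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            fm = self.planted_features(rng, n_signal=0)  # pure noise
            rep = ovr_nested_cv(fm, "A", seed=seed, model_grid=SMALL_GRID)
            aucs.append(rep.auc)
        assert 0.3 <= float(np.median(aucs)) <= 0.7

    def test_single_member_target_group_rejected(self, rng):
        from ictosig.ml import FeatureMatrix

        X = rng.normal(0, 1, (6, 5))
        fm = FeatureMatrix(
            values=pd.DataFrame(X),
            provenance="test",
            labels=pd.Series(["A"] + ["B"] * 5),
        )
        with pytest.raises(ValueError, match="target group"):
            ovr_nested_cv(fm, "A", model_grid=SMALL_GRID)
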