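"""Enrichment-score walk, permutation NES, and the compound GSEA score."""

import subprocess
import textwrap

import numpy as np
import pytest

from ictosig.gsea import (
    GseaScoreClassifier,
    _hit_walk_extrema,
    _hit_weights,
    build_ranked_list,
    direction_gene_sets,
    enrichment_score,
    gsea_preranked,
    gsea_score,
)
from ictosig.types import Category, RankedList

from conftest import make_profile, make_set


def brute_force_es(genes, scores, gene_set, weight=1.0):
    """Independent step-by-step running-sum walk."""
    hits = [g in gene_set for g in genes]
    nh = sum(hits)
    n = len(genes)
    S = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, walk = 0.0, []
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** weight) / S if S > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        walk.append(run)
    return max(walk, key=abs)


def random_ranked(rng, n=100, prefix="g"):
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    genes = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    return RankedList("T", genes, scores)


class TestRankedList:
    def test_signed_log_p_scoring_and_order(self):
        prof = make_profile("t", {
            "g1": (1.0, 1e-4, 1e-3),
            "g2": (-1.0, 1e-4, 1e-3),
            "g3": (0.5, 0.5, 0.6),
        })
        rl = build_ranked_list(prof)
        assert list(rl.genes) == ["g1", "g3", "g2"]
        assert rl.scores == pytest.approx([4.0, np.log10(2), -4.0], abs=1e-9)

    def test_row_order_invariance(self):
        rows = {f"g{i}": (i % 3 - 1.0 or 0.5, 0.01 * (i + 1), 0.05) for i in range(9)}
        a = build_ranked_list(make_profile("t", rows))
        shuffled = dict(reversed(list(rows.items())))
        b = build_ranked_list(make_profile("t", shuffled))
        assert list(a.genes) == list(b.genes)

    def test_all_zero_log2fc_is_an_error(self):
        prof = make_profile("t", {"g1": (0.0, 0.01, 0.02)})
        with pytest.raises(ValueError, match="direction"):
            build_ranked_list(prof)

    def test_single_gene_list(self):
        rl = build_ranked_list(make_profile("t", {"g1": (2.0, 0.01, 0.02)}))
        assert len(rl) == 1 and rl.scores[0] > 0


class TestDirectionSets:
    def test_up_only_set_is_single_record(self):
        recs = direction_gene_sets(make_set("x", up={"a", "b", "c"}))
        assert len(recs) == 1 and recs[0]["direction"] == "up"
        assert recs[0]["eligible"]

    def test_min_size_boundary_is_inclusive(self):
        recs = direction_gene_sets(make_set("x", up={"a", "b", "c"}), min_size=3)
        assert recs[0]["eligible"]
        recs = direction_gene_sets(make_set("x", up={"a", "b"}), min_size=3)
        assert not recs[0]["eligible"]

    def test_empty_compound_yields_no_sets(self):
        assert direction_gene_sets(make_set("x")) == []


class TestEnrichmentScore:
    def test_all_hit_degenerate_set_scores_one(self, rng):
        rl = random_ranked(rng, 30)
        es, _ = enrichment_score(rl, set(rl.genes))
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_absent_gene_set_is_an_error(self, rng):
        rl = random_ranked(rng, 20)
        with pytest.raises(ValueError, match="absent"):
            enrichment_score(rl, {"zzz"})

    def test_matches_brute_force_walk(self, rng):
        for _ in range(25):
            rl = random_ranked(rng, 100)
            genes = set(rng.choice(rl.genes, size=10, replace=False))
            for w in (0.0, 1.0, 1.5):
                es, _ = enrichment_score(rl, genes, weight=w)
                assert es == pytest.approx(
                    brute_force_es(rl.genes, rl.scores, genes, w), abs=1e-12
                )

    def test_top_k_unweighted_set_walks_to_plus_one_region(self, rng):
        rl = random_ranked(rng, 50)
        genes = set(rl.genes[:5])
        es, _ = enrichment_score(rl, genes, weight=0.0)
        assert es == pytest.approx(1.0 - 0.0, abs=1e-12)

    def test_sign_reversal_negates_es(self, rng):
        rl = random_ranked(rng, 60)
        flipped = RankedList("T", rl.genes[::-1].copy(), (-rl.scores[::-1]).copy())
        genes = set(rng.choice(rl.genes, size=8, replace=False))
        es, _ = enrichment_score(rl, genes)
        es_f, _ = enrichment_score(flipped, genes)
        assert es_f == pytest.approx(-es, abs=1e-12)

    def test_closed_form_extrema_equal_full_walk(self, rng):
        rl = random_ranked(rng, 80)
        abs_w = np.abs(rl.scores)
        for _ in range(20):
            k = int(rng.integers(3, 15))
            idx = np.sort(rng.choice(80, size=k, replace=False))
            genes = set(rl.genes[idx])
            es_walk, _ = enrichment_score(rl, genes)
            hit_pos = idx[None, :]
            w = _hit_weights(abs_w, hit_pos)
            es_closed = _hit_walk_extrema(hit_pos, w, 80)[0]
            assert es_closed == pytest.approx(es_walk, abs=1e-12)

    def test_matches_fgsea_reference_implementation(self, rng, tmp_path):
        rl = random_ranked(rng, 50)
        idx = np.sort(rng.choice(50, size=6, replace=False)) + 1  # 1-based
        np.savetxt(tmp_path / "stats.txt", rl.scores)
        np.savetxt(tmp_path / "sel.txt", idx, fmt="%d")
        rcode = textwrap.dedent(f"""
            suppressMessages(library(fgsea))
            stats <- scan('{tmp_path}/stats.txt', quiet=TRUE)
            sel <- scan('{tmp_path}/sel.txt', quiet=TRUE)
            cat(sprintf('%.12f', calcGseaStat(stats, selectedStats=sel, gseaParam=1)))
        """)
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        es_r = float(out.stdout.strip())
        es_py, _ = enrichment_score(rl, set(rl.genes[idx - 1]))
        assert es_py == pytest.approx(es_r, abs=1e-9)


class TestPrerankedGsea:
    def test_same_seed_reproduces_results(self, rng):
        rl = random_ranked(rng, 200)
        sets = [("s1", set(rl.genes[:10])), ("s2", set(rl.genes[50:70]))]
        a = gsea_preranked(rl, sets, n_perm=200, seed=5)
        b = gsea_preranked(rl, sets, n_perm=200, seed=5)
        assert [(r.nes, r.pvalue, r.padj) for r in a] == [
            (r.nes, r.pvalue, r.padj) for r in b
        ]

    def test_p_floor_and_bh_ordering(self, rng):
        rl = random_ranked(rng, 500)
        res = gsea_preranked(rl, [("top", set(rl.genes[:20]))], n_perm=500, seed=1)[0]
        assert res.pvalue >= 1.0 / (1 + 500)
        assert res.padj >= res.pvalue
        assert np.sign(res.nes) == np.sign(res.es)

    def test_planted_top_set_is_significant_and_positive(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rl = random_ranked(rng, 1000)
            res = gsea_preranked(
                rl, [("planted", set(rl.genes[:20]))], n_perm=500, seed=seed
            )[0]
            hits += (res.padj < 0.05) and (res.nes > 0)
        assert hits >= 9

    def test_too_small_n_perm_and_oversized_set_rejected(self, rng):
        rl = random_ranked(rng, 20)
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(rl, [("s", set(rl.genes[:3]))], n_perm=50)
        with pytest.raises(ValueError, match="larger"):
            gsea_preranked(rl, [("s", {f"x{i}" for i in range(30)})], n_perm=100)


class TestGseaScore:
    def make_tool_profile(self, rng, n=400):
        rows = {}
        for i in range(n):
            p = 10 ** rng.uniform(-8, 0)
            lfc = rng.normal(0, 2) or 0.5
            rows[f"g{i}"] = (lfc, p, min(1.0, 2 * p))
        return make_profile("TOOLX", rows, category=Category.TOOL)

    def test_disjoint_compound_scores_zero(self, rng):
        tool = self.make_tool_profile(rng)
        test = make_set("x", up={"zz1", "zz2", "zz3"})
        res = gsea_score(test, [tool], n_perm=200, seed=0)
        assert res.score == 0.0 and res.n_significant_sets == 0

    def test_empty_compound_flagged_not_calculable(self, rng):
        tool = self.make_tool_profile(rng)
        res = gsea_score(make_set("x"), [tool], n_perm=200, seed=0)
        assert not res.calculable and res.score == 0.0

    def test_planted_top_up_genes_recover_their_tool(self, rng):
        tool = self.make_tool_profile(rng)
        rl = build_ranked_list(tool)
        planted = set(rl.genes[:25])
        found = 0
        for seed in range(5):
            res = gsea_score(make_set("x", up=planted), [tool],
                             n_perm=500, seed=seed)
            contributing_tools = {t for t, _, _ in res.contributors}
            found += res.score > 0 and "TOOLX" in contributing_tools
        assert found == 5

    def test_score_additivity_over_contributors(self, rng):
        tool = self.make_tool_profile(rng)
        rl = build_ranked_list(tool)
        test = make_set("x", up=set(rl.genes[:25]), down=set(rl.genes[-25:]))
        res = gsea_score(test, [tool], n_perm=500, seed=2)
        assert res.score == pytest.approx(
            sum(abs(nes) for _, _, nes in res.contributors), abs=1e-9
        )

    def test_classifier_wrapper_matches_function(self, rng):
        tool = self.make_tool_profile(rng)
        test = make_set("x", up=set(f"g{i}" for i in range(20)))
        clf = GseaScoreClassifier(n_perm=200, seed=3).fit([tool])
        direct = gsea_score(test, [build_ranked_list(tool)], n_perm=200, seed=3)
        assert clf.decision_function([test])[0] == pytest.approx(direct.score)
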