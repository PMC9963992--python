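"""Self-contained preranked gene-set enrichment analysis (GSEA).

Implements the weighted Kolmogorov–Smirnov running-sum enrichment score,
a gene-permutation null for the normalized enrichment score (NES), and
Benjamini–Hochberg adjustment, plus the compound-level *GSEA score*: for a
test compound, its up- and downregulated DE gene sets are tested against
the signed ranked list of every tool compound, and the absolute NES values
of the significant (adjusted p < alpha) set×list pairs are summed.
"""

from __future__ import annotations

import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .de import bh_adjust
from .similarity import negative_noise_union, subtract_noise
from .types import CompoundProfile, DEGeneSet, GseaResult, GseaScore, RankedList

__all__ = [
    "build_ranked_list",
    "direction_gene_sets",
    "enrichment_score",
    "gsea_preranked",
    "gsea_score",
    "GseaScoreClassifier",
]

P_FLOOR = 1e-300


def build_ranked_list(
    tool_profile: CompoundProfile, exclude: Iterable[str] = ()
) -> RankedList:
    """Signed p-value ranking of a tool compound's genes.

    Each gene is scored ``−log10(p) × sign(log2FC)`` (p floored at 1e-300),
    so strongly upregulated genes head the list and strongly downregulated
    genes tail it. Ties are broken by larger |log2FC| first, then gene id,
    making the ordering independent of input row order. Genes in ``exclude``
    (e.g. the noise union) are dropped before ranking.
    """
    tbl = tool_profile.de_table
    exclude = frozenset(exclude)
    if exclude:
        tbl = tbl.loc[~tbl.index.isin(exclude)]
    if len(tbl) == 0:
        raise ValueError(f"{tool_profile.compound_id}: empty DE table")
    lfc = tbl["log2fc"].to_numpy(dtype=float)
    if np.all(lfc == 0):
        raise ValueError(
            f"{tool_profile.compound_id}: all log2fc are zero — no direction"
        )
    p = np.clip(tbl["pvalue"].to_numpy(dtype=float), P_FLOOR, 1.0)
    score = -np.log10(p) * np.sign(lfc)
    order = (
        pd.DataFrame(
            {"score": score, "abs_lfc": np.abs(lfc), "gene": tbl.index}
        )
        .sort_values(
            ["score", "abs_lfc", "gene"], ascending=[False, False, True]
        )
        .index.to_numpy()
    )
    return RankedList(
        compound_id=tool_profile.compound_id,
        genes=tbl.index.to_numpy(dtype=object)[order],
        scores=score[order],
    )


def direction_gene_sets(
    test: DEGeneSet, min_size: int = 3
) -> list[dict]:
    """Up- and down-direction gene sets of a test compound.

    Returns records with keys ``set_id``, ``genes``, ``direction`` and
    ``eligible`` (size >= min_size, inclusive). Empty sets are omitted.
    """
    out = []
    for direction, genes in (("up", test.up), ("down", test.down)):
        if not genes:
            continue
        out.append(
            {
                "set_id": f"{test.compound_id}_{direction}",
                "genes": frozenset(genes),
                "direction": direction,
                "eligible": len(genes) >= min_size,
            }
        )
    return out


def _hit_walk_extrema(
    hit_pos: np.ndarray, hit_weights: np.ndarray, n: int
) -> np.ndarray:
    """Signed extremum of the running sum for each row of hit positions.

    ``hit_pos`` (B, k) must be sorted ascending per row; ``hit_weights``
    are the matching normalized hit increments (rows sum to 1). The running
    sum between hits falls linearly by 1/(n−k) per miss, so its extrema
    occur immediately after a hit or immediately before one; both candidate
    sets are evaluated in closed form.
    """
    B, k = hit_pos.shape
    miss = 1.0 / (n - k) if n > k else 0.0
    W = np.cumsum(hit_weights, axis=1)
    i = np.arange(1, k + 1)
    after = W - miss * (hit_pos + 1 - i)          # just after hit i
    before = (W - hit_weights) - miss * (hit_pos - (i - 1))  # just before hit i
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def _hit_weights(
    abs_scores_w: np.ndarray, hit_pos: np.ndarray
) -> np.ndarray:
    w = abs_scores_w[hit_pos]
    tot = w.sum(axis=1, keepdims=True)
    k = hit_pos.shape[1]
    uniform = np.full_like(w, 1.0 / k)
    return np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), uniform)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of a gene set in a ranked list.

    Hits increment by |score|^weight normalized over the hits; misses
    decrement by 1/(N − n_hits). Returns the signed extremum of the walk
    (by absolute value) and the full running sum.
    """
    genes = frozenset(gene_set)
    hit_mask = np.fromiter((g in genes for g in ranked.genes), bool, len(ranked))
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set absent from ranked list")
    n = len(ranked)
    w = np.abs(ranked.scores) ** weight
    hit_w = w * hit_mask
    tot = hit_w.sum()
    steps = (
        hit_w / tot if tot > 0 else hit_mask / n_hit
    ).astype(float)
    if n > n_hit:
        steps = steps - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es(
    rng: np.random.Generator,
    abs_scores_w: np.ndarray,
    k: int,
    n_perm: int,
) -> np.ndarray:
    """Null enrichment scores from random same-size gene sets."""
    n = len(abs_scores_w)
    u = rng.random((n_perm, n))
    part = np.argpartition(u, k, axis=1)[:, :k]
    hit_pos = np.sort(part, axis=1)
    weights = _hit_weights(abs_scores_w, hit_pos)
    return _hit_walk_extrema(hit_pos, weights, n)


def gsea_preranked(
    ranked: RankedList,
    gene_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> list[GseaResult]:
    """Preranked GSEA with a gene-permutation null.

    For each gene set: the observed enrichment score; a null of ``n_perm``
    random same-size sets drawn from the ranked list; NES = ES divided by
    the mean |null ES| of matching sign; nominal p =
    (1 + #{null at least as extreme, same sign}) / (1 + #{null same sign});
    BH adjustment across all sets in the call. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    items = list(gene_sets.items()) if isinstance(gene_sets, Mapping) else list(gene_sets)
    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** weight
    n = len(ranked)
    records = []
    for set_id, genes in items:
        genes = frozenset(genes)
        if len(genes) > n:
            raise ValueError(f"gene set {set_id!r} larger than ranked list")
        es, _ = enrichment_score(ranked, genes, weight=weight)
        k = len(genes & set(ranked.genes))
        null = _null_es(rng, abs_w, k, n_perm)
        if es == 0:
            nes, p = 0.0, 1.0
        else:
            same = null[np.sign(null) == np.sign(es)]
            if len(same) == 0:
                same = np.abs(null)
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else 0.0
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
        records.append((set_id, es, nes, float(p), k))
    padj = bh_adjust([r[3] for r in records])
    return [
        GseaResult(gene_set_id=sid, es=es, nes=nes, pvalue=p, padj=float(q),
                   set_size=k)
        for (sid, es, nes, p, k), q in zip(records, padj)
    ]


def _pair_seed(root: int | None, tool_id: str, set_id: str) -> list[int]:
    crc = zlib.crc32(f"{tool_id}|{set_id}".encode()) & 0x7FFFFFFF
    return [0 if root is None else int(root), crc]


def gsea_score(
    positive: DEGeneSet,
    tools: Sequence[CompoundProfile | RankedList],
    alpha: float = 0.05,
    n_perm: int = 1000,
    min_size: int = 3,
    weight: float = 1.0,
    seed: int | None = None,
    noise: Iterable[str] = (),
) -> GseaScore:
    """Compound-level GSEA score against a panel of tool ranked lists.

    The test compound's up/down DE gene sets (noise-subtracted, at least
    ``min_size`` genes) are tested against every tool compound's ranked
    list; BH adjustment is applied across all set×list pairs for this
    compound and |NES| of pairs with adjusted p < ``alpha`` are summed.
    A compound with no eligible set is flagged not calculable (score 0).
    """
    if not tools:
        raise ValueError("need at least one tool compound")
    noise = frozenset(noise)
    test = subtract_noise(positive, noise)
    sets = [s for s in direction_gene_sets(test, min_size=min_size) if s["eligible"]]
    if not sets:
        return GseaScore(
            compound_id=positive.compound_id, score=0.0, n_significant_sets=0,
            contributors=[], calculable=False,
        )
    ranked_lists = [
        t if isinstance(t, RankedList) else build_ranked_list(t, exclude=noise)
        for t in tools
    ]
    rows = []  # (tool_id, direction, nes, p)
    for ranked in ranked_lists:
        present = set(ranked.genes)
        for s in sets:
            genes = s["genes"] & present
            if not genes:
                continue
            res = gsea_preranked(
                ranked,
                [(s["set_id"], genes)],
                n_perm=n_perm,
                weight=weight,
                seed=_pair_seed(seed, ranked.compound_id, s["set_id"]),
            )[0]
            rows.append((ranked.compound_id, s["direction"], res.nes, res.pvalue))
    if not rows:
        return GseaScore(
            compound_id=positive.compound_id, score=0.0, n_significant_sets=0,
            contributors=[], calculable=False,
        )
    padj = bh_adjust([r[3] for r in rows])
    contributors = [
        (tool_id, direction, float(nes))
        for (tool_id, direction, nes, _), q in zip(rows, padj)
        if q < alpha
    ]
    score = float(sum(abs(nes) for _, _, nes in contributors))
    return GseaScore(
        compound_id=positive.compound_id,
        score=score,
        n_significant_sets=len(contributors),
        contributors=contributors,
        calculable=True,
    )


class GseaScoreClassifier(BaseEstimator):
    """Estimator wrapper around the compound-level GSEA score.

    ``fit`` takes the tool compound profiles (X) and, optionally, the
    FAERS-negative DE gene sets whose pooled genes are removed from every
    ranked list and test set; ``decision_function`` returns GSEA scores for
    test DE gene sets and ``predict`` calls a compound positive when its
    score exceeds ``threshold``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = 1000,
        min_size: int = 3,
        weight: float = 1.0,
        threshold: float = 0.0,
        seed: int | None = None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_size = min_size
        self.weight = weight
        self.threshold = threshold
        self.seed = seed

    def fit(
        self,
        X: Sequence[CompoundProfile],
        y=None,
        negatives: Sequence[DEGeneSet] = (),
    ):
        if not X:
            raise ValueError("need at least one tool profile")
        self.noise_ = negative_noise_union(list(negatives))
        self.ranked_ = [build_ranked_list(t, exclude=self.noise_) for t in X]
        return self

    def score_compounds(self, X: Sequence[DEGeneSet]) -> list[GseaScore]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ranked_")
        return [
            gsea_score(
                s,
                self.ranked_,
                alpha=self.alpha,
                n_perm=self.n_perm,
                min_size=self.min_size,
                weight=self.weight,
                seed=self.seed,
                noise=self.noise_,
            )
            for s in X
        ]

    def decision_function(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        return np.array([g.score for g in self.score_compounds(X)], dtype=float)

    def predict(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        return self.decision_function(X) > self.threshold
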