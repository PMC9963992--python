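"""Shared-DE-gene statistics and the alikeness-% classifier.

The alikeness-% of a test compound against one reference (tool) compound is
the number of direction-matched shared DE genes divided by the tool
compound's DE-gene count, times 100. Summed over all tool compounds and
compared against a cutoff (default: strictly greater than 10) it yields a
binary seizure-liability call. Before scoring, the pooled DE genes of the
FAERS-negative compounds are subtracted from every set as non-ictogenic
"noise".
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .types import AlikenessTable, Category, CategoryOverlap, DEGeneSet, VENN_REGIONS

__all__ = [
    "negative_noise_union",
    "subtract_noise",
    "shared_de_count",
    "cross_tabulate",
    "venn_counts",
    "alikeness_percent",
    "alikeness_table",
    "AlikenessClassifier",
]


def negative_noise_union(
    negatives: Sequence[DEGeneSet],
    restrict_to: Iterable[DEGeneSet] | None = None,
) -> frozenset[str]:
    """Direction-agnostic union of all negative compounds' DE genes.

    With ``restrict_to`` the union is intersected with the pooled genes of
    the given sets, i.e. only noise genes that are also regulated by a
    tool/positive compound are reported (the narrow reading of noise
    removal); by default the full union is returned.
    """
    for s in negatives:
        if s.category is not None and Category(s.category) != Category.FAERS_NEGATIVE:
            raise ValueError(
                f"{s.compound_id}: noise union expects FAERS-negative sets"
            )
    union: frozenset[str] = frozenset().union(*(s.genes for s in negatives)) \
        if negatives else frozenset()
    if restrict_to is not None:
        signal = frozenset().union(*(s.genes for s in restrict_to)) \
            if restrict_to else frozenset()
        union &= signal
    return union


def subtract_noise(s: DEGeneSet, noise: Iterable[str]) -> DEGeneSet:
    """Remove noise gene ids from both the up and down sets."""
    noise = frozenset(noise)
    return DEGeneSet(
        compound_id=s.compound_id,
        up=s.up - noise,
        down=s.down - noise,
        category=s.category,
    )


def shared_de_count(x: DEGeneSet, y: DEGeneSet, direction_matched: bool = True) -> int:
    """Number of DE genes shared by two compounds.

    Direction-matched: up∩up plus down∩down. Direction-agnostic: overlap of
    the pooled gene sets.
    """
    if direction_matched:
        return len(x.up & y.up) + len(x.down & y.down)
    return len(x.genes & y.genes)


def cross_tabulate(profiles: Sequence[DEGeneSet]) -> pd.DataFrame:
    """Symmetric compound-by-compound table of shared DE-gene counts.

    Off-diagonal entries are direction-agnostic overlaps; the diagonal holds
    each compound's total DE count.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    ids = [p.compound_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_id in cross-tabulation input")
    n = len(profiles)
    mat = np.zeros((n, n), dtype=int)
    for i, x in enumerate(profiles):
        mat[i, i] = x.n_de
        for j in range(i + 1, n):
            c = shared_de_count(x, profiles[j], direction_matched=False)
            mat[i, j] = mat[j, i] = c
    return pd.DataFrame(mat, index=ids, columns=ids)


def _category_union(sets: Sequence[DEGeneSet], variant: str) -> frozenset[str]:
    if variant == "both":
        parts = [s.genes for s in sets]
    elif variant == "up_only":
        parts = [s.up for s in sets]
    elif variant == "down_only":
        parts = [s.down for s in sets]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return frozenset().union(*parts) if parts else frozenset()


def venn_counts(
    tool: Sequence[DEGeneSet],
    pos: Sequence[DEGeneSet],
    neg: Sequence[DEGeneSet],
    variant: str = "both",
) -> CategoryOverlap:
    """Region counts of the 3-set Venn over per-category gene-set unions.

    A gene belongs to a category if at least one of its compounds regulates
    it (in the chosen direction for the ``up_only``/``down_only`` variants).
    """
    t = _category_union(tool, variant)
    p = _category_union(pos, variant)
    g = _category_union(neg, variant)
    counts = {
        "tool_only": len(t - p - g),
        "pos_only": len(p - t - g),
        "neg_only": len(g - t - p),
        "tool_pos": len((t & p) - g),
        "tool_neg": len((t & g) - p),
        "pos_neg": len((p & g) - t),
        "tool_pos_neg": len(t & p & g),
    }
    return CategoryOverlap(counts=counts, variant=variant)


def alikeness_percent(test: DEGeneSet, tool: DEGeneSet) -> float:
    """Alikeness-% of a test compound against one tool compound.

    Direction-matched shared DE genes divided by the tool compound's DE
    count, ×100. Both sets are expected noise-subtracted by the caller. An
    empty tool set yields 0 with a warning.
    """
    denom = tool.n_de
    if denom == 0:
        warnings.warn(
            f"tool compound {tool.compound_id!r} has no DE genes after "
            "noise subtraction; alikeness-% set to 0",
            stacklevel=2,
        )
        return 0.0
    return shared_de_count(test, tool, direction_matched=True) / denom * 100.0


def alikeness_table(
    positives: Sequence[DEGeneSet],
    tools: Sequence[DEGeneSet],
    cutoff: float = 10.0,
) -> AlikenessTable:
    """Full alikeness-% matrix with per-compound sums and cutoff calls.

    Inputs must already be noise-subtracted. Classification is strict:
    a compound is called positive iff its alikeness-% sum exceeds
    ``cutoff``.
    """
    pos_ids = [p.compound_id for p in positives]
    tool_ids = [t.compound_id for t in tools]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = pd.DataFrame(
            [[alikeness_percent(p, t) for t in tools] for p in positives],
            index=pos_ids,
            columns=tool_ids,
            dtype=float,
        )
    sums = mat.sum(axis=1) if tool_ids else pd.Series(0.0, index=pos_ids)
    classified = sums > cutoff
    return AlikenessTable(matrix=mat, sums=sums, classified=classified, cutoff=cutoff)


def aggregate_alikeness(
    matrix: pd.DataFrame, cutoff: float = 10.0
) -> AlikenessTable:
    """Aggregate a precomputed alikeness-% matrix into sums and cutoff calls.

    Rows are test compounds, columns tool compounds; the per-compound sum
    is the row total and a compound is classified positive iff its sum
    strictly exceeds ``cutoff``. Useful when the per-pair percentages are
    already available (e.g. from a published screen).
    """
    sums = matrix.sum(axis=1).astype(float)
    return AlikenessTable(
        matrix=matrix.astype(float), sums=sums, classified=sums > cutoff,
        cutoff=cutoff,
    )


class AlikenessClassifier(BaseEstimator, ClassifierMixin):
    """Cutoff classifier on the alikeness-% sum against tool signatures.

    Follows the scikit-learn estimator protocol over lists of
    :class:`~ictosig.types.DEGeneSet` in place of array X: ``fit`` stores the
    reference tool signatures and the noise union from the FAERS-negative
    sets, ``decision_function`` returns alikeness-% sums and ``predict``
    applies the strict ``> cutoff`` rule.

    Parameters
    ----------
    cutoff : float
        Classification threshold on the alikeness-% sum (strict).
    restrict_noise : bool
        If True, subtract only noise genes also regulated by a tool
        compound (narrow noise reading); default subtracts the full
        negative union.
    """

    def __init__(self, cutoff: float = 10.0, restrict_noise: bool = False):
        self.cutoff = cutoff
        self.restrict_noise = restrict_noise

    def fit(self, X: Sequence[DEGeneSet], y=None, negatives: Sequence[DEGeneSet] = ()):
        """Store tool reference sets (X) and derive the noise union."""
        tools = list(X)
        if not tools:
            raise ValueError("need at least one tool signature")
        self.noise_ = negative_noise_union(
            list(negatives), restrict_to=tools if self.restrict_noise else None
        )
        self.tools_ = [subtract_noise(t, self.noise_) for t in tools]
        return self

    def transform(self, X: Sequence[DEGeneSet]) -> AlikenessTable:
        """Alikeness table of the given test compounds against the tools."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "tools_")
        tests = [subtract_noise(s, self.noise_) for s in X]
        return alikeness_table(tests, self.tools_, cutoff=self.cutoff)

    def decision_function(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        return self.transform(X).sums.to_numpy(dtype=float)

    def predict(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        return self.decision_function(X) > self.cutoff
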