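"""Differential-expression thresholding, filtering and the cytotoxicity screen.

The DE calling itself is expected upstream (e.g. DESeq2 output ingested as
TSV); this module applies the panel's significance thresholds (FDR < 0.05,
|log2FC| > 1.5), the low-expression filter used before count-based
classification, a deliberately simple two-group DE test for synthetic count
matrices, and the LDH cytotoxicity percentage with its nonparametric tests.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CompoundProfile, CytotoxResult, DEGeneSet

__all__ = [
    "threshold_de",
    "low_expression_filter",
    "simple_de_test",
    "cytotoxicity_percent",
    "cytotox_significance",
]


def threshold_de(
    profile: CompoundProfile, fdr_cut: float = 0.05, lfc_cut: float = 1.5
) -> DEGeneSet:
    """Threshold a DE table into signed up/down gene sets.

    A gene is upregulated iff ``fdr < fdr_cut`` and ``log2fc > lfc_cut``,
    downregulated iff ``fdr < fdr_cut`` and ``log2fc < -lfc_cut``. The
    fold-change criterion is applied to the magnitude of the log2
    fold-change, the only reading under which downregulated genes can pass.

    Returns an empty set (not an error) for an empty table.
    """
    tbl = profile.de_table
    if len(tbl) == 0:
        return DEGeneSet(profile.compound_id, category=profile.category)
    lfc = tbl["log2fc"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lfc)):
        bad = tbl.index[~np.isfinite(lfc)][0]
        raise ValueError(
            f"{profile.compound_id}: non-finite log2fc for gene {bad!r}"
        )
    fdr = tbl["fdr"].to_numpy(dtype=float)
    sig = fdr < fdr_cut
    up = frozenset(tbl.index[sig & (lfc > lfc_cut)])
    down = frozenset(tbl.index[sig & (lfc < -lfc_cut)])
    return DEGeneSet(profile.compound_id, up=up, down=down, category=profile.category)


def low_expression_filter(
    counts: pd.DataFrame, min_value: float = 5.0, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop genes with fewer than ``min_value`` normalized counts in at least
    ``min_fraction`` of the samples.

    The boundary is inclusive: a gene below ``min_value`` in exactly
    ``min_fraction`` of samples is removed. Row order of survivors is
    preserved; an empty matrix passes through unchanged.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        return counts.copy()
    vals = counts.to_numpy(dtype=float)
    frac_low = (vals < min_value).mean(axis=1)
    return counts.loc[frac_low < min_fraction].copy()


def simple_de_test(
    treated: pd.DataFrame, vehicle: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Two-group DE stand-in for synthetic count matrices.

    Per gene: log2 fold-change of (mean + pseudocount) ratios, Welch's
    unequal-variance t-test on log2(count + pseudocount), and
    Benjamini–Hochberg adjustment across all tested genes. This is a
    deliberately simple screen for simulator output — not a negative-binomial
    DE model — so real experiments should ingest proper DE tables instead.

    Returns a DataFrame indexed by gene with columns log2fc, pvalue, fdr.
    """
    if not treated.index.equals(vehicle.index):
        raise ValueError("treated and vehicle matrices must share gene rows")
    if treated.shape[1] < 2 or vehicle.shape[1] < 2:
        raise ValueError(
            "need >= 2 replicates per group for the two-group test; "
            "supply externally computed DE tables for unreplicated designs"
        )
    t = np.log2(treated.to_numpy(dtype=float) + pseudocount)
    v = np.log2(vehicle.to_numpy(dtype=float) + pseudocount)
    log2fc = np.log2(treated.mean(axis=1).to_numpy() + pseudocount) - np.log2(
        vehicle.mean(axis=1).to_numpy() + pseudocount
    )
    with warnings.catch_warnings():
        # zero-variance rows yield nan p-values; treated as non-significant
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(t, v, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "fdr": fdr}, index=treated.index
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cytotoxicity_percent(
    treated: float,
    low_controls: Sequence[float],
    high_controls: Sequence[float],
) -> float:
    """Cytotoxicity % of one treated well from LDH absorbances.

    ``(treated − mean(low)) / (mean(high) − mean(low)) × 100``, where the
    low controls are vehicle wells and the high controls are detergent-lysed
    wells with maximal LDH release. The result is 0 at the low-control mean,
    100 at the high-control mean, and may fall outside [0, 100].
    """
    low = np.asarray(low_controls, dtype=float)
    high = np.asarray(high_controls, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError("need at least one low- and one high-control well")
    span = high.mean() - low.mean()
    if span == 0:
        raise ValueError("degenerate controls: high and low means are equal")
    return float((treated - low.mean()) / span * 100.0)


def cytotox_significance(
    groups: Mapping[str, Sequence[float]],
    vehicle: Sequence[float],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CytotoxResult:
    """Kruskal–Wallis omnibus test with gatekept Mann–Whitney post hocs.

    Pairwise vehicle-vs-group two-sided Mann–Whitney U p-values are computed
    only when the omnibus p is below ``alpha``. With ``bonferroni`` the
    pairwise p-values are multiplied by the number of comparisons (they are
    otherwise reported unadjusted). Degenerate all-tied input yields p = 1
    with the ``degenerate`` flag set.
    """
    if len(groups) < 1:
        raise ValueError("need at least one treatment group")
    veh = np.asarray(vehicle, dtype=float)
    samples = [veh] + [np.asarray(g, dtype=float) for g in groups.values()]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 observations per group")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return CytotoxResult(
            cytotoxicity_pct={k: list(map(float, v)) for k, v in groups.items()},
            omnibus_p=1.0,
            group_p={k: 1.0 for k in groups},
            degenerate=True,
        )
    omnibus_p = float(stats.kruskal(*samples).pvalue)
    group_p: dict[str, float] = {}
    if omnibus_p < alpha:
        for name, obs in groups.items():
            p = float(
                stats.mannwhitneyu(
                    veh, np.asarray(obs, dtype=float), alternative="two-sided"
                ).pvalue
            )
            if bonferroni:
                p = min(1.0, p * len(groups))
            group_p[name] = p
    return CytotoxResult(
        cytotoxicity_pct={k: list(map(float, v)) for k, v in groups.items()},
        omnibus_p=omnibus_p,
        group_p=group_p,
        degenerate=False,
    )
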