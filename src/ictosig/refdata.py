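"""Reported reference values from the rat cortical-neuron compound screen.

The screen exposed rat cortical neuronal cultures for 24 h to 34 compounds
— 11 established ictogens (tool compounds), 13 compounds with frequent
seizure adverse-event reports (FAERS-positive) and 10 with few or none
(FAERS-negative) — and derived per-compound DE gene sets (FDR < 0.05,
|log2FC| > 1.5). The values below are the screen's published summary
numbers: per-compound DE counts, the FAERS-positive × tool alikeness-%
matrix, compound-level GSEA scores, and the shared-signature LOOCV
confusion. They serve as fixtures for validating the scoring arithmetic
(sums, cutoff calls, rank correlation, summary percentages) without access
to the underlying sequencing data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TOOL_COMPOUNDS = [
    "4-aminopyridine",
    "amoxapine",
    "bicuculline",
    "chlorpromazine",
    "donepezil",
    "kainic acid",
    "picrotoxin",
    "pilocarpine",
    "pentylenetetrazol",
    "SNC80",
    "strychnine",
]

FAERS_POSITIVE_COMPOUNDS = [
    "amitriptyline",
    "aminophylline",
    "bupropion",
    "clozapine",
    "diphenhydramine",
    "isoniazid",
    "maprotiline",
    "mirtazapine",
    "paroxetine",
    "temozolomide",
    "theophylline",
    "tramadol",
    "venlafaxine",
]

# Number of DE genes per FAERS-positive compound in the screen.
DE_GENE_COUNTS = {
    "amitriptyline": 346,
    "aminophylline": 158,
    "bupropion": 202,
    "clozapine": 3695,
    "diphenhydramine": 3,
    "isoniazid": 32,
    "maprotiline": 141,
    "mirtazapine": 827,
    "paroxetine": 0,
    "temozolomide": 21,
    "theophylline": 200,
    "tramadol": 100,
    "venlafaxine": 151,
}

# Alikeness-% of each FAERS-positive compound (columns) against each tool
# compound (rows), as reported for the screen.
_ALIKENESS_ROWS = {
    "4-aminopyridine": [2.9, 18.4, 9.8, 9.8, 0, 0, 1.1, 1.7, 0, 0.6, 1.7, 0.6, 0],
    "amoxapine": [2.1, 0.3, 0.8, 50.2, 0, 0.1, 1.5, 4.3, 0, 0.1, 0.9, 0.2, 1.0],
    "bicuculline": [4.7, 2.0, 2.0, 28, 0, 0, 2.0, 17.3, 0, 0, 1.3, 1.3, 0.7],
    "chlorpromazine": [16.4, 0, 4.9, 29.5, 0, 0, 18.0, 11.5, 0, 3.3, 6.6, 1.6, 1.6],
    "donepezil": [0, 0, 9.1, 18.2, 0, 0, 0, 9.1, 0, 0, 4.5, 4.5, 0],
    "kainic acid": [0, 36.5, 17.6, 4.7, 0, 0, 0, 1.2, 0, 0, 0, 0, 0],
    "picrotoxin": [3.5, 0, 1.2, 11.8, 0, 0, 1.2, 9.4, 0, 0, 5.9, 2.4, 1.2],
    "pilocarpine": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "pentylenetetrazol": [1.1, 4.4, 5.2, 7.4, 0, 0.2, 0.3, 1.1, 0, 0.3, 0.2, 0, 0.5],
    "SNC80": [3.3, 0.5, 1.9, 61.9, 0, 0, 1.7, 11.1, 0, 0.5, 2.1, 0.7, 2.4],
    "strychnine": [0, 0, 0, 0, 0, 0, 12.5, 0, 0, 12.5, 12.5, 0, 0],
}

# Reported alikeness-% sums per FAERS-positive compound.
REPORTED_ALIKENESS_SUMS = {
    "amitriptyline": 34.0,
    "aminophylline": 62.1,
    "bupropion": 52.5,
    "clozapine": 221.5,
    "diphenhydramine": 0.0,
    "isoniazid": 0.3,
    "maprotiline": 38.3,
    "mirtazapine": 66.7,
    "paroxetine": 0.0,
    "temozolomide": 17.3,
    "theophylline": 35.7,
    "tramadol": 11.3,
    "venlafaxine": 7.4,
}

# Compound-level GSEA scores reported for the screen; compounds for which
# no score could be computed are absent (treated as 0 in comparisons).
REPORTED_GSEA_SCORES = {
    "clozapine": 28.8,
    "mirtazapine": 20.1,
    "bupropion": 11.9,
    "amitriptyline": 8.5,
    "aminophylline": 7.8,
    "theophylline": 5.1,
    "maprotiline": 4.9,
    "venlafaxine": 3.4,
}

# Shared-signature LOOCV confusion over 13 positives and 10 negatives:
# 10/13 positives and 10/10 negatives called correctly.
REPORTED_LOOCV_CONFUSION = {"tp": 10, "fp": 0, "tn": 10, "fn": 3}

# Correct-categorization calls per method over the 11 retained positive
# compounds (diphenhydramine and paroxetine excluded for lacking DE genes).
REPORTED_CORRECT = {
    "alikeness": {
        "amitriptyline": True, "aminophylline": True, "bupropion": True,
        "clozapine": True, "isoniazid": False, "maprotiline": True,
        "mirtazapine": True, "temozolomide": True, "theophylline": True,
        "tramadol": True, "venlafaxine": False,
    },
    "gsea": {
        "amitriptyline": True, "aminophylline": True, "bupropion": True,
        "clozapine": True, "isoniazid": False, "maprotiline": True,
        "mirtazapine": True, "temozolomide": False, "theophylline": True,
        "tramadol": False, "venlafaxine": True,
    },
    "ml": {
        "amitriptyline": True, "aminophylline": True, "bupropion": True,
        "clozapine": True, "isoniazid": True, "maprotiline": True,
        "mirtazapine": True, "temozolomide": True, "theophylline": True,
        "tramadol": True, "venlafaxine": False,
    },
}


def alikeness_matrix() -> pd.DataFrame:
    """Reported alikeness-% matrix: rows FAERS-positive, columns tools."""
    mat = pd.DataFrame(
        _ALIKENESS_ROWS, index=FAERS_POSITIVE_COMPOUNDS, dtype=float
    )
    return mat[TOOL_COMPOUNDS]


def gsea_score_vector() -> pd.Series:
    """Reported GSEA scores over all 13 positives, 0 where not calculable."""
    return pd.Series(
        {c: REPORTED_GSEA_SCORES.get(c, 0.0) for c in FAERS_POSITIVE_COMPOUNDS},
        dtype=float,
    )


def alikeness_sum_vector() -> pd.Series:
    """Reported alikeness-% sums over all 13 positive compounds."""
    return pd.Series(REPORTED_ALIKENESS_SUMS, dtype=float).reindex(
        FAERS_POSITIVE_COMPOUNDS
    )
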