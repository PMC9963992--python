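"""Core domain containers for compound-level transcriptomic signatures.

A *compound profile* holds one compound's differential-expression (DE) table
versus vehicle — per gene a log2 fold-change, a nominal p-value and a
Benjamini–Hochberg FDR — and optionally a gene-by-replicate count matrix.
Signed *DE gene sets* (up / down) are derived from a profile by thresholding
and are the currency of every downstream similarity and scoring step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DE_TABLE_COLUMNS = ("log2fc", "pvalue", "fdr")


class Category(str, enum.Enum):
    """Compound category within a seizure-liability panel.

    TOOL compounds are established ictogens whose signatures serve as
    references; FAERS_POSITIVE compounds carry many seizure adverse-event
    reports (the test set); FAERS_NEGATIVE compounds carry few or none and
    define the transcriptomic "noise" to be subtracted.
    """

    TOOL = "tool"
    FAERS_POSITIVE = "faers_positive"
    FAERS_NEGATIVE = "faers_negative"
    VEHICLE = "vehicle"


@dataclass
class CompoundProfile:
    """One compound's identity, category and DE table (plus optional counts).

    Parameters
    ----------
    compound_id : str
        Unique compound name.
    category : Category
        Panel category of the compound.
    de_table : pandas.DataFrame
        Indexed by gene id with columns ``log2fc``, ``pvalue``, ``fdr``.
        p-values and FDRs must lie in (0, 1].
    counts : pandas.DataFrame, optional
        Gene-by-replicate non-negative integer matrix.
    concentration : float, optional
        Exposure concentration in µM.
    """

    compound_id: str
    category: Category
    de_table: pd.DataFrame
    counts: Optional[pd.DataFrame] = None
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        self.category = Category(self.category)
        tbl = self.de_table
        missing = [c for c in DE_TABLE_COLUMNS if c not in tbl.columns]
        if missing:
            raise ValueError(
                f"{self.compound_id}: DE table missing columns {missing}"
            )
        if tbl.index.has_duplicates:
            dup = tbl.index[tbl.index.duplicated()][0]
            raise ValueError(f"{self.compound_id}: duplicate gene id {dup!r}")
        if len(tbl):
            for col in ("pvalue", "fdr"):
                vals = tbl[col].to_numpy(dtype=float)
                if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1):
                    raise ValueError(
                        f"{self.compound_id}: column {col!r} must lie in (0, 1]"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.de_table)


@dataclass(frozen=True)
class DEGeneSet:
    """Signed DE gene sets for one compound: up- and downregulated ids."""

    compound_id: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()
    category: Optional[Category] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"{self.compound_id}: genes in both up and down sets: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        """Direction-agnostic union of up- and downregulated genes."""
        return self.up | self.down

    @property
    def n_de(self) -> int:
        return len(self.up) + len(self.down)

    def __len__(self) -> int:
        return self.n_de


@dataclass
class CytotoxResult:
    """Per-well cytotoxicity percentages and group-level rank-test p-values."""

    cytotoxicity_pct: dict[str, list[float]]
    omnibus_p: float
    group_p: dict[str, float]
    degenerate: bool = False


@dataclass
class AlikenessTable:
    """Alikeness-% matrix of test compounds against tool compounds.

    ``matrix`` is indexed by test compound (rows) and tool compound
    (columns); ``sums`` are row totals; ``classified`` marks rows whose sum
    strictly exceeds ``cutoff``.
    """

    matrix: pd.DataFrame
    sums: pd.Series
    classified: pd.Series
    cutoff: float

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        if vals.size and (np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9)):
            raise ValueError("alikeness percentages must lie in [0, 100]")
        if not np.allclose(self.sums.to_numpy(), vals.sum(axis=1), atol=1e-9):
            raise ValueError("sum column inconsistent with row totals")

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["sum"] = self.sums
        out["classified"] = self.classified
        return out


VENN_REGIONS = (
    "tool_only",
    "pos_only",
    "neg_only",
    "tool_pos",
    "tool_neg",
    "pos_neg",
    "tool_pos_neg",
)


@dataclass
class CategoryOverlap:
    """Counts for the 7 regions of the 3-set Venn over category gene sets."""

    counts: dict[str, int]
    variant: str = "both"

    def __post_init__(self) -> None:
        if set(self.counts) != set(VENN_REGIONS):
            raise ValueError(f"expected regions {VENN_REGIONS}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("region counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RankedList:
    """Signed gene ranking for one compound, sorted descending by score."""

    compound_id: str
    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate gene ids")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """Enrichment of one gene set in one ranked list."""

    gene_set_id: str
    es: float
    nes: float
    pvalue: float
    padj: float
    set_size: int

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.es <= 1 + 1e-9:
            raise ValueError("enrichment score must lie in [-1, 1]")


@dataclass
class GseaScore:
    """Compound-level GSEA score: sum of |NES| over significant set×list pairs."""

    compound_id: str
    score: float
    n_significant_sets: int
    contributors: list[tuple[str, str, float]] = field(default_factory=list)
    calculable: bool = True

    def __post_init__(self) -> None:
        if self.n_significant_sets == 0 and abs(self.score) > 1e-9:
            raise ValueError("nonzero score with no significant sets")
        contrib_sum = sum(abs(nes) for _, _, nes in self.contributors)
        if abs(contrib_sum - self.score) > 1e-9:
            raise ValueError("score must equal sum of |NES| over contributors")


@dataclass
class ClassificationReport:
    """Pooled binary-classification summary with NIR and binomial test."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    nir: float
    binom_p: float
    degenerate: bool = False
    predictions: Optional[pd.DataFrame] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "nir": self.nir,
            "binom_p": self.binom_p,
            "degenerate": self.degenerate,
        }


def split_by_category(
    items: Sequence, category: Category
) -> list:
    """Return the items (profiles or gene sets) belonging to one category."""
    return [x for x in items if Category(x.category) == category]
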