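"""Score comparison, categorization summaries and the end-to-end pipeline.

Ties the stages together: simulate (or load) per-compound DE tables,
threshold, subtract FAERS-negative noise, score by alikeness-% and GSEA,
classify by the shared-signature LOOCV, compare the two scores by Spearman
rank correlation, and summarize correct categorization per method.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as iomod
from .de import threshold_de
from .gsea import GseaScoreClassifier
from .ml import loocv_shared_feature
from .similarity import AlikenessClassifier
from .synthetic import PanelConfig, generate_panel
from .types import AlikenessTable, Category, GseaScore, split_by_category

__all__ = [
    "compare_scores",
    "summarize_classifications",
    "SummaryTable",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("ictosig")


def compare_scores(
    alikeness: AlikenessTable | pd.Series,
    gsea_scores: Sequence[GseaScore] | pd.Series,
) -> tuple[float, float]:
    """Tie-corrected Spearman correlation of alikeness sums vs GSEA scores.

    Compounds are paired by id; a compound whose GSEA score could not be
    calculated enters as 0. Returns (rho, two-sided p) using average ranks
    and the t approximation; a constant vector yields (nan, nan) with a
    warning.
    """
    a = alikeness.sums if isinstance(alikeness, AlikenessTable) else alikeness
    if isinstance(gsea_scores, pd.Series):
        g = gsea_scores
    else:
        g = pd.Series({s.compound_id: s.score for s in gsea_scores}, dtype=float)
    g = g.reindex(a.index).fillna(0.0)
    if len(a) < 3:
        raise ValueError("need >= 3 compounds in common")
    av = a.to_numpy(dtype=float)
    gv = g.to_numpy(dtype=float)
    if np.all(av == av[0]) or np.all(gv == gv[0]):
        warnings.warn("constant score vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(av, gv)
    return float(rho), float(p)


@dataclass
class SummaryTable:
    """Per-compound categorization summary with per-method totals.

    ``table`` is indexed by retained compound; ``percentages`` maps method
    name to (n_correct, n_retained, rounded whole-percent); ``excluded``
    lists compounds dropped for having too few DE genes.
    """

    table: pd.DataFrame
    percentages: dict[str, tuple[int, int, int]]
    excluded: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "percentages": {
                    m: {"correct": c, "n": n, "percent": p}
                    for m, (c, n, p) in self.percentages.items()
                },
                "excluded": self.excluded,
                "table": json.loads(self.table.to_json(orient="index")),
            },
            indent=2,
        )


def summarize_classifications(
    alikeness: AlikenessTable,
    gsea_scores: Sequence[GseaScore] | pd.Series,
    ml_correct: Mapping[str, bool],
    de_counts: Mapping[str, int],
    exclusion_threshold: int = 3,
) -> SummaryTable:
    """Summarize correct categorization of test compounds per method.

    Compounds with at most ``exclusion_threshold`` DE genes are excluded
    (they cannot express a signature). For the alikeness method a compound
    is correct when its sum exceeds the cutoff; for the GSEA method when
    its score is positive; ML correctness is supplied by the caller (from
    the LOOCV predictions). Percentages are whole-percent roundings of the
    correct/retained ratios; ranks (1 = highest score) are reported for
    the correctly categorized compounds of each scored method.
    """
    if isinstance(gsea_scores, pd.Series):
        gsea = gsea_scores.astype(float)
    else:
        gsea = pd.Series({s.compound_id: s.score for s in gsea_scores}, dtype=float)
    ids = list(alikeness.sums.index)
    excluded = [c for c in ids if de_counts.get(c, 0) <= exclusion_threshold]
    retained = [c for c in ids if c not in excluded]
    if not retained:
        warnings.warn("no compounds retained after DE-count exclusion")
        return SummaryTable(table=pd.DataFrame(), percentages={}, excluded=excluded)
    tbl = pd.DataFrame(index=pd.Index(retained, name="compound_id"))
    tbl["n_de"] = [de_counts.get(c, 0) for c in retained]
    tbl["alikeness_sum"] = alikeness.sums.reindex(retained)
    tbl["alikeness_correct"] = alikeness.classified.reindex(retained)
    tbl["gsea_score"] = gsea.reindex(retained).fillna(0.0)
    tbl["gsea_correct"] = tbl["gsea_score"] > 0
    tbl["ml_correct"] = [bool(ml_correct.get(c, False)) for c in retained]
    for method, score_col in (("alikeness", "alikeness_sum"), ("gsea", "gsea_score")):
        correct = tbl[f"{method}_correct"]
        ranks = (-tbl.loc[correct, score_col]).rank(method="first").astype(int)
        tbl[f"{method}_rank"] = ranks.reindex(tbl.index)
    percentages = {}
    n = len(retained)
    for method in ("alikeness", "gsea", "ml"):
        c = int(tbl[f"{method}_correct"].sum())
        percentages[method] = (c, n, round(c / n * 100))
    return SummaryTable(table=tbl, percentages=percentages, excluded=excluded)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``panel`` (synthetic generation) or the three table directories
    must be provided. All randomness derives from ``seed``.
    """

    out_dir: str = "ictosig_out"
    seed: int = 0
    panel: Optional[PanelConfig] = None
    tool_tables: Sequence[str] = ()
    positive_tables: Sequence[str] = ()
    negative_tables: Sequence[str] = ()
    fdr_cut: float = 0.05
    lfc_cut: float = 1.5
    alikeness_cutoff: float = 10.0
    alpha: float = 0.05
    min_set_size: int = 3
    n_perm: int = 1000
    exclusion_threshold: int = 3
    global_standardize: bool = False
    restrict_noise: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key=value config file; unknown keys are errors."""
        known = {f.name for f in dataclasses.fields(cls)}
        panel_keys = {f.name for f in dataclasses.fields(PanelConfig)}
        kwargs: dict = {}
        panel_kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("panel."):
                sub = key[len("panel."):]
                if sub not in panel_keys:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                panel_kwargs[sub] = _coerce(value)
            elif key in known:
                kwargs[key] = _coerce(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if panel_kwargs or kwargs.get("panel") == "default":
            kwargs.pop("panel", None)
            kwargs["panel"] = PanelConfig(**panel_kwargs)
        return cls(**kwargs)


def _coerce(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if "," in value:
        return tuple(v.strip() for v in value.split(","))
    return value


def _load_profiles(config: PipelineConfig):
    if config.panel is not None:
        panel_cfg = dataclasses.replace(config.panel, seed=config.seed)
        profiles, truth = generate_panel(panel_cfg)
        return profiles, truth
    profiles = []
    for paths, cat in (
        (config.tool_tables, Category.TOOL),
        (config.positive_tables, Category.FAERS_POSITIVE),
        (config.negative_tables, Category.FAERS_NEGATIVE),
    ):
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing DE table: {p}")
            profiles.append(iomod.read_de_table(p, category=cat))
    if not any(Category(p.category) == Category.TOOL for p in profiles):
        raise ValueError("no tool DE tables provided")
    return profiles, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/load → threshold → subtract → score → classify → summarize.

    Writes the alikeness table (TSV), GSEA scores (JSON), the LOOCV report
    (JSON), the score comparison and the summary to ``config.out_dir`` and
    returns the result bundle in memory. Re-running with an identical
    config reproduces identical outputs.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage=%s elapsed=%.1fs seed=%s", name, time.time() - t0,
                    config.seed)

    stage("load")
    profiles, truth = _load_profiles(config)

    stage("threshold")
    gene_sets = [
        threshold_de(p, fdr_cut=config.fdr_cut, lfc_cut=config.lfc_cut)
        for p in profiles
    ]
    tools = split_by_category(gene_sets, Category.TOOL)
    positives = split_by_category(gene_sets, Category.FAERS_POSITIVE)
    negatives = split_by_category(gene_sets, Category.FAERS_NEGATIVE)
    tool_profiles = split_by_category(profiles, Category.TOOL)
    de_counts = {s.compound_id: s.n_de for s in gene_sets}

    stage("alikeness")
    alik = AlikenessClassifier(
        cutoff=config.alikeness_cutoff, restrict_noise=config.restrict_noise
    ).fit(tools, negatives=negatives)
    alik_table = alik.transform(positives)
    iomod.write_alikeness_table(alik_table, out / "alikeness.tsv")

    stage("gsea")
    scorer = GseaScoreClassifier(
        alpha=config.alpha, n_perm=config.n_perm, min_size=config.min_set_size,
        seed=config.seed,
    ).fit(tool_profiles, negatives=negatives)
    gsea_scores = scorer.score_compounds(positives)
    iomod.write_gsea_scores(gsea_scores, out / "gsea_scores.json")

    stage("ml")
    ml_report = loocv_shared_feature(positives, negatives, tools, seed=config.seed)
    (out / "ml_report.json").write_text(
        json.dumps(ml_report.to_dict(), indent=2) + "\n"
    )
    if ml_report.predictions is not None:
        ml_correct = {
            cid: bool(row["predicted"] == row["label"])
            for cid, row in ml_report.predictions.iterrows()
            if cid in {s.compound_id for s in positives}
        }
    else:
        ml_correct = {}

    stage("compare")
    rho, pval = compare_scores(alik_table, gsea_scores)
    (out / "score_comparison.json").write_text(
        json.dumps({"spearman_rho": rho, "pvalue": pval}, indent=2) + "\n"
    )

    stage("summarize")
    summary = summarize_classifications(
        alik_table, gsea_scores, ml_correct, de_counts,
        exclusion_threshold=config.exclusion_threshold,
    )
    (out / "summary.json").write_text(summary.to_json() + "\n")

    stage("done")
    return {
        "profiles": profiles,
        "truth": truth,
        "alikeness": alik_table,
        "gsea_scores": gsea_scores,
        "ml_report": ml_report,
        "spearman": (rho, pval),
        "summary": summary,
    }
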