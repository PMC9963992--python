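"""Readers and writers for the package's on-disk formats.

DE tables and count matrices are tab-delimited UTF-8 with a header row;
gene sets use the standard GMT layout (set name, description, member
genes); panel truth and scores are JSON. Floats round-trip at 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .synthetic import PanelTruth
from .types import AlikenessTable, Category, CompoundProfile, DEGeneSet, GseaScore

__all__ = [
    "read_de_table",
    "write_de_table",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "write_alikeness_table",
    "write_gsea_scores",
    "write_panel",
    "read_truth",
]

FLOAT_FMT = "%.12g"


def read_de_table(
    path: str | Path,
    compound_id: str | None = None,
    category: Category | str = Category.TOOL,
) -> CompoundProfile:
    """Read a DE table TSV (gene_id, log2fc, pvalue, fdr) into a profile."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CompoundProfile(
        compound_id=compound_id or path.stem,
        category=Category(category),
        de_table=tbl[["log2fc", "pvalue", "fdr"]],
    )


def write_de_table(profile: CompoundProfile, path: str | Path) -> None:
    profile.de_table.to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT
    )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix TSV (first column gene_id)."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {raw[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene set {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: dict[str, Sequence[str]], path: str | Path, description: str = "na"
) -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_alikeness_table(table: AlikenessTable, path: str | Path) -> None:
    table.to_frame().to_csv(
        path, sep="\t", index_label="compound_id", float_format=FLOAT_FMT
    )


def write_gsea_scores(scores: Sequence[GseaScore], path: str | Path) -> None:
    payload = [
        {
            "compound_id": s.compound_id,
            "score": s.score,
            "n_significant_sets": s.n_significant_sets,
            "contributors": [
                {"tool": t, "direction": d, "nes": nes}
                for t, d, nes in s.contributors
            ],
            "calculable": s.calculable,
        }
        for s in scores
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_panel(
    profiles: Sequence[CompoundProfile],
    truth: PanelTruth,
    out_dir: str | Path,
    counts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> None:
    """Write per-compound DE tables (and optional counts) plus truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in profiles:
        write_de_table(p, out / f"{p.compound_id}.tsv")
    if counts:
        for cid, (treated, vehicle) in counts.items():
            write_counts(treated, out / f"{cid}_counts.tsv")
            write_counts(vehicle, out / f"{cid}_vehicle_counts.tsv")
    payload = {
        "planted": {
            cid: dict(sorted(genes.items()))
            for cid, genes in truth.planted.items()
        },
        "donors": truth.donors,
        "shared": {cid: sorted(g) for cid, g in truth.shared.items()},
        "categories": {cid: cat.value for cid, cat in truth.categories.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> PanelTruth:
    raw = json.loads(Path(path).read_text())
    return PanelTruth(
        planted={c: {g: int(s) for g, s in d.items()}
                 for c, d in raw["planted"].items()},
        donors=raw["donors"],
        shared={c: frozenset(g) for c, g in raw["shared"].items()},
        categories={c: Category(v) for c, v in raw["categories"].items()},
    )


def read_de_gene_set(
    path: str | Path,
    category: Category | str,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.5,
) -> DEGeneSet:
    """Convenience: read a DE table and threshold it in one step."""
    from .de import threshold_de

    return threshold_de(
        read_de_table(path, category=Category(category)),
        fdr_cut=fdr_cut,
        lfc_cut=lfc_cut,
    )
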