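"""Synthetic compound panels with planted ground truth.

Emulates a seizure-liability screen: a panel of tool (known ictogen),
FAERS-positive and FAERS-negative compounds, each with a full differential
expression table over a shared gene universe. Positive compounds share a
configurable, direction-matched fraction of their DE genes with randomly
chosen tool donors; negative compounds carry independent "noise" signatures
that collide with tool/positive genes only at a configurable rate. Planted
structure is returned as a :class:`PanelTruth` so parameter-recovery tests
can compare pipeline output against ground truth. Coherent negative-binomial
count matrices can be drawn for any generated profile, with one shared
pseudo-vehicle baseline per panel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import Category, CompoundProfile

__all__ = ["PanelConfig", "PanelTruth", "generate_panel", "generate_counts"]

_CATEGORY_PREFIX = {
    Category.TOOL: "TOOL",
    Category.FAERS_POSITIVE: "POS",
    Category.FAERS_NEGATIVE: "NEG",
}

# Per-category DE-set size ranges (log-uniform), spanning the magnitudes seen
# in real screens: tool signatures from a few dozen to a few thousand genes,
# test compounds down to a handful, noise compounds similar.
DEFAULT_DE_SIZE_RANGE = {
    "tool": (21, 2700),
    "faers_positive": (40, 3700),
    "faers_negative": (7, 2300),
}


class ConfigError(ValueError):
    """Raised when a PanelConfig field is infeasible; names the field."""


@dataclass
class PanelConfig:
    """Parameters of a synthetic compound panel.

    Attributes
    ----------
    n_genes : int
        Size of the gene universe (ids ``G000001`` ...).
    n_tool, n_pos, n_neg : int
        Compounds per category.
    de_size_range : dict
        Per-category (low, high) inclusive range of planted DE-set sizes;
        sizes are drawn log-uniformly to mimic the heavy-tailed spread of
        real per-compound DE counts.
    share_fraction : float
        Fraction of each positive compound's DE genes copied, with
        direction, from its tool donors.
    noise_overlap : float
        Probability that a negative compound's DE gene collides with a
        tool/positive planted gene (otherwise drawn from untouched genes).
    planted_lfc : float
        Log2 effect-size magnitude of planted DE genes.
    nb_mean_log_range : tuple
        Range of per-gene baseline log2 means for the count model.
    nb_dispersion : float
        Negative-binomial dispersion (variance = mu + dispersion * mu**2).
    n_replicates : int
        Replicates per condition in generated count matrices.
    seed : int
        Root seed; identical config implies byte-identical output.
    """

    n_genes: int = 10_000
    n_tool: int = 11
    n_pos: int = 13
    n_neg: int = 10
    de_size_range: Optional[dict] = None
    share_fraction: float = 0.3
    noise_overlap: float = 0.05
    planted_lfc: float = 2.5
    nb_mean_log_range: tuple = (2.0, 10.0)
    nb_dispersion: float = 0.1
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name in ("n_tool", "n_pos", "n_neg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("share_fraction", "noise_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.de_size_range is None:
            # default ranges, clipped to the gene universe
            self.de_size_range = {
                cat: (min(lo, self.n_genes), min(hi, self.n_genes))
                for cat, (lo, hi) in DEFAULT_DE_SIZE_RANGE.items()
            }
        for cat, (lo, hi) in self.de_size_range.items():
            if not (0 <= lo <= hi <= self.n_genes):
                raise ConfigError(
                    f"de_size_range[{cat!r}]=({lo}, {hi}) must lie within "
                    f"[0, n_genes={self.n_genes}]"
                )
        if self.planted_lfc <= 0:
            raise ConfigError("planted_lfc must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")


@dataclass
class PanelTruth:
    """Planted structure of a generated panel.

    ``planted`` maps compound id to ``{gene_id: +1 | -1}``; ``donors`` maps
    each positive compound to the tool compounds it copied genes from;
    ``shared`` maps each positive compound to the copied gene ids.
    """

    planted: dict[str, dict[str, int]]
    donors: dict[str, list[str]]
    shared: dict[str, frozenset[str]]
    categories: dict[str, Category]


def _gene_ids(n_genes: int) -> np.ndarray:
    return np.array([f"G{i:06d}" for i in range(1, n_genes + 1)], dtype=object)


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(max(lo, 1)), np.log(hi)))))


def _de_table(
    rng: np.random.Generator,
    universe: np.ndarray,
    planted: dict[str, int],
    planted_lfc: float,
) -> pd.DataFrame:
    """Full-universe DE table where exactly the planted genes are significant."""
    n = len(universe)
    log2fc = rng.normal(0.0, 0.3, size=n)
    pvalue = rng.uniform(0.05, 1.0, size=n)
    fdr = pvalue + (1.0 - pvalue) * rng.uniform(0.0, 1.0, size=n)
    tbl = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "fdr": fdr}, index=universe
    )
    if planted:
        genes = list(planted)
        signs = np.array([planted[g] for g in genes], dtype=float)
        mag = planted_lfc * (1.0 + rng.uniform(-0.15, 0.5, size=len(genes)))
        mag = np.maximum(mag, 1.6)  # keep planted genes above the 1.5 cut
        f = 10.0 ** rng.uniform(-8.0, np.log10(0.049), size=len(genes))
        p = np.clip(f * rng.uniform(0.05, 1.0, size=len(genes)), 1e-300, None)
        tbl.loc[genes, "log2fc"] = signs * mag
        tbl.loc[genes, "pvalue"] = p
        tbl.loc[genes, "fdr"] = f
    return tbl


def generate_panel(config: PanelConfig) -> tuple[list[CompoundProfile], PanelTruth]:
    """Generate a compound panel with planted DE structure.

    Deterministic given ``config`` (including its seed). Each compound's DE
    table covers the whole gene universe; exactly the planted genes pass
    FDR < 0.05 and |log2FC| > 1.5.
    """
    rng = np.random.default_rng(config.seed)
    universe = _gene_ids(config.n_genes)

    planted: dict[str, dict[str, int]] = {}
    donors: dict[str, list[str]] = {}
    shared: dict[str, frozenset[str]] = {}
    categories: dict[str, Category] = {}

    def draw_genes(k: int, pool: np.ndarray) -> np.ndarray:
        k = min(k, len(pool))
        return rng.choice(pool, size=k, replace=False)

    # Tool compounds: independent signed signatures.
    tool_ids = [f"TOOL{i:02d}" for i in range(1, config.n_tool + 1)]
    lo, hi = config.de_size_range["tool"]
    for cid in tool_ids:
        size = _draw_size(rng, lo, hi)
        genes = draw_genes(size, universe)
        signs = rng.choice([-1, 1], size=len(genes))
        planted[cid] = dict(zip(genes.tolist(), signs.tolist()))
        categories[cid] = Category.TOOL

    tool_union = sorted({g for cid in tool_ids for g in planted[cid]})

    # Positive compounds: a share_fraction slice copied (with sign) from
    # randomly chosen tool donors, the remainder drawn from the universe.
    pos_ids = [f"POS{i:02d}" for i in range(1, config.n_pos + 1)]
    lo, hi = config.de_size_range["faers_positive"]
    for cid in pos_ids:
        size = _draw_size(rng, lo, hi)
        n_shared = int(round(config.share_fraction * size))
        chosen: dict[str, int] = {}
        my_donors: list[str] = []
        if n_shared > 0 and tool_ids:
            n_donors = int(rng.integers(1, min(3, len(tool_ids)) + 1))
            my_donors = sorted(
                rng.choice(np.array(tool_ids, dtype=object), size=n_donors,
                           replace=False).tolist()
            )
            donor_pool: dict[str, int] = {}
            for d in my_donors:
                donor_pool.update(planted[d])
            pool_genes = np.array(sorted(donor_pool), dtype=object)
            take = draw_genes(n_shared, pool_genes)
            chosen.update({g: donor_pool[g] for g in take.tolist()})
        shared[cid] = frozenset(chosen)
        donors[cid] = my_donors
        n_rest = size - len(chosen)
        if n_rest > 0:
            rest_pool = universe[~np.isin(universe, list(chosen))]
            rest = draw_genes(n_rest, rest_pool)
            rest_signs = rng.choice([-1, 1], size=len(rest))
            chosen.update(dict(zip(rest.tolist(), rest_signs.tolist())))
        planted[cid] = chosen
        categories[cid] = Category.FAERS_POSITIVE

    # Negative compounds: independent noise, colliding with tool/positive
    # genes only at rate noise_overlap.
    signal_union = sorted(
        {g for cid in tool_ids + pos_ids for g in planted[cid]}
    )
    signal_arr = np.array(signal_union, dtype=object)
    quiet_arr = universe[~np.isin(universe, signal_arr)]
    neg_ids = [f"NEG{i:02d}" for i in range(1, config.n_neg + 1)]
    lo, hi = config.de_size_range["faers_negative"]
    for cid in neg_ids:
        size = _draw_size(rng, lo, hi)
        n_collide = int(rng.binomial(size, config.noise_overlap))
        genes = np.concatenate(
            [
                draw_genes(n_collide, signal_arr),
                draw_genes(size - n_collide, quiet_arr),
            ]
        )
        signs = rng.choice([-1, 1], size=len(genes))
        planted[cid] = dict(zip(genes.tolist(), signs.tolist()))
        categories[cid] = Category.FAERS_NEGATIVE

    profiles = [
        CompoundProfile(
            compound_id=cid,
            category=categories[cid],
            de_table=_de_table(rng, universe, planted[cid], config.planted_lfc),
        )
        for cid in tool_ids + pos_ids + neg_ids
    ]
    truth = PanelTruth(
        planted=planted, donors=donors, shared=shared, categories=categories
    )
    return profiles, truth


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, size: tuple
) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p[:, None] * np.ones(size))


def generate_counts(
    profile: CompoundProfile, config: PanelConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (treated, vehicle) negative-binomial count matrices for a profile.

    Baseline per-gene log2 means are drawn from the panel seed alone, so
    every compound in a panel shares one pseudo-vehicle condition; the
    treated condition shifts each gene's mean by the profile's own log2
    fold-change (planted genes therefore shift by ±planted_lfc-scale
    effects, the rest only by their small null jitter).
    """
    if config.nb_dispersion <= 0:
        raise ConfigError("nb_dispersion must be positive")
    genes = profile.de_table.index.to_numpy(dtype=object)
    base_rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.nb_mean_log_range
    base_mu = 2.0 ** base_rng.uniform(lo, hi, size=len(genes))

    crc = zlib.crc32(profile.compound_id.encode()) & 0x7FFFFFFF
    rng_t = np.random.default_rng([config.seed, 3, crc])
    rng_v = np.random.default_rng([config.seed, 4])  # shared vehicle per panel

    lfc = profile.de_table["log2fc"].to_numpy(dtype=float)
    mu_t = base_mu * 2.0 ** lfc
    shape = (len(genes), config.n_replicates)
    treated = _nb_draw(rng_t, mu_t, config.nb_dispersion, shape)
    vehicle = _nb_draw(rng_v, base_mu, config.nb_dispersion, shape)
    cols_t = [f"{profile.compound_id}_rep{i+1}" for i in range(config.n_replicates)]
    cols_v = [f"VEHICLE_rep{i+1}" for i in range(config.n_replicates)]
    return (
        pd.DataFrame(treated, index=genes, columns=cols_t),
        pd.DataFrame(vehicle, index=genes, columns=cols_v),
    )
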