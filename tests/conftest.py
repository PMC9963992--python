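import numpy as np
import pandas as pd
import pytest

from ictosig.synthetic import PanelConfig, generate_panel
from ictosig.types import Category, CompoundProfile, DEGeneSet


def make_profile(compound_id, rows, category=Category.TOOL):
    """Build a CompoundProfile from {gene: (log2fc, pvalue, fdr)}."""
    tbl = pd.DataFrame.from_dict(
        rows, orient="index", columns=["log2fc", "pvalue", "fdr"]
    )
    return CompoundProfile(compound_id=compound_id, category=category, de_table=tbl)


def make_set(compound_id, up=(), down=(), category=None):
    return DEGeneSet(compound_id=compound_id, up=frozenset(up),
                     down=frozenset(down), category=category)


def random_gene_set(rng, compound_id, universe, n_up, n_down, category=None):
    genes = rng.choice(universe, size=n_up + n_down, replace=False)
    return make_set(compound_id, up=genes[:n_up], down=genes[n_up:],
                    category=category)


SMALL_PANEL_CONFIG = PanelConfig(
    n_genes=2000,
    n_tool=4,
    n_pos=4,
    n_neg=3,
    de_size_range={
        "tool": (30, 250),
        "faers_positive": (20, 200),
        "faers_negative": (20, 200),
    },
    seed=7,
)


@pytest.fixture(scope="session")
def small_panel():
    """A small synthetic panel shared across tests (read-only)."""
    return generate_panel(SMALL_PANEL_CONFIG)


@pytest.fixture(scope="session")
def small_panel_sets(small_panel):
    from ictosig.de import threshold_de

    profiles, truth = small_panel
    return [threshold_de(p) for p in profiles], truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
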