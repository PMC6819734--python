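"""Shared fixtures: printed didactic lineage block and small communities."""

import numpy as np
import pandas as pd
import pytest

from microgame.synthetic_data import CommunitySpec, simulate_community
from microgame.taxa_io import AbundanceMatrix, TaxonomyTable

# The didactic 8-strain hierarchy: strains 1-8 under species 1-4, genera 1-2,
# and a single family/order/class/phylum. Taxon ids follow the subscript
# convention phylum..strain read left to right.
TABLE1_ROWS = [
    ("1111111", "1", "1", "1", "1", "1", "1", "1"),
    ("1111112", "2", "1", "1", "1", "1", "1", "1"),
    ("1111123", "3", "2", "1", "1", "1", "1", "1"),
    ("1111124", "4", "2", "1", "1", "1", "1", "1"),
    ("1111235", "5", "3", "2", "1", "1", "1", "1"),
    ("1111236", "6", "3", "2", "1", "1", "1", "1"),
    ("1111247", "7", "4", "2", "1", "1", "1", "1"),
    ("1111248", "8", "4", "2", "1", "1", "1", "1"),
]


@pytest.fixture
def table1_taxonomy() -> TaxonomyTable:
    df = pd.DataFrame(
        TABLE1_ROWS,
        columns=["taxon_id", "strain", "species", "genus", "family", "order", "class", "phylum"],
    ).set_index("taxon_id")
    return TaxonomyTable(df)


@pytest.fixture
def table1_abundance(table1_taxonomy) -> AbundanceMatrix:
    rng = np.random.default_rng(11)
    taxa = list(table1_taxonomy.taxa)
    df = pd.DataFrame(
        rng.lognormal(3.0, 1.0, size=(len(taxa), 3)),
        index=pd.Index(taxa, name="taxon_id"),
        columns=["h1", "h2", "h3"],
    )
    return AbundanceMatrix(df)


def small_spec(seed: int = 0, **overrides) -> CommunitySpec:
    kwargs = dict(
        rank_sizes={"genus": 12, "phylum": 3},
        n_hosts_per_group={"winter": 12, "summer": 10},
        n_shared_hosts=5,
        cooperation_strength=0.3,
        parasitism_shift={("P1", "P2"): 0.6},
        seed=seed,
    )
    kwargs.update(overrides)
    return CommunitySpec(**kwargs)


@pytest.fixture
def small_community():
    """12 genera / 3 phyla, two seasons, deterministic."""
    return simulate_community(small_spec(0))
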