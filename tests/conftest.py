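import numpy as np
import pandas as pd
import pytest

import phyloallometry as pa


@pytest.fixture
def three_taxon_tree():
    """Ultrametric ((A:1,B:1):1,C:2); — covariance known by hand."""
    return pa.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_tree():
    return pa.Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star_tree():
    return pa.Phylogeny.from_newick("(A:2,B:2,C:2,D:2);")


@pytest.fixture(scope="session")
def yule_tree_59():
    """One reproducible 59-tip tree shared by the simulation-heavy tests."""
    return pa.simulate_tree(59, seed=59)


@pytest.fixture(scope="session")
def chol_59(yule_tree_59):
    return np.linalg.cholesky(yule_tree_59.bm_covariance().C)


def make_table(df, species_col="species", log_cols=(), index=None):
    data = pd.DataFrame(df)
    if index is not None:
        data.index = pd.Index(index, name="observation_id")
    return pa.TraitTable(data, species_col=species_col, log_cols=log_cols)


@pytest.fixture
def simple_species_table():
    rng = np.random.default_rng(7)
    x = rng.normal(size=4)
    return make_table({
        "species": ["A", "B", "C", "D"],
        "x": x,
        "y": 2.0 * x + 1.0,
    }, index=["A", "B", "C", "D"])
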