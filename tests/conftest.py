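import numpy as np
import pandas as pd
import pytest

from phylospatial.taxonomy_tree import (
    CladeSpec,
    LanguageTaxonomy,
    TaxonEntry,
    build_hierarchy,
)


@pytest.fixture(scope="session")
def six_tip_taxonomy():
    """Two clades (C = 0.8 and 0.4, L_c = 3 each), six tips, hand-enumerable."""
    entries = [
        TaxonEntry("a1", "aaa", "A", ("x", "y", "z"), 3),
        TaxonEntry("a2", "aab", "A", ("x", "y", "w"), 3),
        TaxonEntry("a3", "aac", "A", ("x", "q"), 2),
        TaxonEntry("b1", "bba", "B", ("u", "v"), 2),
        TaxonEntry("b2", "bbb", "B", ("u", "v", "t"), 3),
        TaxonEntry("b3", "bbc", "B", ("r",), 1),
    ]
    clades = [CladeSpec("A", 0.8, 3), CladeSpec("B", 0.4, 3)]
    return LanguageTaxonomy(entries), clades


@pytest.fixture(scope="session")
def six_tip_tree(six_tip_taxonomy):
    taxonomy, clades = six_tip_taxonomy
    return build_hierarchy(taxonomy, clades)


@pytest.fixture(scope="session")
def small_geometry():
    """A fixed 30-society phylogeny + geography for fitting tests."""
    from phylospatial.spatial import distance_matrix
    from phylospatial.synthetic_data import simulate_coordinates, simulate_taxonomy
    from phylospatial.taxonomy_tree import phylo_similarity

    tax, clades = simulate_taxonomy(30, 4, seed=7)
    tree = build_hierarchy(tax, clades)
    P = phylo_similarity(tree)
    coords = simulate_coordinates(
        30, seed=8, clustered=True, clade_of=[e.clade_id for e in tax.entries]
    )
    ids = list(coords.index)
    return P.loc[ids, ids], distance_matrix(coords), coords


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
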