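import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from stomabiome import bundle_io, simulate
from stomabiome.bundle_io import (
    Bundle, FeatureTable, GeneSetCatalog, KoCopyTable, PhyloTree,
    SampleMetadata, TaxonomyMap, TraitDB,
)


@pytest.fixture
def tiny_tree():
    return PhyloTree(TreeNode.read(["((A:1,B:1):1,(C:2,D:1):1):0;"]))


@pytest.fixture
def tiny_bundle(tiny_tree):
    """Hand-built four-sample, four-feature bundle, fully consistent."""
    table = FeatureTable(pd.DataFrame(
        [[10, 0, 5, 5], [0, 8, 8, 4], [6, 6, 4, 4], [3, 7, 0, 10]],
        index=["s1", "s2", "s3", "s4"], columns=["A", "B", "C", "D"]))
    taxonomy = TaxonomyMap(pd.DataFrame(
        {"domain": ["Bacteria"] * 4, "phylum": ["P1", "P1", "P2", "P2"],
         "class": ["C1"] * 4, "order": ["O1", "O1", "O2", "O2"],
         "family": ["F1", "F1", "F2", "F2"],
         "genus": ["gA", "gA", "gC", "gD"],
         "species": ["spA", "", "", "spD"]},
        index=["A", "B", "C", "D"]))
    metadata = SampleMetadata(pd.DataFrame(
        {"stoma_status": ["stoma", "stoma", "non_stoma", "non_stoma"],
         "antibiotic_user": ["no", "no", "no", "no"],
         "age": [50, 60, 55, 65]},
        index=["s1", "s2", "s3", "s4"]))
    traits = TraitDB(pd.DataFrame(
        [{"rank": "genus", "name": "gA", "gram": "GramPos", "oxygen": "Anaerobe"},
         {"rank": "genus", "name": "gC", "gram": "Various", "oxygen": "NonAnaerobe"},
         {"rank": "species", "name": "spD", "gram": "GramNeg", "oxygen": "Anaerobe"}]))
    copies = KoCopyTable(pd.DataFrame(
        [[2.0, 1.0, 1.0], [1.0, 1.0, 0.0], [0.0, 2.0, 2.0], [1.0, 0.0, 3.0]],
        index=["A", "B", "C", "D"], columns=["K1", "K2", "K3"]))
    catalog = GeneSetCatalog({"pw1": {"K1", "K2"}, "pw2": {"K3"}},
                             {"pw1": "pathway one", "pw2": "pathway two"})
    return Bundle(table=table, taxonomy=taxonomy, tree=tiny_tree,
                  metadata=metadata, traits=traits, ko_copies=copies,
                  catalog=catalog)


@pytest.fixture(scope="session")
def small_sim_bundle():
    """A small exchangeable-groups synthetic bundle (session-cached)."""
    return simulate.simulate_bundle(simulate.null_config(seed=42))


@pytest.fixture(scope="session")
def paper_like_bundle():
    """One study-shaped synthetic bundle (session-cached)."""
    return simulate.simulate_bundle(simulate.SimConfig(seed=5))
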