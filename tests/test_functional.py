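"""KO projection, pathway aggregation and genus-pathway z-scores."""

import numpy as np
import pandas as pd
import pytest

from stomabiome import functional
from stomabiome.bundle_io import (
    FeatureTable, GeneSetCatalog, KoCopyTable, TaxonomyMap,
)


def make_rel(rows, features):
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                      columns=features, dtype=float)
    return FeatureTable(df.div(df.sum(axis=1), axis=0), kind="relabund")


class TestProjectKo:
    def test_single_feature_copies_become_shares(self):
        t = make_rel([[1.0]], ["A"])
        copies = KoCopyTable(pd.DataFrame([[2.0, 1.0, 1.0]], index=["A"],
                                          columns=["K1", "K2", "K3"]))
        out = functional.project_ko(t, copies)
        assert np.allclose(out.values[0], [0.5, 0.25, 0.25])

    def test_identical_compositions_identical_rows(self):
        t = make_rel([[2, 3], [4, 6]], ["A", "B"])
        copies = KoCopyTable(pd.DataFrame([[1.0, 2.0], [3.0, 1.0]],
                                          index=["A", "B"], columns=["K1", "K2"]))
        out = functional.project_ko(t, copies)
        assert np.allclose(out.values[0], out.values[1])

    def test_hand_multiplied_product(self):
        t = make_rel([[1, 1, 2]], ["A", "B", "C"])
        copies = KoCopyTable(pd.DataFrame(
            [[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]],
            index=["A", "B", "C"], columns=["K1", "K2"]))
        out = functional.project_ko(t, copies)
        raw = np.array([0.25 * 1 + 0.5 * 1, 0.25 * 2 + 0.5 * 1])
        assert np.allclose(out.values[0], raw / raw.sum())

    def test_linearity_of_raw_projection(self):
        rng = np.random.default_rng(0)
        copies = KoCopyTable(pd.DataFrame(rng.integers(0, 4, (3, 5)).astype(float),
                                          index=list("ABC"),
                                          columns=[f"K{i}" for i in range(5)]))
        a = rng.dirichlet([1, 1, 1])
        b = rng.dirichlet([1, 1, 1])
        mix = make_rel([(a + b) / 2], list("ABC"))
        c = copies.data.to_numpy()
        raw_mix = mix.values[0] @ c
        assert np.allclose(raw_mix, (a @ c + b @ c) / 2)

    def test_exact_zeros_preserved(self):
        t = make_rel([[1, 0]], ["A", "B"])
        copies = KoCopyTable(pd.DataFrame([[1.0, 0.0], [0.0, 5.0]],
                                          index=["A", "B"], columns=["K1", "K2"]))
        out = functional.project_ko(t, copies)
        assert out.data.loc["s0", "K2"] == 0.0

    def test_missing_present_feature_rejected(self):
        t = make_rel([[1, 1]], ["A", "B"])
        copies = KoCopyTable(pd.DataFrame([[1.0]], index=["A"], columns=["K1"]))
        with pytest.raises(ValueError, match="missing from copy table"):
            functional.project_ko(t, copies)


class TestAggregatePathways:
    def make_ko(self, rows, kos):
        return make_rel(rows, kos)

    def test_single_pathway_holding_all_kos(self):
        ko = self.make_ko([[0.2, 0.3, 0.5]], ["K1", "K2", "K3"])
        cat = GeneSetCatalog({"pw": {"K1", "K2", "K3"}})
        rel, raw = functional.aggregate_pathways(ko, cat)
        assert raw["pw"].iloc[0] == pytest.approx(1.0)
        assert rel.values[0, 0] == pytest.approx(1.0)

    def test_disjoint_partition_raw_sums_to_one(self):
        ko = self.make_ko([[0.2, 0.3, 0.5], [0.6, 0.1, 0.3]], ["K1", "K2", "K3"])
        cat = GeneSetCatalog({"a": {"K1"}, "b": {"K2", "K3"}})
        _, raw = functional.aggregate_pathways(ko, cat)
        assert np.allclose(raw.sum(axis=1), 1.0)

    def test_overlapping_sets_hand_computed(self):
        ko = self.make_ko([[0.5, 0.25, 0.25]], ["K1", "K2", "K3"])
        cat = GeneSetCatalog({"a": {"K1", "K2"}, "b": {"K2", "K3"}})
        rel, raw = functional.aggregate_pathways(ko, cat)
        assert raw.iloc[0].tolist() == pytest.approx([0.75, 0.5])
        assert np.allclose(rel.values[0], [0.6, 0.4])

    def test_orphan_kos_dropped_with_warning(self):
        ko = self.make_ko([[1.0]], ["K1"])
        cat = GeneSetCatalog({"a": {"K1", "K9"}})
        with pytest.warns(UserWarning, match="absent"):
            _, raw = functional.aggregate_pathways(ko, cat)
        assert raw["a"].iloc[0] == pytest.approx(1.0)

    def test_empty_catalog_rejected(self):
        ko = self.make_ko([[1.0]], ["K1"])
        with pytest.raises(ValueError):
            functional.aggregate_pathways(ko, GeneSetCatalog({}))


class TestGenusPathwayZscores:
    @pytest.fixture
    def four_genus_setup(self):
        copies = KoCopyTable(pd.DataFrame(
            [[2.0, 0.0, 1.0], [4.0, 0.0, 1.0], [0.0, 3.0, 1.0], [1.0, 1.0, 1.0]],
            index=list("abcd"), columns=["K1", "K2", "K3"]))
        taxonomy = TaxonomyMap(pd.DataFrame(
            {"domain": ["B"] * 4, "phylum": ["P"] * 4, "class": ["C"] * 4,
             "order": ["O"] * 4, "family": ["F"] * 4,
             "genus": ["g1", "g2", "g3", "g4"], "species": [""] * 4},
            index=list("abcd")))
        catalog = GeneSetCatalog({"pwA": {"K1", "K2"}, "pwB": {"K3"}})
        return copies, catalog, taxonomy

    def test_hand_computed_zscores(self, four_genus_setup):
        copies, catalog, taxonomy = four_genus_setup
        z, flat = functional.genus_pathway_zscores(copies, catalog, taxonomy)
        contrib = np.array([1.0, 2.0, 1.5, 1.0])  # mean copies over {K1,K2}
        expected = (contrib - contrib.mean()) / contrib.std(ddof=1)
        assert np.allclose(z.loc[["g1", "g2", "g3", "g4"], "pwA"], expected,
                           atol=1e-12)

    def test_constant_column_flagged_zero(self, four_genus_setup):
        copies, catalog, taxonomy = four_genus_setup
        z, flat = functional.genus_pathway_zscores(copies, catalog, taxonomy)
        assert "pwB" in flat
        assert np.allclose(z["pwB"], 0.0)

    def test_exclusive_pathway_peaks_at_carrier_genus(self):
        copies = KoCopyTable(pd.DataFrame(
            [[1.0, 5.0], [1.0, 0.0], [1.0, 0.0]],
            index=list("abc"), columns=["K1", "K2"]))
        taxonomy = TaxonomyMap(pd.DataFrame(
            {"domain": ["B"] * 3, "phylum": ["P"] * 3, "class": ["C"] * 3,
             "order": ["O"] * 3, "family": ["F"] * 3,
             "genus": ["g1", "g2", "g3"], "species": [""] * 3},
            index=list("abc")))
        z, _ = functional.genus_pathway_zscores(
            copies, GeneSetCatalog({"pw": {"K2"}}), taxonomy)
        assert z["pw"].idxmax() == "g1"

    def test_columns_standardized(self, four_genus_setup):
        copies, catalog, taxonomy = four_genus_setup
        z, flat = functional.genus_pathway_zscores(copies, catalog, taxonomy)
        for col in z.columns:
            if col in flat:
                continue
            assert z[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[col].std(ddof=1) == pytest.approx(1.0)
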