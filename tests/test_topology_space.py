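"""Recipe enumeration and tree realization over the exemplar scaffold."""

from collections import Counter

import pytest

from roguestate.topology_space import (BACKBONES, CERATOPHYLLUM_PLACEMENTS,
                                       TopologyRecipe, clade_leafsets,
                                       enumerate_recipes, load_templates,
                                       pairwise_distinct, realize,
                                       recipes_to_dataframe)
from roguestate.treeio import CladeRef, RootedTree, TreeError, read_newick


class TestEnumeration:
    def test_exactly_96_unique_recipes(self, recipes):
        assert len(recipes) == 96
        assert len(set(recipes)) == 96

    def test_32_per_backbone_24_per_placement(self, recipes):
        by_backbone = Counter(r.backbone for r in recipes)
        assert by_backbone == {b: 32 for b in BACKBONES}
        by_cer = Counter(r.ceratophyllum for r in recipes)
        assert by_cer == {c: 24 for c in CERATOPHYLLUM_PLACEMENTS}

    def test_ordering_is_backbone_major(self, recipes):
        assert [r.backbone for r in recipes[:32]] == ["JM"] * 32
        assert recipes[0].ceratophyllum == "sister_chloranthaceae"

    def test_bad_field_rejected(self):
        with pytest.raises(ValueError, match="bad ceratophyllum"):
            TopologyRecipe("JM", "sister_mars", "sister_cabombaceae",
                           "sister_papaveraceae", "araceae_first")

    def test_dataframe_round_trip(self, recipes):
        df = recipes_to_dataframe(recipes)
        assert len(df) == 96
        assert df.drop_duplicates().shape[0] == 96


class TestTemplates:
    def test_three_distinct_resolutions(self, templates):
        assert set(templates) == set(BACKBONES)
        sigs = set()
        for t in templates.values():
            # collapse Chloranthaceae away: resolution of the three big clades
            reduced = t.tree.prune({"CHLORANTHACEAE"})
            sigs.add(reduced.canonical_signature())
        assert len(sigs) == 3


def _realize(recipe, templates, exemplar):
    return realize(recipe, templates, exemplar.scaffold)


class TestRealize:
    def test_stem_node_for_chloranthaceae_placement(self, templates, exemplar):
        recipe = TopologyRecipe("JM", "sister_chloranthaceae",
                                "sister_nymphaeoideae",
                                "sister_papaveraceae", "araceae_first")
        res = _realize(recipe, templates, exemplar)
        expected = res.tree.mrca({"Ceratophyllum_demersum",
                                  "Chloranthus_spicatus"})
        assert res.ceratophyllum_stem is expected
        # stem clade = Ceratophyllum + Chloranthaceae only
        assert res.tree.leafset(res.ceratophyllum_stem) == (
            clade_leafsets(exemplar.scaffold)["Chloranthaceae"]
            | {"Ceratophyllum_demersum"})

    def test_sister_to_all_other_mesangiosperms(self, templates, exemplar):
        recipe = TopologyRecipe("JM", "sister_all_other_mesangiosperms",
                                "sister_nymphaeoideae",
                                "sister_papaveraceae", "araceae_first")
        res = _realize(recipe, templates, exemplar)
        # the stem node IS the redefined mesangiosperm crown node
        assert res.ceratophyllum_stem is res.mesangiosperm_crown

    def test_crown_node_spans_five_clades(self, templates, exemplar):
        recipe = TopologyRecipe("1KP", "sister_monocots",
                                "sister_cabombaceae",
                                "sister_other_ranunculales",
                                "tofieldiaceae_first")
        res = _realize(recipe, templates, exemplar)
        clades = clade_leafsets(exemplar.scaffold)
        crown_leaves = res.tree.leafset(res.mesangiosperm_crown)
        expected = (clades["Eudicots"] | clades["Monocots"]
                    | clades["Magnoliids"] | clades["Chloranthaceae"]
                    | {"Ceratophyllum_demersum"})
        assert crown_leaves == expected

    @pytest.mark.parametrize("nuphar,expect_sister", [
        ("sister_nymphaeoideae", {"Nymphaea_alba", "Victoria_amazonica"}),
        ("sister_cabombaceae", {"Cabomba_caroliniana", "Brasenia_schreberi"}),
    ])
    def test_nuphar_flag(self, templates, exemplar, nuphar, expect_sister):
        recipe = TopologyRecipe("DE", "sister_eudicots", nuphar,
                                "sister_papaveraceae", "araceae_first")
        res = _realize(recipe, templates, exemplar)
        parent = res.tree.leaf_node("Nuphar_lutea").parent_node
        assert res.tree.leafset(parent) == expect_sister | {"Nuphar_lutea"}

    @pytest.mark.parametrize("euptelea,expect_sister", [
        ("sister_papaveraceae", {"Papaver_somniferum",
                                 "Eschscholzia_californica"}),
        ("sister_other_ranunculales", {"Papaver_somniferum",
                                       "Eschscholzia_californica",
                                       "Ranunculus_acris",
                                       "Aquilegia_vulgaris"}),
    ])
    def test_euptelea_flag(self, templates, exemplar, euptelea, expect_sister):
        recipe = TopologyRecipe("JM", "sister_chloranthaceae",
                                "sister_nymphaeoideae", euptelea,
                                "araceae_first")
        res = _realize(recipe, templates, exemplar)
        parent = res.tree.leaf_node("Euptelea_pleiosperma").parent_node
        assert res.tree.leafset(parent) == expect_sister | {"Euptelea_pleiosperma"}

    @pytest.mark.parametrize("flag,first_family", [
        ("araceae_first", {"Arum_maculatum", "Spathiphyllum_wallisii"}),
        ("tofieldiaceae_first", {"Tofieldia_calyculata", "Pleea_tenuifolia"}),
    ])
    def test_alismatales_flag(self, templates, exemplar, flag, first_family):
        recipe = TopologyRecipe("JM", "sister_chloranthaceae",
                                "sister_nymphaeoideae",
                                "sister_papaveraceae", flag)
        res = _realize(recipe, templates, exemplar)
        clades = clade_leafsets(exemplar.scaffold)
        alism = res.tree.resolve(CladeRef(leaves=clades["Alismatales"]))
        children = [res.tree.leafset(c) for c in alism.child_nodes()]
        assert first_family in children  # basal family diverges first

    def test_deterministic(self, templates, exemplar):
        recipe = TopologyRecipe("DE", "sister_monocots", "sister_cabombaceae",
                                "sister_other_ranunculales", "araceae_first")
        a = _realize(recipe, templates, exemplar)
        b = _realize(recipe, templates, exemplar)
        assert a.tree.is_isomorphic(b.tree)
        assert a.tree.to_newick() == b.tree.to_newick()

    def test_missing_clade_label_is_named(self, templates, exemplar):
        broken = read_newick(
            exemplar.scaffold.to_newick().replace("Papaveraceae", "Popaveraceae"))
        recipe = TopologyRecipe("JM", "sister_chloranthaceae",
                                "sister_nymphaeoideae",
                                "sister_papaveraceae", "araceae_first")
        with pytest.raises(TreeError, match="Papaveraceae"):
            realize(recipe, templates, broken)

    def test_rogue_graft_order_does_not_matter(self, templates, exemplar):
        """Regraft Nuphar and Euptelea in either order: same topology."""
        recipe = TopologyRecipe("JM", "sister_eudicots", "sister_cabombaceae",
                                "sister_papaveraceae", "araceae_first")
        base = _realize(recipe, templates, exemplar).tree
        t = base.prune({"Nuphar_lutea"}).prune({"Euptelea_pleiosperma"})
        nuphar = read_newick("Nuphar_lutea;")
        euptelea = read_newick("Euptelea_pleiosperma;")
        cab = {"Cabomba_caroliniana", "Brasenia_schreberi"}
        pap = {"Papaver_somniferum", "Eschscholzia_californica"}
        ab, _ = t.graft_sister(nuphar, cab)
        ab, _ = ab.graft_sister(euptelea, pap)
        ba, _ = t.graft_sister(euptelea, pap)
        ba, _ = ba.graft_sister(nuphar, cab)
        assert ab.is_isomorphic(ba)
        assert ab.is_isomorphic(base)


class TestPairwiseDistinct:
    def test_identical_trees_reported(self):
        a = read_newick("((A,B),C);")
        b = read_newick("(C,(B,A));")  # same rooted topology, reordered
        ok, dupes = pairwise_distinct([a, b])
        assert not ok and dupes == [(0, 1)]

    def test_singleton_true(self):
        ok, dupes = pairwise_distinct([read_newick("((A,B),C);")])
        assert ok and not dupes

    def test_differing_leafsets_rejected(self):
        with pytest.raises(TreeError, match="leaf sets"):
            pairwise_distinct([read_newick("((A,B),C);"),
                               read_newick("((A,B),D);")])
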