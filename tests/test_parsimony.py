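"""Sankoff unit-cost engine vs. the exhaustive oracle and Fitch."""

import numpy as np
import pytest
import dendropy

from roguestate.characters import FULL_SET, CharacterColumn
from roguestate.parsimony import (INF, brute_force_mpr, downpass, fitch_length,
                                  mpr_sets, tree_length)
from roguestate.treeio import RootedTree, TreeError, read_newick

from conftest import random_column, random_instance, random_tree


def col(**states):
    mapping = {}
    for name, value in states.items():
        if value == "?":
            mapping[name] = FULL_SET
        else:
            mapping[name] = frozenset({int(value)})
    return CharacterColumn(mapping)


def rootings(tree):
    """Every rooting of the tree's unrooted topology (test helper)."""
    text = tree.to_newick()
    base = read_newick(text)
    leafsets = [base.leafset(n) for n in base.nodes()
                if n.parent_node is not None]
    out = [base]
    for ls in leafsets:
        t = read_newick(text)
        node = t.resolve(ls) if len(ls) > 1 else t.leaf_node(next(iter(ls)))
        if node.parent_node is t.root and len(t.root.child_nodes()) == 2:
            continue  # same unrooted edge as the original root
        t._dtree.reroot_at_edge(node.edge)
        t._dtree.suppress_unifurcations()
        out.append(RootedTree(t._dtree))
    return out


class TestWorkedExamples:
    """Micro-instances with expectations frozen from the exhaustive oracle."""

    def test_three_leaf_informative(self):
        t = read_newick("((A,B),C);")
        c = col(A=0, B=1, C=0)
        vectors = downpass(t, c)
        assert vectors[t.root] == (1, 2)
        result = mpr_sets(t, c)
        oracle = brute_force_mpr(t, c)
        assert result.tree_length == oracle.tree_length == 1
        assert result.states_at(t.root) == frozenset({0})
        assert result.states_at(t.mrca({"A", "B"})) == frozenset({0})
        assert oracle.states_at(t.root) == frozenset({0})

    def test_three_leaf_with_missing(self):
        t = read_newick("((A,B),C);")
        c = col(A=0, B="?", C=1)
        assert downpass(t, c)[t.root] == (1, 1)
        result = mpr_sets(t, c)
        oracle = brute_force_mpr(t, c)
        assert result.tree_length == oracle.tree_length == 1
        assert result.states_at(t.root) == FULL_SET  # uncertain
        assert oracle.states_at(t.root) == FULL_SET

    def test_single_leaf(self):
        t = read_newick("X;")
        assert tree_length(t, col(X=1)) == 0

    def test_four_leaf_two_changes(self):
        t = read_newick("((A,B),(C,D));")
        assert tree_length(t, col(A=0, B=1, C=0, D=1)) == 2

    def test_monomorphic_column(self):
        t = read_newick("((A,B),(C,D));")
        result = mpr_sets(t, col(A=1, B=1, C=1, D=1))
        assert result.tree_length == 0
        assert all(s == frozenset({1}) for s in result.node_sets.values())

    def test_all_missing_column(self):
        t = read_newick("((A,B),C);")
        c = col(A="?", B="?", C="?")
        assert tree_length(t, c) == 0
        assert all(s == FULL_SET for s in mpr_sets(t, c).node_sets.values())

    @pytest.mark.parametrize("n,k", [(4, 1), (5, 2), (6, 3), (7, 2)])
    def test_star_tree_closed_form(self, n, k):
        """On a star tree, length = min(k, n-k) for k present leaves."""
        names = [f"L{i}" for i in range(n)]
        t = read_newick("(" + ",".join(names) + ");")
        c = CharacterColumn({name: frozenset({1 if i < k else 0})
                             for i, name in enumerate(names)})
        assert tree_length(t, c) == min(k, n - k)
        assert brute_force_mpr(t, c).tree_length == min(k, n - k)

    def test_missing_character_entry_names_leaf(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(TreeError, match="'C'"):
            tree_length(t, CharacterColumn({"A": frozenset({0}),
                                            "B": frozenset({1})}))

    def test_brute_force_size_guard(self):
        rng = np.random.default_rng(0)
        t = random_tree(rng, n_min=30, n_max=30, polytomies=False)
        with pytest.raises(TreeError, match="refused"):
            brute_force_mpr(t, random_column(rng, t))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(200))
    def test_matches_brute_force(self, seed):
        tree, column = random_instance(seed)
        fast = mpr_sets(tree, column)
        slow = brute_force_mpr(tree, column)
        assert fast.tree_length == slow.tree_length
        for node in tree.nodes():
            assert fast.states_at(node) == slow.states_at(node), \
                f"node {sorted(tree.leafset(node))}"


class TestInvariants:
    @pytest.mark.parametrize("seed", range(30))
    def test_rerooting_invariance(self, seed):
        tree, column = random_instance(seed, n_max=8)
        baseline = tree_length(tree, column)
        for rerooted in rootings(tree):
            assert tree_length(rerooted, column) == baseline

    @pytest.mark.parametrize("seed", range(40))
    def test_missing_leaf_neutrality(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n_min=3)
        column = random_column(rng, tree, p_missing=0.5)
        missing = [n for n in tree.leaf_names if column[n] == FULL_SET]
        if not missing or len(tree) < 3:
            pytest.skip("instance has no removable missing leaf")
        target = missing[0]
        pruned = tree.prune({target})
        before = mpr_sets(tree, column)
        after = mpr_sets(pruned, column)
        assert before.tree_length == after.tree_length
        for node in pruned.nodes():
            original = tree.mrca(pruned.leafset(node))
            assert after.states_at(node) == before.states_at(original)

    @pytest.mark.parametrize("seed", range(30))
    def test_adding_leaf_never_decreases_length(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n_min=3)
        column = random_column(rng, tree)
        target = tree.leafset(tree.mrca(
            rng.choice(tree.leaf_names,
                       size=int(rng.integers(1, len(tree) + 1)),
                       replace=False)))
        bigger, _ = tree.graft_sister(read_newick("EXTRA;"), target)
        new_states = {**dict(column.states),
                      "EXTRA": frozenset({int(rng.integers(0, 2))})}
        assert tree_length(bigger, CharacterColumn(new_states)) >= \
            tree_length(tree, column)

    @pytest.mark.parametrize("seed", range(30))
    def test_fitch_agreement_on_resolved_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, polytomies=False)
        column = random_column(rng, tree, p_missing=0.0)
        assert fitch_length(tree, column) == tree_length(tree, column)

    @pytest.mark.parametrize("seed", range(10))
    def test_against_dendropy_fitch(self, seed):
        """Independent library cross-check of the tree length."""
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(seed + 1000)
        tree = random_tree(rng, polytomies=False)
        column = random_column(rng, tree, p_missing=0.0)
        nexus = ["#NEXUS", "BEGIN DATA;",
                 f"DIMENSIONS NTAX={len(tree)} NCHAR=1;",
                 'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
                 "MATRIX"]
        for name in tree.leaf_names:
            nexus.append(f"{name} {next(iter(column[name]))}")
        nexus += [";", "END;"]
        taxa = dendropy.TaxonNamespace()
        data = dendropy.StandardCharacterMatrix.get(
            data="\n".join(nexus), schema="nexus", taxon_namespace=taxa)
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                  preserve_underscores=True,
                                  taxon_namespace=taxa)
        taxon_state_sets_map = data.taxon_state_sets_map(gaps_as_missing=True)
        score = fitch_down_pass(dtree.postorder_node_iter(),
                                taxon_state_sets_map=taxon_state_sets_map)
        assert score == tree_length(tree, column)
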