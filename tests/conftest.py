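"""Shared fixtures and random-instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from roguestate.characters import FULL_SET, CharacterColumn
from roguestate.synthetic_data import build_exemplar
from roguestate.topology_space import enumerate_recipes, load_templates
from roguestate.treeio import RootedTree


def random_topology_newick(rng, names, polytomies=True) -> str:
    """Random rooted topology over the given leaf names (recursive splits)."""

    def build(ns):
        if len(ns) == 1:
            return ns[0]
        max_parts = min(4 if polytomies else 2, len(ns))
        k = int(rng.integers(2, max_parts + 1))
        idx = list(rng.permutation(len(ns)))
        cut_positions = sorted(
            rng.choice(np.arange(1, len(ns)), size=k - 1, replace=False))
        groups, prev = [], 0
        for cut in list(cut_positions) + [len(ns)]:
            groups.append([ns[i] for i in idx[prev:cut]])
            prev = cut
        return "(" + ",".join(build(g) for g in groups) + ")"

    return build(list(names)) + ";"


def random_tree(rng, n_min=2, n_max=10, polytomies=True) -> RootedTree:
    n = int(rng.integers(n_min, n_max + 1))
    names = [f"L{i}" for i in range(n)]
    return RootedTree.from_newick(
        random_topology_newick(rng, names, polytomies))


def random_column(rng, tree, p_missing=0.15) -> CharacterColumn:
    """Random binary column with missing/polymorphic cells."""
    states = {}
    for name in tree.leaf_names:
        r = rng.random()
        if r < p_missing:
            states[name] = FULL_SET
        elif r < 0.5 + p_missing / 2:
            states[name] = frozenset({0})
        else:
            states[name] = frozenset({1})
    return CharacterColumn(states)


def random_instance(seed, n_max=10):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_max=n_max)
    return tree, random_column(rng, tree)


@pytest.fixture(scope="session")
def exemplar():
    return build_exemplar()


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def recipes():
    return enumerate_recipes()
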