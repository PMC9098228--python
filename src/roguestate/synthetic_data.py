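"""Synthetic trees and characters, plus the packaged exemplar fixture.

The simulator emulates the statistical shape of the real analysis inputs at
desk scale: a clade-structured binary character on a rooted tree, a tunable
fraction of missing cells, and designated rogue terminals.  Two character
models are provided: a symmetric per-edge flip (Markov) model whose true
ancestral states and change count are returned for recovery/calibration
tests, and a per-clade frequency model for building matrices with controlled
state composition.  Everything is a pure function of ``(config, seed)``.

The exemplar fixture is a 41-taxon scaffold tree over named higher clades
(eudicot, monocot, magnoliid, Chloranthaceae, and ANA-grade exemplars, plus
the four rogue taxa) with a shipped, human-editable carpel-fusion record CSV.
It exists to exercise every pipeline stage without external downloads, not to
reproduce any published tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

import dendropy

from .characters import (ABSENT, FULL_SET, PRESENT, CharacterColumn,
                         CharacterError, FusionRecord, read_matrix)
from .topology_space import REQUIRED_CLADES, clade_leafsets
from .treeio import RootedTree, TreeError

__all__ = [
    "SimulationConfig",
    "SimulatedCharacter",
    "ExemplarFixture",
    "simulate_tree",
    "simulate_character",
    "build_exemplar",
    "load_config_yaml",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated data set.

    ``clade_spec`` is a list of ``(name, size, present_frequency)`` triples;
    sizes must sum to ``n_leaves``.  ``flip_rate`` is the per-edge probability
    of a state change in the Markov character model; ``missing_fraction`` is
    the proportion of leaves masked to the full state set after simulation.
    """

    n_leaves: int
    seed: int
    clade_spec: Tuple[Tuple[str, int, float], ...] = ()
    missing_fraction: float = 0.0
    flip_rate: float = 0.05
    root_state: Optional[int] = None

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")
        if not 0.0 <= self.flip_rate <= 0.5:
            raise ValueError("flip_rate must be in [0, 0.5]")
        if self.clade_spec:
            total = sum(size for _, size, _ in self.clade_spec)
            if total != self.n_leaves:
                raise ValueError(
                    f"clade sizes sum to {total}, expected {self.n_leaves}")
            for name, size, freq in self.clade_spec:
                if size < 1:
                    raise ValueError(f"clade {name}: size must be >= 1")
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"clade {name}: frequency out of range")

    @property
    def effective_clades(self) -> Tuple[Tuple[str, int, float], ...]:
        if self.clade_spec:
            return self.clade_spec
        return (("t", self.n_leaves, 0.5),)


def _random_subtree(names: List[str], rng) -> str:
    """Newick text of a random fully resolved tree via recursive bipartition."""
    if len(names) == 1:
        return names[0]
    k = int(rng.integers(1, len(names)))
    idx = rng.permutation(len(names))
    left = [names[i] for i in sorted(idx[:k])]
    right = [names[i] for i in sorted(idx[k:])]
    return f"({_random_subtree(left, rng)},{_random_subtree(right, rng)})"


def simulate_tree(config: SimulationConfig) -> RootedTree:
    """Random rooted binary tree honouring the clade specification.

    Each named clade is built as a random subtree over its own leaves (so it
    is monophyletic by construction, with its root labelled by the clade
    name), and the clade subtrees are then joined by recursive random splits.
    """
    rng = np.random.default_rng(config.seed)
    pieces = []
    for name, size, _ in config.effective_clades:
        leaves = [f"{name}_{i + 1:02d}" for i in range(size)]
        text = _random_subtree(leaves, rng)
        if size > 1:
            text += name  # label the clade root
        pieces.append(text)
    if len(pieces) == 1:
        newick = pieces[0]
        if not newick.startswith("("):
            newick = f"({newick})"
    else:
        # join clade subtrees with the same recursive-split scheme,
        # treating each piece as an opaque unit
        order = {f"@{i:04d}": p for i, p in enumerate(pieces)}
        skeleton = _random_subtree(sorted(order), rng)
        newick = skeleton
        for key, piece in order.items():
            newick = newick.replace(key, piece)
    return RootedTree.from_newick(newick + ";")


@dataclass(frozen=True)
class SimulatedCharacter:
    """A simulated binary character with its generating truth."""

    column: CharacterColumn
    true_leaf_states: Mapping[str, int]
    true_node_states: Mapping[FrozenSet[str], int]  # keyed by descendant leafset
    n_changes: int
    root_state: int


def simulate_character(tree: RootedTree,
                       config: SimulationConfig) -> SimulatedCharacter:
    """Evolve a binary character along the tree by symmetric per-edge flips.

    The root state is drawn uniformly unless fixed in the config.  After
    simulation, ``missing_fraction`` of the leaves are masked to the full
    state set.  True states of every node and the realized change count are
    returned so tests can check that parsimony length never exceeds the true
    number of changes and that root-state recovery is calibrated.
    """
    rng = np.random.default_rng(config.seed + 1)  # decoupled from tree stream
    root_state = (int(config.root_state) if config.root_state is not None
                  else int(rng.integers(0, 2)))
    states: Dict[object, int] = {}
    n_changes = 0
    for node in tree.nodes():
        if node.parent_node is None:
            states[node] = root_state
            continue
        s = states[node.parent_node]
        if rng.random() < config.flip_rate:
            s = 1 - s
            n_changes += 1
        states[node] = s

    leaf_states = {lf.taxon.label: states[lf] for lf in tree.leaves()}
    node_states = {tree.leafset(node): states[node] for node in tree.nodes()}

    names = sorted(leaf_states)
    n_missing = int(round(config.missing_fraction * len(names)))
    masked = set(rng.choice(names, size=n_missing, replace=False)) \
        if n_missing else set()
    column = CharacterColumn({
        name: FULL_SET if name in masked else frozenset({leaf_states[name]})
        for name in names
    })
    return SimulatedCharacter(column=column, true_leaf_states=leaf_states,
                              true_node_states=node_states,
                              n_changes=n_changes, root_state=root_state)


def simulate_clade_frequency_column(tree: RootedTree,
                                    config: SimulationConfig
                                    ) -> CharacterColumn:
    """Draw leaf states iid within clades at the configured frequencies."""
    rng = np.random.default_rng(config.seed + 2)
    freqs = {name: freq for name, _, freq in config.effective_clades}
    states = {}
    for name in sorted(lf.taxon.label for lf in tree.leaves()):
        clade = name.rsplit("_", 1)[0]
        p = freqs.get(clade, 0.5)
        states[name] = frozenset({PRESENT if rng.random() < p else ABSENT})
    names = sorted(states)
    n_missing = int(round(config.missing_fraction * len(names)))
    if n_missing:
        for name in rng.choice(names, size=n_missing, replace=False):
            states[name] = FULL_SET
    return CharacterColumn(states)


@dataclass(frozen=True)
class ExemplarFixture:
    """The packaged desk-scale analysis inputs."""

    scaffold: RootedTree
    records: Tuple[FusionRecord, ...]

    @property
    def record_map(self) -> Dict[str, FusionRecord]:
        return {r.taxon: r for r in self.records}


def build_exemplar() -> ExemplarFixture:
    """Load and validate the packaged exemplar tree and record CSV.

    Checks that every clade name used by topology recipes is present, that
    the records cover every leaf, and that the *Ceratophyllum* record is
    unknown so both scorings are exercised.
    """
    base = resources.files("roguestate").joinpath("data")
    scaffold = RootedTree.from_newick(
        base.joinpath("exemplar_tree.nwk").read_text())
    records = tuple(read_matrix(
        base.joinpath("exemplar_records.csv").read_text()))

    clade_leafsets(scaffold, REQUIRED_CLADES)  # raises naming missing clade

    tree_taxa = set(scaffold.leaf_names)
    record_taxa = {r.taxon for r in records}
    uncovered = tree_taxa - record_taxa
    if uncovered:
        raise CharacterError(
            f"exemplar records missing taxa: {sorted(uncovered)}")
    cer = [r for r in records if r.taxon.startswith("Ceratophyllum")]
    if not cer or cer[0].fusion_present_any != "unknown":
        raise CharacterError("exemplar Ceratophyllum record must be unknown")
    return ExemplarFixture(scaffold=scaffold, records=records)


def load_config_yaml(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "clade_spec" in raw:
        raw["clade_spec"] = tuple(tuple(item) for item in raw["clade_spec"])
    return SimulationConfig(**raw)
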