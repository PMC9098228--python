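"""Enumeration and realization of the 96-tree topology space.

The space is the Cartesian product of three backbone hypotheses for the
relationships among the species-rich mesangiosperm clades (eudicots, monocots,
magnoliids — the three possible rooted resolutions, conventionally labelled
JM, 1KP and DE) with all placements of four phylogenetically unstable taxa:

* *Ceratophyllum*: sister to Chloranthaceae, to eudicots, to monocots, or to
  all other mesangiosperms (4 options);
* *Nuphar*: sister to the rest of Nymphaeaceae (Nymphaeoideae) or sister to
  Cabombaceae (2);
* *Euptelea*: sister to all other Ranunculales or sister to Papaveraceae (2);
* the root of Alismatales: Araceae first or Tofieldiaceae first (2).

3 x 4 x 2 x 2 x 2 = 96 distinct recipes.  ``realize`` turns a recipe into a
full tree by combining a backbone template (among-clade structure, shipped as
editable Newick files) with a scaffold tree that supplies the within-clade
resolution, and reports the two focal nodes: the *Ceratophyllum* stem node and
the mesangiosperm crown node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .treeio import CladeRef, RootedTree, TreeError

__all__ = [
    "BACKBONES",
    "CERATOPHYLLUM_PLACEMENTS",
    "NUPHAR_PLACEMENTS",
    "EUPTELEA_PLACEMENTS",
    "ALISMATALES_ROOTS",
    "TopologyRecipe",
    "BackboneTemplate",
    "RogueTaxa",
    "Realization",
    "enumerate_recipes",
    "recipes_to_dataframe",
    "load_templates",
    "clade_leafsets",
    "realize",
    "pairwise_distinct",
]

BACKBONES = ("JM", "1KP", "DE")
CERATOPHYLLUM_PLACEMENTS = (
    "sister_chloranthaceae",
    "sister_eudicots",
    "sister_monocots",
    "sister_all_other_mesangiosperms",
)
NUPHAR_PLACEMENTS = ("sister_nymphaeoideae", "sister_cabombaceae")
EUPTELEA_PLACEMENTS = ("sister_other_ranunculales", "sister_papaveraceae")
ALISMATALES_ROOTS = ("araceae_first", "tofieldiaceae_first")

#: Placeholder leaf names expected in backbone template files.
PLACEHOLDERS = ("CHLORANTHACEAE", "MAGNOLIIDS", "MONOCOTS", "EUDICOTS")

#: Internal-node labels the scaffold must carry.
REQUIRED_CLADES = (
    "Eudicots", "Monocots", "Magnoliids", "Chloranthaceae",
    "Ranunculales", "Papaveraceae",
    "Alismatales", "Araceae", "Tofieldiaceae",
    "Nymphaeales", "Cabombaceae", "Nymphaeoideae",
)


@dataclass(frozen=True)
class TopologyRecipe:
    """One point of the 96-point topology space."""

    backbone: str
    ceratophyllum: str
    nuphar: str
    euptelea: str
    alismatales_root: str

    def __post_init__(self):
        for value, domain, name in (
            (self.backbone, BACKBONES, "backbone"),
            (self.ceratophyllum, CERATOPHYLLUM_PLACEMENTS, "ceratophyllum"),
            (self.nuphar, NUPHAR_PLACEMENTS, "nuphar"),
            (self.euptelea, EUPTELEA_PLACEMENTS, "euptelea"),
            (self.alismatales_root, ALISMATALES_ROOTS, "alismatales_root"),
        ):
            if value not in domain:
                raise ValueError(f"bad {name}: {value!r}")

    def as_tuple(self) -> Tuple[str, str, str, str, str]:
        return (self.backbone, self.ceratophyllum, self.nuphar,
                self.euptelea, self.alismatales_root)


def enumerate_recipes() -> List[TopologyRecipe]:
    """All 96 recipes, backbone-major, then Ceratophyllum, Nuphar, Euptelea,
    Alismatales (the layout order of the published summary table)."""
    return [
        TopologyRecipe(b, c, n, e, a)
        for b in BACKBONES
        for c in CERATOPHYLLUM_PLACEMENTS
        for n in NUPHAR_PLACEMENTS
        for e in EUPTELEA_PLACEMENTS
        for a in ALISMATALES_ROOTS
    ]


def recipes_to_dataframe(recipes: Iterable[TopologyRecipe]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.as_tuple() for r in recipes],
        columns=["backbone", "ceratophyllum", "nuphar", "euptelea",
                 "alismatales_root"],
    )


@dataclass(frozen=True)
class BackboneTemplate:
    """Among-clade structure over the four mesangiosperm placeholders."""

    id: str
    tree: RootedTree

    def __post_init__(self):
        missing = set(PLACEHOLDERS) - set(self.tree.leaf_names)
        if missing:
            raise TreeError(f"template {self.id}: missing placeholders "
                            f"{sorted(missing)}")


def load_templates(directory: Optional[Path] = None
                   ) -> Dict[str, BackboneTemplate]:
    """Load the three backbone templates (packaged defaults if no directory)."""
    templates = {}
    if directory is None:
        base = resources.files("roguestate").joinpath("data", "templates")
        for bid in BACKBONES:
            text = base.joinpath(f"{bid}.nwk").read_text()
            templates[bid] = BackboneTemplate(bid, RootedTree.from_newick(text))
    else:
        for bid in BACKBONES:
            path = Path(directory) / f"{bid}.nwk"
            templates[bid] = BackboneTemplate(bid, RootedTree.from_file(path))
    return templates


@dataclass(frozen=True)
class RogueTaxa:
    """Names under which the four unstable taxa appear in the scaffold."""

    ceratophyllum: str = "Ceratophyllum_demersum"
    nuphar: str = "Nuphar_lutea"
    euptelea: str = "Euptelea_pleiosperma"
    tofieldiaceae: str = "Tofieldiaceae"  # internal-node label (a clade)


def clade_leafsets(scaffold: RootedTree,
                   clades: Sequence[str] = REQUIRED_CLADES
                   ) -> Dict[str, FrozenSet[str]]:
    """Leaf sets of the labelled clades of a pristine scaffold tree."""
    sets = {}
    for name in clades:
        node = scaffold.find_label(name)
        if node is None:
            raise TreeError(f"scaffold lacks required clade label {name!r}")
        sets[name] = scaffold.leafset(node)
    return sets


@dataclass(frozen=True)
class Realization:
    """A realized analysis tree plus its two focal nodes."""

    recipe: TopologyRecipe
    tree: RootedTree
    ceratophyllum_stem: object  # dendropy Node in .tree
    mesangiosperm_crown: object  # dendropy Node in .tree


def _surviving(leafset: FrozenSet[str], tree: RootedTree) -> FrozenSet[str]:
    out = leafset & frozenset(tree.leaf_names)
    if not out:
        raise TreeError("clade has no surviving leaves in the working tree")
    return out


def realize(recipe: TopologyRecipe,
            templates: Mapping[str, BackboneTemplate],
            scaffold: RootedTree,
            rogues: RogueTaxa = RogueTaxa()) -> Realization:
    """Build the full analysis tree for one recipe.

    Deterministic: the same recipe, templates and scaffold always yield an
    isomorphic tree.  The four rogues are first removed from the scaffold, the
    mesangiosperm region is rebuilt per the backbone template, the three
    within-clade rogues are regrafted per the recipe, and *Ceratophyllum* is
    grafted last so its stem node is the freshest node.
    """
    clades = clade_leafsets(scaffold)
    tof_subtree = scaffold.extract_subtree(CladeRef(label=rogues.tofieldiaceae))

    rogue_leaves = {rogues.ceratophyllum, rogues.nuphar, rogues.euptelea}
    missing = rogue_leaves - set(scaffold.leaf_names)
    if missing:
        raise TreeError(f"scaffold lacks rogue taxa {sorted(missing)}")

    work = scaffold
    for name in (rogues.ceratophyllum, rogues.nuphar, rogues.euptelea):
        work = work.prune(CladeRef(leaves=frozenset({name})))
    work = work.prune(CladeRef(leaves=_surviving(clades["Tofieldiaceae"], work)))

    work = _rebuild_mesangiosperms(work, templates[recipe.backbone], clades)

    # --- Nuphar ---------------------------------------------------------
    target = {"sister_nymphaeoideae": "Nymphaeoideae",
              "sister_cabombaceae": "Cabombaceae"}[recipe.nuphar]
    nuphar_tree = RootedTree.from_newick(f"{rogues.nuphar};")
    work, _ = work.graft_sister(
        nuphar_tree, CladeRef(leaves=_surviving(clades[target], work)))

    # --- Euptelea -------------------------------------------------------
    if recipe.euptelea == "sister_papaveraceae":
        eup_target = _surviving(clades["Papaveraceae"], work)
    else:
        eup_target = _surviving(
            clades["Ranunculales"] - frozenset({rogues.euptelea}), work)
    eup_tree = RootedTree.from_newick(f"{rogues.euptelea};")
    work, _ = work.graft_sister(eup_tree, CladeRef(leaves=eup_target))

    # --- Alismatales root ----------------------------------------------
    alism_rest = clades["Alismatales"] - clades["Tofieldiaceae"]
    if recipe.alismatales_root == "araceae_first":
        tof_target = _surviving(alism_rest - clades["Araceae"], work)
    else:
        tof_target = _surviving(alism_rest, work)
    work, _ = work.graft_sister(tof_subtree, CladeRef(leaves=tof_target))

    # --- Ceratophyllum (last, so the stem node is the graft node) -------
    mes_leafset = _surviving(
        clades["Eudicots"] | clades["Monocots"] | clades["Magnoliids"]
        | clades["Chloranthaceae"], work)
    cer_targets = {
        "sister_chloranthaceae": _surviving(clades["Chloranthaceae"], work),
        "sister_eudicots": _surviving(clades["Eudicots"], work),
        "sister_monocots": _surviving(clades["Monocots"], work),
        "sister_all_other_mesangiosperms": mes_leafset,
    }
    cer_tree = RootedTree.from_newick(f"{rogues.ceratophyllum};")
    work, stem = work.graft_sister(
        cer_tree, CladeRef(leaves=cer_targets[recipe.ceratophyllum]))

    crown = work.mrca(mes_leafset | frozenset({rogues.ceratophyllum}))
    return Realization(recipe=recipe, tree=work,
                       ceratophyllum_stem=stem, mesangiosperm_crown=crown)


def _rebuild_mesangiosperms(work: RootedTree,
                            template: BackboneTemplate,
                            clades: Mapping[str, FrozenSet[str]]) -> RootedTree:
    """Replace the mesangiosperm subtree with the template's arrangement."""
    placeholder_to_clade = {
        "CHLORANTHACEAE": "Chloranthaceae",
        "MAGNOLIIDS": "Magnoliids",
        "MONOCOTS": "Monocots",
        "EUDICOTS": "Eudicots",
    }
    # Serialize each clade subtree and splice into the template newick.
    pieces = {}
    for placeholder, clade in placeholder_to_clade.items():
        sub = work.extract_subtree(
            CladeRef(leaves=_surviving(clades[clade], work)))
        pieces[placeholder] = sub.to_newick().rstrip().rstrip(";")
    template_text = template.tree.to_newick().rstrip().rstrip(";")
    for placeholder, text in pieces.items():
        template_text = template_text.replace(placeholder, text)
    mes_tree = RootedTree.from_newick(template_text + ";")

    mes_leafset = _surviving(
        clades["Chloranthaceae"] | clades["Magnoliids"]
        | clades["Monocots"] | clades["Eudicots"], work)
    without = work.prune(CladeRef(leaves=mes_leafset))
    # The pruned tree lost the whole mesangiosperm clade; graft the rebuilt
    # version back where its sister group still sits.
    old_mes_node = work.resolve(CladeRef(leaves=mes_leafset))
    parent = old_mes_node.parent_node
    if parent is None:
        raise TreeError("mesangiosperms cannot be the whole scaffold")
    sibling_leaves = work.leafset(parent) - mes_leafset
    attach = _surviving(sibling_leaves, without)
    rebuilt, _ = without.graft_sister(mes_tree, CladeRef(leaves=attach))
    return rebuilt


def pairwise_distinct(trees: Sequence[RootedTree]) -> Tuple[bool, List[Tuple[int, int]]]:
    """True iff no two trees are isomorphic as rooted trees.

    All trees must share one leaf set; duplicate pairs are reported by index.
    """
    if not trees:
        return True, []
    leafsets = [frozenset(t.leaf_names) for t in trees]
    if len(set(leafsets)) > 1:
        raise TreeError("trees have differing leaf sets")
    sigs = [t.canonical_signature() for t in trees]
    dupes = []
    seen: Dict[object, int] = {}
    for i, s in enumerate(sigs):
        if s in seen:
            dupes.append((seen[s], i))
        else:
            seen[s] = i
    return not dupes, dupes
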