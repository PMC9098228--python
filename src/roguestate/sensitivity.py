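"""Two-strategy ancestral-state sensitivity sweep and its renderings.

Strategy 1 asks whether phylogenetic context disambiguates the rogue taxon
itself: *Ceratophyllum* is scored unknown, and the state reconstructed at its
stem node (the node from which it diverges) is recorded for every topology
and both character codings.

Strategy 2 asks how the reconstruction at the mesangiosperm crown node reacts
to the interpretation of *Ceratophyllum*: the sweep is run twice, once with
the taxon scored unknown and once scored as fused (the pseudomonomery
interpretation), again under both codings.

Calls are ``P`` (fusion present), ``A`` (absent) or ``U`` (uncertain — both
states equally parsimonious).  "Scored as unknown" is implemented as a coding
override to the full state set rather than leaf deletion, which preserves the
stem node's identity; by missing-leaf neutrality of unit-cost parsimony the
two are equivalent.

A transcription of the published stem-lineage calls over all 96 topologies
ships with the package (``load_published_stem_calls``) so summary tallies can
be recomputed and compared without the original 792-species matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .characters import (FULL_SET, PRESENT, CharacterColumn, CodingScheme,
                         FusionRecord, apply_coding)
from .parsimony import mpr_sets
from .topology_space import (ALISMATALES_ROOTS, BACKBONES,
                             CERATOPHYLLUM_PLACEMENTS, EUPTELEA_PLACEMENTS,
                             NUPHAR_PLACEMENTS, BackboneTemplate, Realization,
                             RogueTaxa, TopologyRecipe, enumerate_recipes,
                             realize)
from .treeio import RootedTree

__all__ = [
    "CODINGS",
    "FocalCall",
    "SensitivityGrid",
    "call_from_states",
    "run_strategy1",
    "run_strategy2",
    "render_table1",
    "recount_sensitive_from_rendered",
    "fig13_tallies",
    "plot_fig13",
    "load_published_stem_calls",
    "run_provenance",
]

CODINGS = ("any_fusion", "congenital_only")
SCORINGS = ("unknown", "fused")

_SCORING_SETS = {"unknown": FULL_SET, "fused": frozenset({PRESENT})}


def call_from_states(states) -> str:
    """Map an MPR state set to a P/A/U call."""
    states = frozenset(states)
    if states == frozenset({PRESENT}):
        return "P"
    if states == FULL_SET:
        return "U"
    if len(states) == 1:
        return "A"
    raise ValueError(f"invalid state set {states!r}")


@dataclass(frozen=True)
class FocalCall:
    recipe: TopologyRecipe
    focal: str  # ceratophyllum_stem | mesangiosperm_crown
    coding: str
    ceratophyllum_scoring: str  # unknown | fused
    call: str  # P | A | U


@dataclass
class SensitivityGrid:
    """Complete recipe x coding call map for one focal node and scoring."""

    focal: str
    ceratophyllum_scoring: str
    calls: Dict[Tuple[TopologyRecipe, str], str] = field(default_factory=dict)

    def call(self, recipe: TopologyRecipe, coding: str) -> str:
        return self.calls[(recipe, coding)]

    @property
    def recipes(self) -> List[TopologyRecipe]:
        seen = []
        for (recipe, coding) in self.calls:
            if coding == CODINGS[0]:
                seen.append(recipe)
        return seen

    def validate_complete(self, recipes: Optional[Sequence[TopologyRecipe]] = None):
        recipes = list(recipes) if recipes is not None else enumerate_recipes()
        missing = [(r, c) for r in recipes for c in CODINGS
                   if (r, c) not in self.calls]
        if missing:
            raise ValueError(f"grid incomplete: {len(missing)} missing calls, "
                             f"first {missing[0]}")

    # ------------------------------------------------------------- tallies

    def tally(self, coding: str) -> Dict[str, int]:
        out = {"P": 0, "A": 0, "U": 0}
        for (recipe, c), call in self.calls.items():
            if c == coding:
                out[call] += 1
        return out

    def sensitive_recipes(self) -> List[TopologyRecipe]:
        """Recipes whose call differs between the two codings."""
        return [r for r in self.recipes
                if self.call(r, "any_fusion") != self.call(r, "congenital_only")]

    def paired_tally(self) -> Dict[str, int]:
        """Recipe-level counts over coding pairs.

        ``p_both``/``a_both``/``u_both`` count recipes with that call under
        both codings; ``sensitive`` counts recipes whose calls differ.
        """
        out = {"p_both": 0, "a_both": 0, "u_both": 0, "sensitive": 0,
               "total": 0}
        for recipe in self.recipes:
            x = self.call(recipe, "any_fusion")
            y = self.call(recipe, "congenital_only")
            out["total"] += 1
            if x != y:
                out["sensitive"] += 1
            else:
                out[{"P": "p_both", "A": "a_both", "U": "u_both"}[x]] += 1
        return out

    # --------------------------------------------------------------- I/O

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for recipe in self.recipes:
            rows.append(recipe.as_tuple()
                        + (self.call(recipe, "any_fusion"),
                           self.call(recipe, "congenital_only")))
        return pd.DataFrame(rows, columns=[
            "backbone", "ceratophyllum", "nuphar", "euptelea",
            "alismatales_root", "any_fusion", "congenital_only"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, focal: str,
                       ceratophyllum_scoring: str) -> "SensitivityGrid":
        grid = cls(focal=focal, ceratophyllum_scoring=ceratophyllum_scoring)
        for row in df.itertuples(index=False):
            recipe = TopologyRecipe(row.backbone, row.ceratophyllum,
                                    row.nuphar, row.euptelea,
                                    row.alismatales_root)
            grid.calls[(recipe, "any_fusion")] = row.any_fusion
            grid.calls[(recipe, "congenital_only")] = row.congenital_only
        return grid

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, focal: str = "ceratophyllum_stem",
                 ceratophyllum_scoring: str = "unknown") -> "SensitivityGrid":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), focal,
                                  ceratophyllum_scoring)


# ------------------------------------------------------------------ sweeps

def _focal_node(res: Realization, focal: str):
    return {"ceratophyllum_stem": res.ceratophyllum_stem,
            "mesangiosperm_crown": res.mesangiosperm_crown}[focal]


def _sweep(records: Sequence[FusionRecord],
           templates: Mapping[str, BackboneTemplate],
           scaffold: RootedTree,
           focal: str,
           scoring: str,
           rogues: RogueTaxa,
           recipes: Sequence[TopologyRecipe]) -> SensitivityGrid:
    columns = {
        coding: apply_coding(records, CodingScheme(
            mode=coding,
            overrides={rogues.ceratophyllum: _SCORING_SETS[scoring]}))
        for coding in CODINGS
    }
    grid = SensitivityGrid(focal=focal, ceratophyllum_scoring=scoring)
    for recipe in recipes:
        res = realize(recipe, templates, scaffold, rogues)
        node = _focal_node(res, focal)
        for coding, col in columns.items():
            result = mpr_sets(res.tree, col)
            grid.calls[(recipe, coding)] = call_from_states(
                result.states_at(node))
    return grid


def run_strategy1(records: Sequence[FusionRecord],
                  templates: Mapping[str, BackboneTemplate],
                  scaffold: RootedTree,
                  rogues: RogueTaxa = RogueTaxa(),
                  recipes: Optional[Sequence[TopologyRecipe]] = None
                  ) -> SensitivityGrid:
    """Stem-node reconstruction with *Ceratophyllum* scored unknown.

    One call per recipe per coding: the MPR state set at the node from which
    *Ceratophyllum* diverges, collapsed to P/A/U.
    """
    recipes = list(recipes) if recipes is not None else enumerate_recipes()
    return _sweep(records, templates, scaffold, "ceratophyllum_stem",
                  "unknown", rogues, recipes)


def run_strategy2(records: Sequence[FusionRecord],
                  templates: Mapping[str, BackboneTemplate],
                  scaffold: RootedTree,
                  rogues: RogueTaxa = RogueTaxa(),
                  recipes: Optional[Sequence[TopologyRecipe]] = None
                  ) -> Dict[str, SensitivityGrid]:
    """Mesangiosperm-crown reconstruction under both *Ceratophyllum* scorings.

    Returns one grid per scoring (``unknown`` and ``fused``).
    """
    recipes = list(recipes) if recipes is not None else enumerate_recipes()
    return {scoring: _sweep(records, templates, scaffold,
                            "mesangiosperm_crown", scoring, rogues, recipes)
            for scoring in SCORINGS}


# --------------------------------------------------------------- rendering

_ROW_LABELS = {
    "sister_chloranthaceae": "Ceratophyllum sister to Chloranthaceae",
    "sister_eudicots": "Ceratophyllum sister to eudicots",
    "sister_monocots": "Ceratophyllum sister to monocots",
    "sister_all_other_mesangiosperms":
        "Ceratophyllum sister to other mesangiosperms",
}
_NUPHAR_LABELS = {
    "sister_nymphaeoideae": "Nuphar + Nymphaeoideae",
    "sister_cabombaceae": "Nuphar + Cabombaceae",
}
_COL_LABELS = {
    ("sister_other_ranunculales", "araceae_first"):
        "Euptelea basal / Araceae basal",
    ("sister_other_ranunculales", "tofieldiaceae_first"):
        "Euptelea basal / Tofieldiaceae basal",
    ("sister_papaveraceae", "araceae_first"):
        "Euptelea + Papaveraceae / Araceae basal",
    ("sister_papaveraceae", "tofieldiaceae_first"):
        "Euptelea + Papaveraceae / Tofieldiaceae basal",
}


def render_table1(grid: SensitivityGrid) -> str:
    """Markdown rendering in the published summary-table layout.

    Rows: Ceratophyllum placement x Nuphar placement x backbone (three lines
    per visual cell); column blocks: Euptelea x Alismatales.  Each cell shows
    ``any-fusion/congenital-only``; coding-sensitive cells are bolded.
    """
    grid.validate_complete()
    cols = [("sister_other_ranunculales", "araceae_first"),
            ("sister_other_ranunculales", "tofieldiaceae_first"),
            ("sister_papaveraceae", "araceae_first"),
            ("sister_papaveraceae", "tofieldiaceae_first")]
    lines = []
    header = ["Placement", "Nymphaeales", "Backbone"] + [
        _COL_LABELS[c] for c in cols]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for cer in CERATOPHYLLUM_PLACEMENTS:
        for nup in NUPHAR_PLACEMENTS:
            for backbone in BACKBONES:
                cells = []
                for eup, ali in cols:
                    recipe = TopologyRecipe(backbone, cer, nup, eup, ali)
                    x = grid.call(recipe, "any_fusion")
                    y = grid.call(recipe, "congenital_only")
                    cell = f"{x}/{y}"
                    if x != y:
                        cell = f"**{cell}**"
                    cells.append(cell)
                lines.append("| " + " | ".join(
                    [_ROW_LABELS[cer], _NUPHAR_LABELS[nup], backbone] + cells)
                    + " |")
    return "\n".join(lines) + "\n"


def recount_sensitive_from_rendered(rendered: str) -> int:
    """Count coding-sensitive entries in a rendered table (one per recipe)."""
    return rendered.count("**") // 2


def fig13_tallies(grids: Mapping[str, SensitivityGrid]) -> pd.DataFrame:
    """Per-backbone P/A/U tallies over the 32 trees of each backbone.

    One row per (backbone, coding, scoring): the inputs of the published pie
    charts.  Twelve rows for two grids; counts sum to 32 within a row.
    """
    rows = []
    for scoring, grid in grids.items():
        grid.validate_complete()
        for backbone in BACKBONES:
            for coding in CODINGS:
                counts = {"P": 0, "A": 0, "U": 0}
                for (recipe, c), call in grid.calls.items():
                    if c == coding and recipe.backbone == backbone:
                        counts[call] += 1
                rows.append({
                    "backbone": backbone,
                    "coding": coding,
                    "ceratophyllum_scoring": scoring,
                    "n_fused": counts["P"],
                    "n_free": counts["A"],
                    "n_equivocal": counts["U"],
                })
    return pd.DataFrame(rows)


def plot_fig13(tallies: pd.DataFrame, path) -> None:
    """Optional pie-chart rendering of the per-backbone tallies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scorings = sorted(tallies["ceratophyllum_scoring"].unique())
    ncols = len(CODINGS) * len(scorings)
    fig, axes = plt.subplots(len(BACKBONES), ncols,
                             figsize=(3 * ncols, 3 * len(BACKBONES)))
    axes = axes.reshape(len(BACKBONES), ncols)
    for i, backbone in enumerate(BACKBONES):
        j = 0
        for scoring in scorings:
            for coding in CODINGS:
                row = tallies[(tallies.backbone == backbone)
                              & (tallies.coding == coding)
                              & (tallies.ceratophyllum_scoring == scoring)]
                vals = [int(row.n_fused.iloc[0]), int(row.n_free.iloc[0]),
                        int(row.n_equivocal.iloc[0])]
                ax = axes[i, j]
                ax.pie([v for v in vals if v > 0],
                       labels=[l for v, l in zip(vals, ["fused", "free",
                                                        "equivocal"]) if v > 0],
                       colors=[c for v, c in zip(vals, ["#c44", "#4a4",
                                                        "#bbb"]) if v > 0])
                ax.set_title(f"{backbone} / {coding}\nCeratophyllum {scoring}",
                             fontsize=8)
                j += 1
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ------------------------------------------------------- published results

def load_published_stem_calls() -> SensitivityGrid:
    """The published stem-lineage calls across all 96 topologies.

    Transcribed from the printed summary table of the original study (call
    pairs per recipe under both codings); used to recompute its tallies with
    this package's grid machinery.
    """
    path = resources.files("roguestate").joinpath("data",
                                                  "published_stem_calls.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    grid = SensitivityGrid.from_dataframe(df, "ceratophyllum_stem", "unknown")
    grid.validate_complete()
    return grid


def run_provenance(records: Sequence[FusionRecord],
                   templates: Mapping[str, BackboneTemplate],
                   scaffold: RootedTree) -> Dict[str, object]:
    """Hashes of every input plus the recipe list, for run logging."""
    from .characters import write_records_csv

    def sha(text: str) -> str:
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    return {
        "matrix_sha256_16": sha(write_records_csv(records)),
        "scaffold_sha256_16": sha(scaffold.to_newick()),
        "template_sha256_16": {bid: sha(t.tree.to_newick())
                               for bid, t in templates.items()},
        "n_recipes": len(enumerate_recipes()),
        "codings": list(CODINGS),
    }
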