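# roguestate

Parsimony ancestral-state reconstruction under rogue-taxon topology
uncertainty, applied to the evolution of carpel fusion (syncarpy) in
flowering plants.

## The scientific problem

Whether the ancestral flower of the mesangiosperms (the clade holding nearly
all living angiosperms) had fused or free carpels hinges on a handful of
phylogenetically unstable ("rogue") lineages — above all *Ceratophyllum*,
whose single-carpel gynoecium makes the character unobservable in the one
taxon whose position matters most. Rather than committing to one tree, this
package reconstructs the character over an explicit *topology space*: three
published mesangiosperm backbone resolutions crossed with every plausible
placement of four rogue groups, giving 3 × 32 = 96 rooted trees. On each
tree, unit-cost (Fitch/Sankoff) parsimony yields the set of states at a focal
node that occur in at least one most-parsimonious reconstruction (the MPR
set), collapsed to a call: **P** (fused in all MPRs), **A** (free in all
MPRs), or **U** (equivocal). Running the 96 trees under two character
codings — *any fusion* counts both congenital and postgenital fusion as
present; *congenital only* counts postgenital fusion as absent — exposes
which conclusions are robust and which are artifacts of a single tree or
coding choice.

## The core algorithm

`parsimony.mpr_sets` runs a two-pass dynamic program on a rooted tree with
polytomies and missing data, using integer arithmetic throughout:

1. **Downpass (Sankoff):** for every node and state, the minimum number of
   changes in the subtree below it, given that state at the node.
2. **Uppass:** for every node and state, the minimum total tree length over
   all labelings that assign that state to the node. A state belongs to the
   node's MPR set iff this conditional length equals the global minimum.

The engine is validated against `parsimony.brute_force_mpr`, an exhaustive
oracle that enumerates every internal-node labeling, and against dendropy's
independent Fitch implementation.

## Worked example

```python
from roguestate import (CharacterColumn, FULL_SET, mpr_sets, read_newick)

tree = read_newick("((A,B),C);")
column = CharacterColumn({
    "A": frozenset({0}),   # carpels free
    "B": FULL_SET,         # unknown
    "C": frozenset({1}),   # carpels fused
})
result = mpr_sets(tree, column)
print(result.tree_length)             # 1
print(result.states_at(tree.root))    # frozenset({0, 1})  -> equivocal
```

A full sweep over the 96 topologies on the packaged 41-taxon exemplar
fixture, from the command line:

```console
$ roguestate sweep --strategy 1 --out stem_calls.tsv
{"p_both": 0, "a_both": 0, "u_both": 96, "sensitive": 0, "total": 96}
$ roguestate report --grid stem_calls.tsv --style table1 --out stem_table.md
```

With *Ceratophyllum* scored unknown, the sparse exemplar matrix leaves the
stem call equivocal on every topology under both codings — the expected
behaviour for a fixture whose job is to exercise the pipeline, not to
reproduce the published tallies (those require the original 792-species
matrix, which is not redistributable; see `docs/methods.md`).

## Package layout

- `roguestate.treeio` — rooted trees over dendropy: Newick/NEXUS I/O, MRCA,
  prune/graft surgery, rooted-isomorphism checks
- `roguestate.characters` — carpel-fusion records, matrix I/O, the two
  coding schemes
- `roguestate.parsimony` — the unit-cost MPR engine and its exhaustive oracle
- `roguestate.topology_space` — the 96-recipe enumeration and tree surgery
  realizing each recipe
- `roguestate.sensitivity` — the topology × coding sweeps, call grids,
  tallies, and table rendering
- `roguestate.synthetic_data` — simulators and the packaged exemplar fixture
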