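# Methods

## Model and assumptions

### Character

Carpel fusion is treated as a single binary character: 0 = carpels free
(apocarpous), 1 = carpels fused (syncarpous). Each taxon carries a
`FusionRecord` with two observation fields: whether any fusion is present
(`yes`/`no`/`unknown`/`inapplicable`) and the fusion type
(`congenital`/`postgenital`/`both`/`none`/`unknown`). Internal consistency is
enforced at construction: a definite fusion type implies fusion present, and
`no` forces type `none`.

Two coding schemes map records to state sets:

- **any_fusion** — present iff any fusion (congenital or postgenital) is
  recorded.
- **congenital_only** — postgenital-only fusion is recoded as absent, on the
  argument that only congenital fusion reflects the developmental syncarpy
  of interest.

Unknown and inapplicable records (the latter covering monomerous gynoecia,
where fusion between carpels is undefined) map to the full state set
{0, 1} — standard missing-data treatment under parsimony. Polymorphic matrix
cells are likewise mapped to the full set. A coding scheme may carry
per-taxon overrides (used to force *Ceratophyllum* to a chosen scoring) and
free-text metadata that never affects computation.

### Trees

Trees are rooted, may contain polytomies, and are scored without branch
lengths. All tree I/O is delegated to dendropy (Newick and NEXUS, with
translate tables); this package adds MRCA resolution, prune/graft surgery,
and canonical-signature rooted-isomorphism checks on top.

### Parsimony

Unit-cost (Fitch-equivalent) parsimony on the two-state character, computed
by the Sankoff dynamic program so that polytomies and state-set leaves need
no special casing:

- *Downpass:* `down[v][s]` = minimum changes within the subtree of `v` given
  state `s` at `v`. For a leaf, 0 if `s` is in the leaf's state set, else a
  large integer sentinel.
- *Uppass:* `up[v][s]` = minimum total tree length over labelings with state
  `s` at `v`, computed root-to-tip from each parent's conditional optima.
- The **MPR set** of a node is the set of states whose conditional length
  equals the global minimum — exactly the states realized at that node in at
  least one most-parsimonious reconstruction (MPR-union semantics).

A focal-node call collapses the MPR set: {1} → P, {0} → A, {0, 1} → U.

All arithmetic is integer; the infinity sentinel is 10^9, far above any
attainable tree length, so no overflow or float-comparison issues arise.

### Topology space

A `TopologyRecipe` is a 5-tuple: backbone ∈ {JM, 1KP, DE} (the three
published resolutions of the mesangiosperm backbone), *Ceratophyllum*
placement (sister to Chloranthaceae, eudicots, monocots, or all other
mesangiosperms), *Nuphar* placement (sister to Nymphaeoideae or to
Cabombaceae), *Euptelea* placement (sister to Papaveraceae or to the other
Ranunculales), and the Alismatales root order (Araceae-first or
Tofieldiaceae-first). 3 × 4 × 2 × 2 × 2 = 96 recipes; enumeration is
backbone-major and deterministic.

`realize` turns a recipe plus a scaffold tree into a concrete rooted tree by
surgery: prune the four rogue groups, rebuild the mesangiosperm region
according to the backbone template, then regraft *Nuphar*, *Euptelea*, the
Alismatales root order, and finally *Ceratophyllum*. The function returns the
tree together with the two focal nodes: the **Ceratophyllum stem node** (the
node from which *Ceratophyllum* diverges) and the **mesangiosperm crown
node** (the MRCA of mesangiosperms including *Ceratophyllum*). The 96
realized trees are verified pairwise non-isomorphic via canonical signatures.

### Analysis strategies

- **Strategy 1** — reconstruct at the Ceratophyllum stem node, with the
  *Ceratophyllum* terminal scored unknown, under both codings: 96 × 2 calls.
- **Strategy 2** — reconstruct at the mesangiosperm crown node, under both
  codings and both *Ceratophyllum* scorings (unknown and fused):
  96 × 2 × 2 calls.

A recipe is **coding-sensitive** when its call differs between the two
codings. `paired_tally` reports recipes P-under-both, A-under-both,
U-under-both, and sensitive; `render_table1` lays the grid out in the
published summary-table format with sensitive cells bolded, and the bold
count is recountable as an independent consistency check.

## Parameters and numerical choices

| quantity | value | rationale |
|---|---|---|
| states | {0, 1} | binary fusion character |
| step cost | 1 per change, symmetric | unit-cost parsimony |
| infinity sentinel | 10^9 | integer, exceeds any tree length |
| oracle size guard | ≤ 16 internal nodes | 2^16 labelings is the brute-force budget |
| simulation flip rate | ≤ 0.5 | above 0.5 the symmetric model is unidentifiable |
| calibration | n = 64 leaves, flip rate 0.05, 500 replicates, coverage ≥ 95% | artifact-defined thresholds for a conservative-uncertainty check |

All generators are pure functions of (config, seed); seeds are mandatory and
derived seeds stay below 2^31.

## Synthetic-data generator scope

`simulate_tree` draws a rooted binary tree by recursive random bipartition,
honouring a clade specification (each named clade monophyletic with a
labelled root). `simulate_character` evolves the binary character by
independent per-edge flips at a single symmetric rate, returns the true
states of every node and the realized change count, and masks a configured
fraction of leaves. This is deliberately minimal: the analysis is
parsimony-based, so the generator only needs clade-structured binary
variation with missing data, not a calibrated evolutionary model.
`simulate_clade_frequency_column` draws leaf states independently within
clades at configured frequencies, for matrices with controlled composition.

## The exemplar fixture

The packaged fixture (41 taxa, `data/exemplar_tree.nwk` +
`data/exemplar_records.csv`) exists so every pipeline stage runs without
external downloads. It contains every clade name the recipes reference, at
least one taxon of every record class (congenital-only, postgenital-only,
both, none, unknown, inapplicable), and an unknown *Ceratophyllum* record so
both scorings are exercised. Records marked "editable placeholder" in the
CSV are structural stand-ins, not curated observations.

## Design decisions and limitations

- **The original matrix is not packaged.** The published per-topology tallies
  (20 fused-under-both, 8 coding-sensitive, 68 equivocal of 96) were produced
  from a 792-species matrix and scaffold tree that cannot be redistributed
  here. The package instead ships a transcription of the published
  per-topology calls (`data/published_stem_calls.tsv`) and recomputes the
  tallies from it with the same grid machinery used for fresh sweeps. Given
  the original files, `run_strategy1` on them is the intended reproduction
  path.
- Likewise, the published strategy-2 claim that scoring *Ceratophyllum* as
  fused makes all 32 JM-backbone crown calls P can only be checked
  qualitatively at desk scale: on the exemplar, the unknown scoring leaves
  all calls equivocal and the fused scoring forces fused calls, which is the
  mechanism behind the published contrast, not its exact per-backbone
  pattern.
- MPR-union semantics (a state is reported if it occurs in *any* MPR) is a
  deliberate, conservative choice: a U call means the topology genuinely
  admits both states at minimal cost, not that the method failed to decide.
- No Bayesian or likelihood reconstruction, no branch lengths, no automated
  data fetching, and no plotting beyond the optional per-backbone tally pies.
- The backbone templates and the scaffold are plain Newick files under
  `data/`; swapping them swaps the analysis inputs with no code change.
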