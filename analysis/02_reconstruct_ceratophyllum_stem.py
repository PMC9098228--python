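#!/usr/bin/env python
"""Strategy 1: reconstruct carpel fusion at the node from which Ceratophyllum
diverges, across all 96 topologies and both character codings, with the
Ceratophyllum terminal scored unknown.  Writes the call grid and the rendered
summary table."""

import json
from pathlib import Path

from roguestate.sensitivity import render_table1, run_strategy1
from roguestate.synthetic_data import build_exemplar
from roguestate.topology_space import load_templates

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    exemplar = build_exemplar()
    templates = load_templates()

    grid = run_strategy1(exemplar.records, templates, exemplar.scaffold)
    grid.to_tsv(OUT / "stem_calls.tsv")
    (OUT / "stem_table.md").write_text(render_table1(grid))

    tally = grid.paired_tally()
    (OUT / "stem_tally.json").write_text(json.dumps(tally, indent=2) + "\n")
    print(json.dumps(tally, indent=2))


if __name__ == "__main__":
    main()
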