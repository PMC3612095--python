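#!/usr/bin/env python
"""Scan the genome for canonical quadruplex-forming sites, pool any externally
annotated triplex/Z-DNA intervals, and measure per-element breakpoint
densities.

Writes results/nonb_elements.bed and results/element_densities.json. Planted
sites from the fixture's truth.json are echoed so recovery can be eyeballed.
"""

import json
from pathlib import Path

from mitobreaks import breakpoints as bp
from mitobreaks import nonb
from mitobreaks.genome import load_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"
FIXTURE = ROOT / "fixture"
ELEMENTS_BED = None  # set to a BED path to add annotated triplex/Z-DNA elements


def main() -> None:
    genome = load_fasta(FIXTURE / "genome.fasta")
    deletions = bp.parse_deletions(FIXTURE / "breakpoints.tsv", genome.length)
    positions = list(bp.BreakpointSet.from_deletions(deletions).positions)

    elements = nonb.scan_quadruplex(genome)
    if ELEMENTS_BED:
        elements += nonb.load_elements(ELEMENTS_BED, genome.length)
    nonb.write_bed(elements, ROOT / "nonb_elements.bed", chrom=genome.id)
    table = nonb.element_density_table(elements, positions, genome.length)
    (ROOT / "element_densities.json").write_text(
        json.dumps(table, indent=1, sort_keys=True) + "\n"
    )

    truth = json.loads((FIXTURE / "truth.json").read_text())
    planted = [(p["start"], p["end"]) for p in truth["planted"]]
    print(f"found {len(elements)} non-B elements:")
    for el in elements:
        marker = " (planted)" if any(
            el.start <= e and s <= el.end for s, e in planted
        ) else ""
        print(f"  {el.name}  {el.start}-{el.end}  density "
              f"{table[el.name]:.1f}/0.1kb{marker}")
    print(f"pooled density {table['pooled']:.1f} per 0.1 kb")


if __name__ == "__main__":
    main()
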