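#!/usr/bin/env python
"""Breakpoint spectrum: parse the deletion table, classify deletions by arc,
and measure breakpoint densities globally and per region.

Reads results/fixture/ (run 01_simulate_fixture.py first, or point the
constants at a real genome + table) and writes results/breakpoint_summary.json.
"""

import json
from pathlib import Path

from mitobreaks import breakpoints as bp
from mitobreaks.genome import default_mito_regions, load_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"
FIXTURE = ROOT / "fixture"


def main() -> None:
    genome = load_fasta(FIXTURE / "genome.fasta")
    regions = default_mito_regions(genome.length)
    deletions = bp.parse_deletions(FIXTURE / "breakpoints.tsv", genome.length)
    bset = bp.BreakpointSet.from_deletions(deletions)
    positions = list(bset.positions)
    by_class = {r.region_class: r for r in regions}

    summary = {
        "n_deletions": len(deletions),
        "n_breakpoints": len(bset),
        "n_distinct_breakpoints": bp.distinct_breakpoint_count(bset),
        "classification_fractions": bp.classification_fractions(
            deletions, regions, genome.length
        ),
        "density_per_0.1kb": {
            "global": bp.breakpoint_density(positions, [(1, genome.length)], genome.length),
            "major_arc": bp.breakpoint_density(positions, [by_class["major_arc"]], genome.length),
            "minor_arc": bp.breakpoint_density(positions, [by_class["minor_arc"]], genome.length),
        },
    }
    out = ROOT / "breakpoint_summary.json"
    out.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    d = summary["density_per_0.1kb"]
    print(
        f"{summary['n_deletions']} deletions -> {summary['n_breakpoints']} breakpoints "
        f"({summary['n_distinct_breakpoints']} distinct)\n"
        f"density per 0.1 kb: global {d['global']:.2f}, "
        f"major arc {d['major_arc']:.2f}, minor arc {d['minor_arc']:.2f}\n"
        f"wrote {out}"
    )


if __name__ == "__main__":
    main()
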