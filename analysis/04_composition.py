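#!/usr/bin/env python
"""GC-content and GC-skew in non-overlapping 20 bp windows, and breakpoint
density stratified by both variables.

Writes results/composition_windows.tsv and results/composition_bins.json.
"""

import json
from pathlib import Path

from mitobreaks import breakpoints as bp
from mitobreaks import composition as comp
from mitobreaks.genome import load_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"
FIXTURE = ROOT / "fixture"


def main() -> None:
    genome = load_fasta(FIXTURE / "genome.fasta")
    deletions = bp.parse_deletions(FIXTURE / "breakpoints.tsv", genome.length)
    positions = list(bp.BreakpointSet.from_deletions(deletions).positions)

    windows = comp.window_profile(genome, 20)
    with open(ROOT / "composition_windows.tsv", "w") as fh:
        fh.write("start\tend\tgc_content\tgc_skew\n")
        for w in windows:
            fh.write(f"{w.start}\t{w.end}\t{w.gc_content:.6g}\t{w.gc_skew:.6g}\n")

    bins = {
        "gc_skew": comp.density_by_bin(
            positions, windows, "gc_skew", comp.DEFAULT_SKEW_EDGES, genome.length
        ),
        "gc_content": comp.density_by_bin(
            positions, windows, "gc_content", comp.DEFAULT_GC_EDGES, genome.length
        ),
    }
    (ROOT / "composition_bins.json").write_text(
        json.dumps(bins, indent=1, sort_keys=True) + "\n"
    )
    print(
        f"mean GC-content {comp.mean_gc_content(windows) * 100:.1f}% | "
        f"mean GC-skew {comp.mean_gc_skew(windows):.2f}\n"
        f"{bins['gc_skew']['fraction_below_mean'] * 100:.0f}% of breakpoints sit in "
        f"windows with below-average GC-skew"
    )


if __name__ == "__main__":
    main()
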