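#!/usr/bin/env python
"""Randomization enrichment tests under both null models.

For the pooled planted-element breakpoint density and the motif-proximity
fraction, compares the observed statistic against 200 randomized breakpoint
datasets: fully random (uniform on the circle) and partially random
(preserving the observed per-region abundances). Writes
results/enrichment.json.
"""

import json
from pathlib import Path

import numpy as np

from mitobreaks import breakpoints as bp
from mitobreaks import motifs as mot
from mitobreaks import randomization as rnd
from mitobreaks.genome import default_mito_regions, load_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"
FIXTURE = ROOT / "fixture"
SEED = 1
N_DATASETS = 200


def main() -> None:
    genome = load_fasta(FIXTURE / "genome.fasta")
    regions = default_mito_regions(genome.length)
    deletions = bp.parse_deletions(FIXTURE / "breakpoints.tsv", genome.length)
    positions = list(bp.BreakpointSet.from_deletions(deletions).positions)
    truth = json.loads((FIXTURE / "truth.json").read_text())
    spans = [(p["start"], p["end"]) for p in truth["planted"]]

    matches = mot.scan_motif(genome, mot.MOTIF_REGISTRY["YMMYMNNMMHM"])
    arr = mot.nearest_distance_array(matches)
    statistics = {
        "planted_element_density": lambda pos: bp.breakpoint_density(
            pos, spans, genome.length
        ),
        "fraction_within_5bp_of_motif": lambda pos: mot.distance_percentages(
            pos, matches, (5,), (False,), distances=arr
        )[5],
    }

    rng = np.random.default_rng(SEED)
    region_counts = rnd.observed_region_counts(positions, regions)
    results = {}
    for name, stat in statistics.items():
        results[name] = {}
        for model in ("random", "partially_random"):
            spec = rnd.NullModelSpec(
                model=model,
                n_positions=len(positions),
                n_datasets=N_DATASETS,
                region_counts=region_counts if model == "partially_random" else None,
            )
            res = rnd.enrichment_test(
                stat, positions, spec, genome.length, regions=regions, name=name, rng=rng
            )
            results[name][model] = res.to_dict()
            print(
                f"{name} [{model}]: observed {res.observed:.3g}, "
                f"null {res.null_mean:.3g} +/- {res.null_sd:.3g}, "
                f"z {res.z:.2f} {res.stars}"
            )

    (ROOT / "enrichment.json").write_text(json.dumps(results, indent=1, sort_keys=True) + "\n")
    print(f"wrote {ROOT / 'enrichment.json'}")


if __name__ == "__main__":
    main()
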