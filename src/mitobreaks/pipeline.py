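"""Orchestration of the full breakpoint-instability analysis.

``run_all`` executes every stage on a genome + deletion table (+ optional
annotated non-B elements): breakpoint parsing and region densities,
quadruplex scanning, composition windows, curvature/bendability peaks, motif
scanning with shuffle backgrounds, and randomization enrichment tests under
both null models. The consolidated report is a plain dict (JSON-serializable,
deterministic for a fixed seed); per-stage tables are written as TSV/BED next
to it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import breakpoints as bp
from . import composition as comp
from . import curvature as curv
from . import motifs as mot
from . import nonb
from . import randomization as rnd
from .genome import CircularGenome, default_mito_regions, load_fasta, load_regions_tsv, validate_partition

log = logging.getLogger("mitobreaks")


@dataclass
class RunConfig:
    genome_path: str
    breakpoint_table: str
    elements_bed: str | None = None
    regions_tsv: str | None = None
    composition_window: int = 20
    curvature_window: int = 31
    bendability_window: int = 3
    peak_min_separation: int = 100
    peak_halfwidth: int = 50
    peak_min_ratio: float = 1.0
    skew_edges: list = field(default_factory=lambda: list(comp.DEFAULT_SKEW_EDGES))
    gc_edges: list = field(default_factory=lambda: list(comp.DEFAULT_GC_EDGES))
    motif: str = mot.MOTIF_REGISTRY["YMMYMNNMMHM"]
    distance_thresholds: tuple = (5, 20)
    n_datasets: int = rnd.DEFAULT_N_DATASETS
    n_shuffles: int = mot.DEFAULT_N_SHUFFLES
    seed: int = 0
    out_dir: str | None = None


def _both_models(statistic, observed, spec_kwargs, genome_length, regions, name, rng):
    results = {}
    for model in ("random", "partially_random"):
        spec = rnd.NullModelSpec(
            model=model,
            region_counts=spec_kwargs["region_counts"] if model == "partially_random" else None,
            n_positions=spec_kwargs["n_positions"],
            n_datasets=spec_kwargs["n_datasets"],
        )
        res = rnd.enrichment_test(
            statistic, observed, spec, genome_length, regions=regions, name=name, rng=rng
        )
        results[model] = res.to_dict()
    return results


def run_all(config: RunConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    genome = load_fasta(config.genome_path)
    L = genome.length
    log.info("stage=genome id=%s length=%d", genome.id, L)

    if config.regions_tsv:
        regions = load_regions_tsv(config.regions_tsv)
    else:
        regions = default_mito_regions(L)
    validate_partition(regions, L)

    deletions = bp.parse_deletions(config.breakpoint_table, L)
    bset = bp.BreakpointSet.from_deletions(deletions)
    positions = list(bset.positions)
    fractions = bp.classification_fractions(deletions, regions, L)
    by_class = {r.region_class: r for r in regions}
    densities = {
        "global": bp.breakpoint_density(positions, [(1, L)], L),
        "major_arc": bp.breakpoint_density(positions, [by_class["major_arc"]], L),
        "minor_arc": bp.breakpoint_density(positions, [by_class["minor_arc"]], L),
    }
    log.info("stage=breakpoints n_deletions=%d n_breakpoints=%d", len(deletions), len(positions))

    quads = nonb.scan_quadruplex(genome)
    elements = list(quads)
    if config.elements_bed:
        elements += nonb.load_elements(config.elements_bed, L)
    element_densities = nonb.element_density_table(elements, positions, L)

    windows = comp.window_profile(genome, config.composition_window)
    skew_bins = comp.density_by_bin(positions, windows, "gc_skew", config.skew_edges, L)
    gc_bins = comp.density_by_bin(positions, windows, "gc_content", config.gc_edges, L)

    profile = curv.compute_profile(
        genome, config.curvature_window, config.bendability_window
    )
    peaks_all = curv.local_maxima(profile.ratio, config.peak_min_separation)
    peaks = [p for p in peaks_all if profile.ratio[p - 1] > config.peak_min_ratio]
    peak_densities = curv.peak_bin_density(positions, peaks, L, config.peak_halfwidth)

    matches = mot.scan_motif(genome, config.motif)
    dist_arr = mot.nearest_distance_array(matches) if matches.count else None
    dist_pct = (
        mot.distance_percentages(
            positions, matches, config.distance_thresholds, distances=dist_arr
        )
        if matches.count
        else {}
    )
    backgrounds = {
        f"k{k}": mot.motif_background(
            genome, config.motif, config.n_shuffles, k=k, seed=rng
        ).to_dict()
        for k in (1, 3)
    }
    rho, rho_p = mot.binned_profile_correlation(positions, matches, bin_size=500)

    spec_kwargs = {
        "n_positions": len(positions),
        "n_datasets": config.n_datasets,
        "region_counts": rnd.observed_region_counts(positions, regions),
    }
    enrichment = {}
    if elements:
        spans = [(el.start, el.end) for el in elements]
        enrichment["pooled_element_density"] = _both_models(
            lambda pos: bp.breakpoint_density(pos, spans, L),
            positions, spec_kwargs, L, regions, "pooled element density", rng,
        )
    if peaks:
        top = peaks[: min(len(peaks), 10)]
        bins = [
            ((p - config.peak_halfwidth - 1) % L + 1, (p + config.peak_halfwidth - 1) % L + 1)
            for p in top
        ]
        enrichment["peak_bin_density"] = _both_models(
            lambda pos: bp.breakpoint_density(pos, bins, L),
            positions, spec_kwargs, L, regions, "curvature peak bin density", rng,
        )
    if matches.count:
        t0 = config.distance_thresholds[0]
        enrichment["motif_proximity"] = _both_models(
            lambda pos: mot.distance_percentages(
                pos, matches, (t0,), (False,), distances=dist_arr
            )[t0],
            positions, spec_kwargs, L, regions, f"fraction within <{t0} bp of motif", rng,
        )

    report = {
        # out_dir is where the report lands, not part of what it states; keeping
        # it out makes reports from identical inputs byte-identical.
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "out_dir"
        },
        "genome": {"id": genome.id, "length": L},
        "breakpoints": {
            "n_deletions": len(deletions),
            "n_breakpoints": len(positions),
            "n_distinct": bp.distinct_breakpoint_count(bset),
            "classification_fractions": fractions,
            "densities_per_0.1kb": densities,
        },
        "quadruplexes": [
            {"name": q.name, "start": q.start, "end": q.end, "class": q.element_class,
             "sequence": q.sequence}
            for q in quads
        ],
        "element_densities_per_0.1kb": element_densities,
        "composition": {
            "mean_gc_content": comp.mean_gc_content(windows),
            "mean_gc_skew": comp.mean_gc_skew(windows),
            "gc_skew_bins": skew_bins,
            "gc_content_bins": gc_bins,
        },
        "curvature": {
            "genome_mean_ratio": curv.genome_mean_ratio(profile.ratio),
            "peaks": peaks,
            "peak_bin_densities_per_0.1kb": {str(k): v for k, v in peak_densities.items()},
        },
        "motif": {
            "pattern": config.motif,
            "n_occurrences": matches.count,
            "distance_percentages": {str(k): v for k, v in dist_pct.items()},
            "backgrounds": backgrounds,
            "binned_spearman_rho": rho,
            "binned_spearman_p": rho_p,
        },
        "enrichment": enrichment,
        "seed": config.seed,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        nonb.write_bed(quads, out / "quadruplexes.bed", chrom=genome.id)
        with open(out / "composition.tsv", "w") as fh:
            fh.write("start\tend\tgc_content\tgc_skew\n")
            for w in windows:
                fh.write(f"{w.start}\t{w.end}\t{w.gc_content:.6g}\t{w.gc_skew:.6g}\n")
        with open(out / "profile.tsv", "w") as fh:
            fh.write("position\tcurvature\tbendability\tratio\n")
            for i in range(L):
                fh.write(
                    f"{i + 1}\t{profile.curvature[i]:.6g}\t{profile.bendability[i]:.6g}"
                    f"\t{profile.ratio[i]:.6g}\n"
                )
    return report
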