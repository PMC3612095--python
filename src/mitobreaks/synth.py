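"""Synthetic circular genomes with planted features and breakpoints of known structure.

The generator emulates the statistical setting of the breakpoint analysis: a
circular genome whose background base composition is controlled per segment,
literal or IUPAC-sampled elements planted at known coordinates, and breakpoint
positions drawn from a mixture of a uniform background and a feature-proximal
component. A fraction pi of breakpoints is placed uniformly within +/-d bp of
a planted feature; the rest are uniform on the genome. The planted truth is
recorded so every downstream stage (scanning, densities, enrichment,
distances) can be checked against known ground truth.

Defaults mirror the real study scale: a 16,569 bp genome with light-strand
mtDNA base composition (A .309, C .313, G .131, T .247 — GC ~= 44.4%, GC-skew
~= -0.41), 1,508 breakpoints (two per deletion for 754 deletions), pi = 0.5
and d = 10 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import CircularGenome, GenomeError
from .motifs import IUPAC
from .nonb import FeatureInterval

MTDNA_BASE_FREQS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}
DEFAULT_LENGTH = 16_569
DEFAULT_N_BREAKPOINTS = 1_508
DEFAULT_PI = 0.5
DEFAULT_PROXIMITY = 10


@dataclass
class SyntheticTruth:
    genome: CircularGenome
    planted: list[FeatureInterval]
    enrichment_fraction: float = DEFAULT_PI
    proximity: int = DEFAULT_PROXIMITY
    n_breakpoints: int = DEFAULT_N_BREAKPOINTS
    seed: int | None = None
    segment_compositions: list = field(default_factory=list)


def _sample_iupac(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise GenomeError(f"invalid IUPAC code {c!r} in planted sequence")
        choices = IUPAC[c]
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices)
    return "".join(out)


def generate_genome(
    length: int = DEFAULT_LENGTH,
    segment_compositions: Sequence[tuple[tuple[int, int], dict[str, float]]] | None = None,
    plant: Sequence[tuple[int, str]] = (),
    seed: int | None = None,
) -> SyntheticTruth:
    """Background genome with per-segment base frequencies and planted elements.

    ``segment_compositions`` is a list of ((start, end), freqs) with 1-based
    inclusive spans that must tile the genome; the default is a single segment
    with mtDNA light-strand composition. ``plant`` is a list of (position,
    sequence) where the sequence may contain IUPAC codes (sampled once).
    Planted elements may wrap through the origin but must not overlap each
    other.
    """
    if length < 1:
        raise GenomeError("genome length must be positive")
    rng = np.random.default_rng(seed)
    if segment_compositions is None:
        segment_compositions = [((1, length), MTDNA_BASE_FREQS)]
    covered = 0
    expected_start = 1
    for (start, end), freqs in segment_compositions:
        if start != expected_start or end < start or end > length:
            raise GenomeError(f"segments must tile the genome in order; bad span ({start},{end})")
        total = sum(freqs.get(b, 0.0) for b in "ACGT")
        if abs(total - 1.0) > 1e-6:
            raise GenomeError(f"segment ({start},{end}) frequencies sum to {total}, not 1")
        covered += end - start + 1
        expected_start = end + 1
    if covered != length:
        raise GenomeError(f"segments cover {covered} bp, expected {length}")

    bases = np.array(list("ACGT"))
    parts = []
    for (start, end), freqs in segment_compositions:
        probs = np.array([freqs.get(b, 0.0) for b in "ACGT"])
        parts.append(rng.choice(bases, size=end - start + 1, p=probs))
    seq = np.concatenate(parts)

    planted: list[FeatureInterval] = []
    occupied: set[int] = set()
    for idx, (pos, pattern) in enumerate(plant, 1):
        if not 1 <= pos <= length:
            raise GenomeError(f"plant position {pos} outside genome")
        realized = _sample_iupac(pattern, rng)
        if len(realized) > length:
            raise GenomeError("planted sequence longer than the genome")
        offsets = [(pos - 1 + k) % length for k in range(len(realized))]
        if occupied & set(offsets):
            raise GenomeError(f"planted element at {pos} overlaps an earlier plant")
        occupied.update(offsets)
        for off, base in zip(offsets, realized):
            seq[off] = base
        end1 = offsets[-1] + 1
        planted.append(
            FeatureInterval(
                name=f"planted_{idx}",
                start=pos,
                end=end1,
                element_class="motif",
                sequence=realized,
            )
        )

    genome = CircularGenome(id=f"synthetic_{seed}", sequence="".join(seq))
    return SyntheticTruth(
        genome=genome,
        planted=planted,
        seed=seed,
        segment_compositions=list(segment_compositions),
    )


def feature_neighborhood(
    planted: Sequence[FeatureInterval], d: int, genome_length: int
) -> np.ndarray:
    """Sorted unique 1-based positions within +/-d bp of any planted feature."""
    pos: set[int] = set()
    for el in planted:
        size = el.size(genome_length)
        for k in range(-d, size + d):
            pos.add((el.start - 1 + k) % genome_length + 1)
    return np.array(sorted(pos), dtype=int)


def generate_breakpoints(
    truth: SyntheticTruth,
    n: int = DEFAULT_N_BREAKPOINTS,
    pi: float = DEFAULT_PI,
    d: int = DEFAULT_PROXIMITY,
    seed: int | None = None,
) -> np.ndarray:
    """Breakpoints from the uniform + feature-proximal mixture (see module docstring)."""
    if not 0.0 <= pi <= 1.0:
        raise GenomeError("enrichment fraction pi must be in [0, 1]")
    if d < 0:
        raise GenomeError("proximity d must be >= 0")
    if pi > 0 and not truth.planted:
        raise GenomeError("pi > 0 requires at least one planted feature")
    rng = np.random.default_rng(seed)
    L = truth.genome.length
    hood = feature_neighborhood(truth.planted, d, L) if truth.planted else np.array([], int)
    out = np.empty(n, dtype=int)
    enriched = rng.random(n) < pi
    n_enriched = int(enriched.sum())
    if n_enriched:
        out[enriched] = rng.choice(hood, size=n_enriched, replace=True)
    out[~enriched] = rng.integers(1, L + 1, size=n - n_enriched)
    truth.enrichment_fraction = pi
    truth.proximity = d
    truth.n_breakpoints = n
    return out


def expected_proximal_fraction(truth: SyntheticTruth, d: int) -> float:
    """Expected fraction of breakpoints within d bp of a planted feature.

    pi + (1 - pi) * footprint, where footprint is the genome fraction covered
    by the +/-d neighborhoods (uniform-background leakage).
    """
    L = truth.genome.length
    footprint = len(feature_neighborhood(truth.planted, d, L)) / L
    pi = truth.enrichment_fraction
    return pi + (1.0 - pi) * footprint


def recovered_enrichment_fraction(
    truth: SyntheticTruth, breakpoints: Sequence[int], d: int
) -> float:
    """Background-corrected estimate of pi from an observed breakpoint set.

    Inverts the mixture expectation: pi_hat = (f_obs - footprint) /
    (1 - footprint) with f_obs the observed fraction within d bp of a feature.
    """
    L = truth.genome.length
    hood = set(feature_neighborhood(truth.planted, d, L).tolist())
    f_obs = sum(1 for b in breakpoints if b in hood) / len(breakpoints)
    footprint = len(hood) / L
    if footprint >= 1.0:
        raise GenomeError("feature neighborhoods cover the whole genome; pi unidentifiable")
    return (f_obs - footprint) / (1.0 - footprint)


def write_fixture(
    truth: SyntheticTruth, breakpoints: Sequence[int], out_dir: str | Path
) -> dict[str, Path]:
    """Write genome.fasta, breakpoints.tsv and truth.json; round-trips through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fasta"
    seq = truth.genome.sequence
    lines = [f">{truth.genome.id}"] + [seq[i : i + 70] for i in range(0, len(seq), 70)]
    fasta.write_text("\n".join(lines) + "\n")

    tsv = out / "breakpoints.tsv"
    rows = []
    bps = list(breakpoints)
    for i in range(0, len(bps) - 1, 2):
        p5, p3 = int(bps[i]), int(bps[i + 1])
        if p5 == p3:
            p3 = p3 % truth.genome.length + 1  # breakpoints of one deletion must differ
        rows.append(f"del{i // 2 + 1}\t{p5}\t{p3}\tsynthetic")
    tsv.write_text("\n".join(rows) + "\n")

    truth_json = out / "truth.json"
    truth_json.write_text(
        json.dumps(
            {
                "genome_id": truth.genome.id,
                "genome_length": truth.genome.length,
                "seed": truth.seed,
                "enrichment_fraction": truth.enrichment_fraction,
                "proximity": truth.proximity,
                "n_breakpoints": truth.n_breakpoints,
                "planted": [
                    {
                        "name": el.name,
                        "start": el.start,
                        "end": el.end,
                        "class": el.element_class,
                        "sequence": el.sequence,
                    }
                    for el in truth.planted
                ],
                "breakpoints": [int(b) for b in bps],
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    return {"fasta": fasta, "breakpoints": tsv, "truth": truth_json}
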