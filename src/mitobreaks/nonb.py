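"""Canonical G-quadruplex detection and externally annotated non-B elements.

The canonical folding rule is four or more runs of >=3 G (or >=3 C for the
complementary-strand pattern) separated by loops of 1-7 nt. Overlapping
candidate matches at a locus are reported as one maximal site, mirroring the
single-site-per-locus behaviour of run-chaining scanners: maximal G-runs are
linked whenever the gap between consecutive runs is 1-7 nt, and every maximal
chain containing at least four runs becomes one reported interval from the
first run's start to the last run's end.

Triplex and Z-DNA elements are not predicted here; they are accepted as
annotated intervals from a BED file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .breakpoints import breakpoint_density
from .genome import CircularGenome, GenomeError

QUAD_MIN_RUN = 3
QUAD_MIN_RUNS = 4
QUAD_MAX_LOOP = 7


@dataclass(frozen=True)
class FeatureInterval:
    """A located element on the circular genome (1-based inclusive; end < start wraps)."""

    name: str
    start: int
    end: int
    element_class: str
    sequence: str = ""

    def size(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


def _runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` of length >= min_len as 0-based [start, end) pairs."""
    return [
        (m.start(), m.end())
        for m in re.finditer(f"{base}{{{min_len},}}", seq)
    ]


def _chain_runs(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Chain runs whose inter-run gap is 1..QUAD_MAX_LOOP; report chains that
    can supply >= 4 G3 pieces.

    Loops may themselves contain G, so a single maximal run of length l can be
    parsed into floor((l + 1) / 4) pieces (three G per piece, one G spent as a
    loop between consecutive pieces); a run of >= 15 G is a site on its own.
    """
    sites = []
    i = 0
    while i < len(runs):
        j = i
        while (
            j + 1 < len(runs)
            and 1 <= runs[j + 1][0] - runs[j][1] <= QUAD_MAX_LOOP
        ):
            j += 1
        capacity = sum((runs[k][1] - runs[k][0] + 1) // 4 for k in range(i, j + 1))
        if capacity >= QUAD_MIN_RUNS:
            sites.append((runs[i][0], runs[j][1]))
        i = j + 1
    return sites


def scan_quadruplex(genome: CircularGenome, circular: bool = True) -> list[FeatureInterval]:
    """Non-overlapping canonical quadruplex-forming sites on the light strand.

    Both the G-run pattern and the C-run pattern are scanned (together they
    represent quadruplexes on either strand). Sites are returned sorted by
    start position, G-pattern hits named Gn and C-pattern hits named Cn.
    """
    L = genome.length
    # Extend far enough that any wrap-spanning site is seen in full; a site
    # longer than the genome is impossible for non-degenerate inputs.
    seq = genome.sequence + (genome.sequence if circular else "")
    raw: set[tuple[int, int, str]] = set()
    for base, cls in (("G", "quadruplex_G"), ("C", "quadruplex_C")):
        for s, e in _chain_runs(_runs(seq, base, QUAD_MIN_RUN)):
            if s >= L:
                continue
            if not circular and e > L:
                continue
            span = e - s
            if span > L:
                span = L  # fully degenerate circular chain
            raw.add((s, span, cls))
    # Drop duplicate wrap images and linear truncations: a chain seen at the
    # string start may be the tail of a longer chain that wraps through the
    # origin, so any site circularly contained in another is discarded.
    candidates = []
    for s, span, cls in sorted(raw):
        start1 = s + 1
        end1 = (s + span - 1) % L + 1
        covered = frozenset((s + k) % L for k in range(span))
        candidates.append((start1, end1, cls, covered))
    sites = []
    for i, (start1, end1, cls, cov) in enumerate(candidates):
        contained = any(
            j != i and cls == c2 and cov < cov2 or (j < i and cls == c2 and cov == cov2)
            for j, (_, _, c2, cov2) in enumerate(candidates)
        )
        if not contained:
            sites.append((start1, end1, cls))
    out = []
    counters = {"quadruplex_G": 0, "quadruplex_C": 0}
    for start1, end1, cls in sites:
        counters[cls] += 1
        name = ("G" if cls == "quadruplex_G" else "C") + str(counters[cls])
        out.append(
            FeatureInterval(
                name=name,
                start=start1,
                end=end1,
                element_class=cls,
                sequence=genome.subsequence(start1, end1),
            )
        )
    return out


def load_elements(path: str | Path, genome_length: int) -> list[FeatureInterval]:
    """Read annotated elements from a BED file (0-based half-open) into 1-based intervals.

    The BED name column carries the element name; an optional 5th column gives
    the element class (defaults to the name's leading letter convention:
    T=triplex, Z=zdna, G=quadruplex_G, otherwise 'element').
    """
    classes = {"T": "triplex", "Z": "zdna", "G": "quadruplex_G", "C": "quadruplex_C"}
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = re.split(r"\s+", line)
        if len(fields) < 4:
            raise GenomeError(f"{path}:{lineno}: BED line needs chrom, start, end, name")
        try:
            bed_start, bed_end = int(fields[1]), int(fields[2])
        except ValueError:
            raise GenomeError(f"{path}:{lineno}: non-numeric BED coordinates") from None
        if bed_start < 0 or bed_end <= bed_start:
            raise GenomeError(f"{path}:{lineno}: invalid BED interval {bed_start}-{bed_end}")
        if bed_end > genome_length:
            raise GenomeError(
                f"{path}:{lineno}: interval end {bed_end} exceeds genome length {genome_length}"
            )
        name = fields[3]
        cls = fields[4] if len(fields) > 4 else classes.get(name[:1], "element")
        out.append(FeatureInterval(name=name, start=bed_start + 1, end=bed_end, element_class=cls))
    return out


def element_density_table(
    elements: Sequence[FeatureInterval],
    breakpoint_positions: Sequence[int],
    genome_length: int,
) -> dict[str, float]:
    """Observed breakpoint density (per 0.1 kb) for each element and pooled over all."""
    table = {
        el.name: breakpoint_density(breakpoint_positions, [(el.start, el.end)], genome_length)
        for el in elements
    }
    table["pooled"] = pooled_density(elements, breakpoint_positions, genome_length)
    return table


def pooled_density(
    elements: Sequence[FeatureInterval],
    breakpoint_positions: Sequence[int],
    genome_length: int,
) -> float:
    return breakpoint_density(
        breakpoint_positions, [(el.start, el.end) for el in elements], genome_length
    )


def write_bed(elements: Sequence[FeatureInterval], path: str | Path, chrom: str = "chrM") -> None:
    """Write elements as BED (0-based half-open); wrapping intervals are split."""
    lines = []
    for el in elements:
        if el.start <= el.end:
            lines.append(f"{chrom}\t{el.start - 1}\t{el.end}\t{el.name}\t{el.element_class}")
        else:
            lines.append(f"{chrom}\t{el.start - 1}\t.\t{el.name}\t{el.element_class}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
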