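"""Circular genome container, coordinate arithmetic and the mitochondrial region partition.

All coordinates are 1-based inclusive, matching rCRS numbering. A region whose
``end`` is smaller than its ``start`` wraps through the origin, so the major arc
(5,799 -> 109 on the 16,569 bp genome) is a single interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABET = set("ACGTN")
RCRS_LENGTH = 16_569

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeError(ValueError):
    """Raised for malformed genomes, regions or coordinates."""


@dataclass(frozen=True)
class CircularGenome:
    """An uppercase circular nucleotide sequence with 1-based coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError("empty genome sequence")
        for i, c in enumerate(self.sequence):
            if c not in ALPHABET:
                raise GenomeError(
                    f"illegal character {c!r} at position {i + 1} in genome {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        self._check(pos)
        return self.sequence[pos - 1]

    def _check(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise GenomeError(f"position {pos} outside 1..{self.length}")

    def subsequence(self, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive; ``end < start`` wraps through the origin."""
        self._check(start)
        self._check(end)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


@dataclass(frozen=True)
class GenomeRegion:
    """A named region of the circular genome; ``end < start`` encodes a wrap."""

    name: str
    start: int
    end: int
    region_class: str

    def size(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


REGION_CLASSES = ("major_arc", "minor_arc", "OH", "OL")


def load_fasta(path: str | Path) -> CircularGenome:
    """Load a single-record FASTA as a circular genome (sequence uppercased)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper())


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest arc distance between two positions on a circle of ``length`` bp."""
    if not (1 <= a <= length and 1 <= b <= length):
        raise GenomeError(f"positions ({a}, {b}) outside 1..{length}")
    d = abs(a - b)
    return min(d, length - d)


def default_mito_regions(genome_length: int = RCRS_LENGTH) -> list[GenomeRegion]:
    """The four-way partition of the human mitochondrial genome.

    Major arc 5,799 -> 109 (wrapping through the origin), minor arc 442-5,720,
    heavy-strand replication origin OH 110-441, light-strand origin OL
    5,721-5,798. Only the 16,569 bp reference length is supported; other
    genomes need a user-supplied partition.
    """
    if genome_length != RCRS_LENGTH:
        raise GenomeError(
            f"built-in mitochondrial partition requires a {RCRS_LENGTH} bp genome, "
            f"got {genome_length}; supply regions explicitly"
        )
    return [
        GenomeRegion("major_arc", 5_799, 109, "major_arc"),
        GenomeRegion("OH", 110, 441, "OH"),
        GenomeRegion("minor_arc", 442, 5_720, "minor_arc"),
        GenomeRegion("OL", 5_721, 5_798, "OL"),
    ]


def load_regions_tsv(path: str | Path) -> list[GenomeRegion]:
    """Region override file: tab-separated name, start, end, class."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise GenomeError(f"{path}:{lineno}: expected 4 tab-separated fields")
        name, start, end, cls = parts
        regions.append(GenomeRegion(name, int(start), int(end), cls))
    return regions


def validate_partition(regions: Sequence[GenomeRegion], genome_length: int) -> None:
    """Check that the regions tile the circle exactly once."""
    covered = sum(r.size(genome_length) for r in regions)
    if covered != genome_length:
        raise GenomeError(
            f"regions cover {covered} bp, expected {genome_length} (partition must tile the genome)"
        )
    hits = [0] * (genome_length + 1)
    for r in regions:
        if r.start <= r.end:
            span: Iterable[int] = range(r.start, r.end + 1)
        else:
            span = list(range(r.start, genome_length + 1)) + list(range(1, r.end + 1))
        for p in span:
            hits[p] += 1
    bad = [p for p in range(1, genome_length + 1) if hits[p] != 1]
    if bad:
        raise GenomeError(f"position {bad[0]} covered {hits[bad[0]]} times by region set")


def classify_position(pos: int, regions: Sequence[GenomeRegion]) -> str:
    """Region class containing a position."""
    for r in regions:
        if r.contains(pos):
            return r.region_class
    raise GenomeError(f"position {pos} not covered by any region")
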