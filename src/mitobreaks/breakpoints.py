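"""Deletion tables, the interval-collapsing rule, arc classification and breakpoint densities.

Deletion breakpoints are the rCRS positions immediately flanking the removed
segment: one upstream of the 5' break and one downstream of the 3' break.
Literature reports often give an interval of equivalent positions when the
deletion is flanked by a direct repeat (e.g. "7,508-7,515"); the convention
adopted here keeps the smallest value of each interval. Deletion rows whose
(5', 3') pair repeats an earlier row are dropped; rows sharing one breakpoint
but differing in the other are distinct deletions and kept.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome import GenomeRegion, GenomeError

_INTERVAL_SEP = re.compile(r"[–—-]")  # hyphen, en dash, em dash


class DeletionTableError(ValueError):
    pass


@dataclass(frozen=True)
class Deletion:
    id: str
    five_prime: int
    three_prime: int
    source: str = ""


@dataclass(frozen=True)
class BreakpointSet:
    """The multiset of breakpoint positions (two per deletion)."""

    positions: tuple[int, ...]

    @classmethod
    def from_deletions(cls, deletions: Iterable[Deletion]) -> "BreakpointSet":
        pos: list[int] = []
        for d in deletions:
            pos.extend((d.five_prime, d.three_prime))
        return cls(tuple(pos))

    @property
    def distinct_positions(self) -> frozenset[int]:
        return frozenset(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def _parse_position_field(field: str, genome_length: int, row: int) -> int:
    """A field is a single position or a dash/en-dash interval; keep the smallest value.

    Thousands separators (commas) are accepted.
    """
    text = field.strip().replace(",", "").replace(" ", "")
    if not text:
        raise DeletionTableError(f"row {row}: empty breakpoint field")
    parts = [p for p in _INTERVAL_SEP.split(text) if p]
    try:
        values = [int(p) for p in parts]
    except ValueError:
        raise DeletionTableError(f"row {row}: non-numeric breakpoint field {field!r}") from None
    pos = min(values)
    if not 1 <= pos <= genome_length:
        raise DeletionTableError(
            f"row {row}: position {pos} outside genome (1..{genome_length})"
        )
    return pos


def parse_deletions(path: str | Path, genome_length: int) -> list[Deletion]:
    """Read a deletion TSV (id, 5' field, 3' field[, source]) applying the collapsing rule."""
    deletions: list[Deletion] = []
    seen: set[tuple[int, int]] = set()
    lines = Path(path).read_text().splitlines()
    for row, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 3:
            raise DeletionTableError(f"row {row}: expected at least 3 tab-separated fields")
        del_id = fields[0].strip()
        p5 = _parse_position_field(fields[1], genome_length, row)
        p3 = _parse_position_field(fields[2], genome_length, row)
        if p5 == p3:
            raise DeletionTableError(f"row {row}: 5' and 3' breakpoints coincide ({p5})")
        source = fields[3].strip() if len(fields) > 3 else ""
        key = (p5, p3)
        if key in seen:  # both extremities repeated -> excluded
            continue
        seen.add(key)
        deletions.append(Deletion(del_id, p5, p3, source))
    return deletions


def distinct_breakpoint_count(bset: BreakpointSet) -> int:
    return len(bset.distinct_positions)


def _interval_size(start: int, end: int, genome_length: int) -> int:
    if start <= end:
        return end - start + 1
    return genome_length - start + 1 + end


def _interval_contains(start: int, end: int, pos: int) -> bool:
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end


def breakpoint_density(
    positions: Sequence[int],
    intervals: Sequence[tuple[int, int] | GenomeRegion],
    genome_length: int,
) -> float:
    """Pooled breakpoint density in breakpoints per 0.1 kb.

    density = (number of positions falling in any interval) / (sum of interval
    sizes in bp) * 100.  Positions are counted with multiplicity; interval
    membership is inclusive at both edges and wrap-aware.
    """
    spans = [
        (iv.start, iv.end) if isinstance(iv, GenomeRegion) else (int(iv[0]), int(iv[1]))
        for iv in intervals
    ]
    total = sum(_interval_size(s, e, genome_length) for s, e in spans)
    if total == 0:
        raise GenomeError("zero total interval size in density computation")
    count = sum(1 for p in positions for s, e in spans if _interval_contains(s, e, p))
    return count / total * 100.0


MAJOR_ONLY = "major_only"
MINOR_ONLY = "minor_only"
INVOLVES_ORIGINS = "involves_origins"


def _unroll(start: int, end: int, genome_length: int) -> list[tuple[int, int]]:
    """A circular inclusive interval as one or two linear intervals."""
    if start <= end:
        return [(start, end)]
    return [(start, genome_length), (1, end)]


def _circular_overlap(a: tuple[int, int], b: tuple[int, int], genome_length: int) -> bool:
    for s1, e1 in _unroll(*a, genome_length):
        for s2, e2 in _unroll(*b, genome_length):
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def classify_deletion(
    d: Deletion, regions: Sequence[GenomeRegion], genome_length: int
) -> str:
    """Classify a deletion as major-arc-only, minor-arc-only or origin-involving.

    The removed span is the open interval between the breakpoints traversed 5'
    to 3' along the light strand. A deletion is arc-exclusive when the span and
    both flanking breakpoints lie inside that arc; any overlap of the span (or
    a breakpoint) with OH or OL makes it origin-involving.
    """
    if d.five_prime == d.three_prime:
        raise GenomeError(f"deletion {d.id}: zero-length span is ambiguous")

    def region_of(pos: int) -> str:
        for r in regions:
            if r.contains(pos):
                return r.region_class
        raise GenomeError(f"position {pos} not in partition")

    bp_classes = {region_of(d.five_prime), region_of(d.three_prime)}
    if bp_classes & {"OH", "OL"}:
        return INVOLVES_ORIGINS
    # Open interval (5', 3'): empty when the breakpoints are adjacent.
    span_start = d.five_prime % genome_length + 1
    span_end = (d.three_prime - 2) % genome_length + 1
    span_empty = span_start == d.three_prime
    touched = set(bp_classes)
    if not span_empty:
        span = (span_start, span_end)
        for r in regions:
            if _circular_overlap(span, (r.start, r.end), genome_length):
                touched.add(r.region_class)
    if touched & {"OH", "OL"}:
        return INVOLVES_ORIGINS
    if touched == {"major_arc"}:
        return MAJOR_ONLY
    if touched == {"minor_arc"}:
        return MINOR_ONLY
    return INVOLVES_ORIGINS


def classification_fractions(
    deletions: Sequence[Deletion], regions: Sequence[GenomeRegion], genome_length: int
) -> dict[str, float]:
    counts = Counter(classify_deletion(d, regions, genome_length) for d in deletions)
    n = len(deletions)
    return {
        cls: counts.get(cls, 0) / n
        for cls in (MAJOR_ONLY, MINOR_ONLY, INVOLVES_ORIGINS)
    }
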