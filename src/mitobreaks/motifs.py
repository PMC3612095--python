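"""Degenerate motif scanning, breakpoint-motif distances and shuffle-based backgrounds.

The central motif is the degenerate 11-mer YMMYMNNMMHM recovered near deletion
breakpoints (Y = C/T, M = A/C, H = A/C/T, N = any). Scanning is on the light
strand with overlapping occurrences counted and wrap-spanning matches included
on the circular genome. Background occurrence counts are estimated from
sequences shuffled so as to preserve the k-mer multiset exactly (k = 1:
base-composition permutation; k >= 2: Euler-path walk on the de Bruijn
multigraph of (k-1)-mers, the Altschul-Erickson construction).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import CircularGenome, GenomeError, circular_distance
from .randomization import EnrichmentResult, pvalue_from_z, zscore

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Motifs discussed for the human mitochondrial genome: the breakpoint-proximal
# 11-mer, the nuclear recombination hot-spot consensus and its 9-mer core, and
# the minimal mTERF binding consensus CCN8CC.
MOTIF_REGISTRY = {
    "YMMYMNNMMHM": "YMMYMNNMMHM",
    "CCNCCNTNNCCNC": "CCNCCNTNNCCNC",
    "CCCCACCCC": "CCCCACCCC",
    "CCN8CC": "CCNNNNNNNNCC",
}

DEFAULT_N_SHUFFLES = 130


@dataclass(frozen=True)
class MotifMatchSet:
    motif: str
    starts: tuple[int, ...]  # 1-based light-strand start positions
    genome_length: int

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def count(self) -> int:
        return len(self.starts)

    def spans(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) spans; end < start marks a wrap."""
        L = self.genome_length
        return [(s, (s + self.length - 2) % L + 1) for s in self.starts]


def motif_regex(motif: str) -> re.Pattern:
    parts = []
    for c in motif.upper():
        if c not in IUPAC:
            raise GenomeError(f"invalid IUPAC code {c!r} in motif {motif!r}")
        klass = IUPAC[c]
        parts.append(klass if len(klass) == 1 else f"[{klass}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    genome: CircularGenome | str,
    motif: str,
    allow_overlap: bool = True,
    circular: bool = True,
) -> MotifMatchSet:
    """All light-strand occurrences of an IUPAC motif (overlapping by default)."""
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome.upper()
    L = len(seq)
    m = len(motif)
    if m > L:
        raise GenomeError(f"motif length {m} exceeds genome length {L}")
    pattern = motif_regex(motif)
    text = seq + (seq[: m - 1] if circular else "")
    starts = [mt.start() + 1 for mt in pattern.finditer(text) if mt.start() < L]
    if not allow_overlap:
        kept, blocked_until = [], 0
        for s in starts:
            if s >= blocked_until:
                kept.append(s)
                blocked_until = s + m
        starts = kept
    return MotifMatchSet(motif=motif.upper(), starts=tuple(starts), genome_length=L)


def nearest_motif_distance(breakpoint: int, matches: MotifMatchSet) -> int:
    """Circular distance from a breakpoint to the nearest motif occurrence.

    Zero when the breakpoint falls inside a match span; otherwise the circular
    distance to the nearest span edge.
    """
    if matches.count == 0:
        raise GenomeError("empty match set")
    L = matches.genome_length
    if not 1 <= breakpoint <= L:
        raise GenomeError(f"breakpoint {breakpoint} outside 1..{L}")
    best = None
    for s, e in matches.spans():
        inside = s <= breakpoint <= e if s <= e else (breakpoint >= s or breakpoint <= e)
        d = 0 if inside else min(
            circular_distance(breakpoint, s, L), circular_distance(breakpoint, e, L)
        )
        best = d if best is None else min(best, d)
        if best == 0:
            break
    return best


def nearest_distance_array(matches: MotifMatchSet) -> np.ndarray:
    """Circular distance from every genome position to the nearest motif base.

    Index i holds the distance for 1-based position i + 1 (0 inside a match
    span, otherwise the distance to the nearest span edge). Equivalent to
    ``nearest_motif_distance`` applied position by position, but O(L).
    """
    if matches.count == 0:
        raise GenomeError("empty match set")
    L = matches.genome_length
    covered = np.zeros(L, dtype=bool)
    for s, e in matches.spans():
        if s <= e:
            covered[s - 1 : e] = True
        else:
            covered[s - 1 :] = True
            covered[:e] = True
    dist = np.where(covered, 0, L).astype(np.int64)
    # Two wrap-around sweeps (forward then backward) settle the circular
    # distance transform.
    for _ in range(2):
        for i in range(2 * L):
            j, jp = i % L, (i - 1) % L
            if dist[jp] + 1 < dist[j]:
                dist[j] = dist[jp] + 1
        for i in range(2 * L, 0, -1):
            j, jn = (i - 1) % L, i % L
            if dist[jn] + 1 < dist[j]:
                dist[j] = dist[jn] + 1
    return dist


def distance_percentages(
    breakpoints: Sequence[int],
    matches: MotifMatchSet,
    thresholds: Sequence[int] = (5, 20),
    inclusive: Sequence[bool] = (False, True),
    distances: np.ndarray | None = None,
) -> dict[int, float]:
    """Fraction of breakpoints within each distance threshold of the nearest motif.

    By default the 5 bp threshold is strict (< 5) and the 20 bp threshold is
    inclusive (<= 20), matching the way such cut-offs are usually phrased.
    A precomputed ``nearest_distance_array`` may be passed to amortize repeated
    calls over randomized datasets.
    """
    if len(thresholds) != len(inclusive):
        raise GenomeError("thresholds and inclusive flags must align")
    if distances is None:
        distances = nearest_distance_array(matches)
    dists = [int(distances[b - 1]) for b in breakpoints]
    n = len(dists)
    out = {}
    for t, inc in zip(thresholds, inclusive):
        hits = sum(1 for d in dists if (d <= t if inc else d < t))
        out[int(t)] = hits / n if n else float("nan")
    return out


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def klet_shuffle(sequence: str, k: int, seed: int | np.random.Generator | None = None) -> str:
    """Random permutation of a linear sequence preserving its k-mer multiset exactly.

    k = 1 permutes the bases. k >= 2 performs a uniform random Euler-path walk
    on the de Bruijn multigraph whose vertices are (k-1)-mers and whose edges
    are the sequence's k-mers: a random last-exit edge is reserved for every
    vertex so that the reserved edges form an arborescence toward the terminal
    vertex, the remaining out-edges are shuffled, and the path is read off.
    Deterministic for a fixed seed.
    """
    seq = sequence.upper()
    n = len(seq)
    if k < 1:
        raise GenomeError("k must be >= 1")
    if n < k:
        raise GenomeError(f"sequence of length {n} shorter than k = {k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == 1:
        return "".join(rng.permutation(list(seq)))

    vertices: dict[str, list[str]] = {}
    for i in range(n - k + 1):
        u, v = seq[i : i + k - 1], seq[i + 1 : i + k]
        vertices.setdefault(u, []).append(v)
        vertices.setdefault(v, [])
    v_start, v_end = seq[: k - 1], seq[n - k + 1 :]
    if len(vertices) == 1:
        return seq  # single vertex: the walk is forced

    nonterminal = [u for u in vertices if u != v_end and vertices[u]]
    for _attempt in range(10_000):
        last = {u: vertices[u][rng.integers(len(vertices[u]))] for u in nonterminal}
        # The reserved edges must let every non-terminal vertex reach v_end.
        ok = True
        for u in nonterminal:
            seen = set()
            cur = u
            while cur != v_end:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA alphabets
        raise GenomeError("failed to sample an arborescence for the k-let shuffle")

    order: dict[str, list[str]] = {}
    for u, targets in vertices.items():
        pool = list(targets)
        if u in last:
            pool.remove(last[u])
        rng.shuffle(pool)
        if u in last:
            pool.append(last[u])
        order[u] = pool

    ptr = {u: 0 for u in vertices}
    out = [v_start]
    cur = v_start
    for _ in range(n - k + 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt[-1])
        cur = nxt
    result = "".join(out)
    if len(result) != n:  # pragma: no cover - construction guarantee
        raise GenomeError("k-let shuffle produced a sequence of the wrong length")
    return result


def motif_background(
    genome: CircularGenome,
    motif: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    k: int = 3,
    seed: int | np.random.Generator | None = None,
    circular: bool = True,
) -> EnrichmentResult:
    """Observed motif count against counts in k-let-preserving shuffled genomes."""
    if n_shuffles < 2:
        raise GenomeError("need at least 2 shuffles for a background")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = scan_motif(genome, motif, circular=circular).count
    null_counts = []
    for _ in range(n_shuffles):
        shuffled = klet_shuffle(genome.sequence, k, rng)
        null_counts.append(scan_motif(shuffled, motif, circular=circular).count)
    z, degenerate = zscore(observed, null_counts)
    p = 1.0 if degenerate else pvalue_from_z(z)
    return EnrichmentResult(
        statistic=f"count[{motif}] vs k={k} shuffle",
        observed=float(observed),
        null_mean=float(np.mean(null_counts)),
        null_sd=float(np.std(null_counts, ddof=1)),
        z=z,
        p=p,
        n_datasets=n_shuffles,
        model=f"klet_shuffle_k{k}",
        degenerate=degenerate,
    )


def binned_profile_correlation(
    breakpoints: Sequence[int],
    matches: MotifMatchSet,
    bin_size: int,
    genome_length: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between binned breakpoint and motif-start counts."""
    L = genome_length if genome_length is not None else matches.genome_length
    if bin_size < 1:
        raise GenomeError("bin_size must be >= 1")
    n_bins = L // bin_size
    if n_bins < 3:
        raise GenomeError("fewer than 3 bins; decrease bin_size")
    bp_counts = np.zeros(n_bins)
    mt_counts = np.zeros(n_bins)
    for p in breakpoints:
        bp_counts[min((p - 1) // bin_size, n_bins - 1)] += 1
    for s in matches.starts:
        mt_counts[min((s - 1) // bin_size, n_bins - 1)] += 1
    rho, p = stats.spearmanr(bp_counts, mt_counts)
    return float(rho), float(p)
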