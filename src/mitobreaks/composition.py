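"""Non-overlapping window profiles of GC-content and GC-skew.

GC-skew is (G - C)/(G + C) counted on the light strand; the human mtDNA light
strand is cytosine-rich, so its genome-wide skew is strongly negative. Windows
tile the genome from position 1 with a fixed size (default 20 bp); a trailing
partial window is dropped. N bases are excluded from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import CircularGenome, GenomeError


@dataclass(frozen=True)
class CompositionWindow:
    start: int  # 1-based inclusive
    end: int
    gc_content: float  # fraction of counted (non-N) bases; NaN if none
    gc_skew: float  # (G-C)/(G+C); NaN when G+C == 0


def window_profile(genome: CircularGenome, window: int = 20) -> list[CompositionWindow]:
    """Tile the genome with non-overlapping windows and compute composition per window."""
    if window < 1:
        raise GenomeError("window size must be >= 1")
    seq = genome.sequence
    out = []
    for start0 in range(0, genome.length - window + 1, window):
        sub = seq[start0 : start0 + window]
        g, c = sub.count("G"), sub.count("C")
        a, t = sub.count("A"), sub.count("T")
        counted = g + c + a + t
        gc_content = (g + c) / counted if counted else float("nan")
        gc_skew = (g - c) / (g + c) if (g + c) else float("nan")
        out.append(CompositionWindow(start0 + 1, start0 + window, gc_content, gc_skew))
    if not out:
        raise GenomeError(f"genome shorter than one {window} bp window")
    return out


def mean_gc_content(windows: Sequence[CompositionWindow]) -> float:
    """Per-window mean GC fraction (windows with no counted bases excluded)."""
    return float(np.nanmean([w.gc_content for w in windows]))


def mean_gc_skew(windows: Sequence[CompositionWindow]) -> float:
    """Per-window mean GC-skew (undefined windows excluded)."""
    return float(np.nanmean([w.gc_skew for w in windows]))


def _window_of(pos: int, window_size: int, n_windows: int) -> int:
    """Index of the window containing a position; positions past the last full
    window (the dropped trailing partial) are assigned to the last full window."""
    idx = (pos - 1) // window_size
    return min(idx, n_windows - 1)


def density_by_bin(
    breakpoint_positions: Sequence[int],
    windows: Sequence[CompositionWindow],
    variable: str,
    bin_edges: Sequence[float],
    genome_length: int,
) -> dict:
    """Breakpoint density per 0.1 kb stratified by a composition variable.

    Each breakpoint inherits the value of its containing window; windows are
    grouped into left-closed right-open bins [e_i, e_{i+1}[ (the last bin is
    closed on the right); the density in a bin is the pooled count of
    breakpoints in that bin's windows over their total size. Also reports the
    fraction of breakpoints whose window value lies below the per-window
    genome mean.
    """
    if variable not in ("gc_skew", "gc_content"):
        raise GenomeError(f"unknown composition variable {variable!r}")
    if len(bin_edges) < 2:
        raise GenomeError("need at least two bin edges")
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise GenomeError("bin edges must be strictly increasing")
    values = np.array([getattr(w, variable) for w in windows])
    wsize = windows[0].end - windows[0].start + 1

    def bin_of(v: float) -> int | None:
        if np.isnan(v) or v < edges[0] or v > edges[-1]:
            return None
        idx = int(np.searchsorted(edges, v, side="right")) - 1
        return min(idx, len(edges) - 2)

    win_bins = [bin_of(v) for v in values]
    bin_sizes = np.zeros(len(edges) - 1)
    for w, b in zip(windows, win_bins):
        if b is not None:
            bin_sizes[b] += w.end - w.start + 1
    bin_counts = np.zeros(len(edges) - 1)
    mean_v = float(np.nanmean(values))
    below = 0
    n_assigned = 0
    for p in breakpoint_positions:
        wi = _window_of(p, wsize, len(windows))
        v = values[wi]
        if not np.isnan(v):
            n_assigned += 1
            if v < mean_v:
                below += 1
        b = win_bins[wi]
        if b is not None:
            bin_counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(bin_sizes > 0, bin_counts / np.maximum(bin_sizes, 1) * 100.0, np.nan)
    total = len(breakpoint_positions)
    return {
        "variable": variable,
        "bin_edges": [float(e) for e in edges],
        "bin_counts": bin_counts.astype(int).tolist(),
        "bin_sizes_bp": bin_sizes.astype(int).tolist(),
        "density_per_0.1kb": [float(d) for d in density],
        "fraction_breakpoints_per_bin": [float(c) / total for c in bin_counts] if total else [],
        "genome_mean": mean_v,
        "fraction_below_mean": below / n_assigned if n_assigned else float("nan"),
    }


# Width-0.2 skew bins over [-1, 1]; width-10-percentage-point GC bins
# (left-closed right-open, matching the "[55-75[" interval convention).
DEFAULT_SKEW_EDGES = [round(-1.0 + 0.2 * i, 1) for i in range(11)]
DEFAULT_GC_EDGES = [round(0.1 * i, 1) for i in range(11)]
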