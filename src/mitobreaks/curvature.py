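"""Intrinsic curvature and bendability profiles of a circular genome.

Curvature is computed as the magnitude of the vector sum of dinucleotide step
deflections (roll/tilt components of the wedge model, phased by the cumulative
helical twist) over a centered window, expressed in degrees per helical turn
(10.5 deg/helical turn = 1 deg/bp). Bendability is the windowed average of the
trinucleotide DNase I sensitivity scale. Regions with a high
curvature/bendability ratio are intrinsically curved yet rigid, i.e. under
elevated topological stress; the analysis cares about the *positions* of ratio
maxima, not the absolute profile values, which depend on the parameter tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .breakpoints import breakpoint_density
from .genome import CircularGenome, GenomeError
from .geometry_tables import BENDABILITY, WEDGE_ANGLES

DEG_PER_TURN = 10.5
# Bendability values are shifted onto a positive scale so the
# curvature/bendability quotient is defined genome-wide; the shift does not
# move ratio maxima ordering within a profile run (see docs/methods.md).
DEFAULT_BEND_SHIFT = 1.0
_MEAN_TWIST = 34.3  # used for steps containing N


@dataclass
class CurvatureProfile:
    """Aligned per-position profiles (index 0 = genome position 1)."""

    curvature: np.ndarray
    bendability: np.ndarray
    ratio: np.ndarray  # NaN where bendability is masked

    def __len__(self) -> int:
        return len(self.curvature)


def _step_deflections(seq: str, table: dict | None = None) -> np.ndarray:
    """Complex deflection of each dinucleotide step of a *linear* string.

    Step k joins bases k and k+1; its deflection is wedge * exp(i * (direction
    + cumulative twist up to the step)). Steps with unknown bases contribute
    zero deflection and the mean helical twist.
    """
    table = table or WEDGE_ANGLES
    n = len(seq) - 1
    wedge = np.zeros(n)
    direction = np.zeros(n)
    twist = np.full(n, _MEAN_TWIST)
    for k in range(n):
        din = seq[k : k + 2]
        if din in table:
            t, w, d = table[din]
            wedge[k], direction[k], twist[k] = w, d, t
    phase = np.concatenate(([0.0], np.cumsum(twist)[:-1]))
    return wedge * np.exp(1j * np.radians(direction + phase))


def curvature_profile_values(
    genome: CircularGenome, window: int = 31, table: dict | None = None
) -> np.ndarray:
    """Per-position curvature in degrees per helical turn, circular wrap at the ends."""
    L = genome.length
    if window < 2:
        raise GenomeError("curvature window must span at least one step")
    if window % 2 == 0:
        raise GenomeError("curvature window must be odd (centered)")
    if L <= window:
        raise GenomeError(f"sequence length {L} not longer than window {window}")
    half = window // 2
    # Doubled sequence keeps the cumulative twist continuous across the origin,
    # so every centered window reads a contiguous block of steps.
    ext = genome.sequence + genome.sequence[: window + 1]
    d = _step_deflections(ext, table)
    csum = np.concatenate(([0.0 + 0.0j], np.cumsum(d)))
    out = np.empty(L)
    n_steps = window - 1
    for p in range(L):  # 0-based center
        lo = p - half
        if lo < 0:
            lo += L  # wrap onto the doubled tail
        out[p] = abs(csum[lo + n_steps] - csum[lo])
    return out / n_steps * DEG_PER_TURN


def bendability_profile_values(
    genome: CircularGenome,
    window: int = 3,
    table: dict | None = None,
    shift: float = DEFAULT_BEND_SHIFT,
) -> np.ndarray:
    """Windowed trinucleotide bendability per position (shifted positive scale).

    The trinucleotide value is assigned to its center base; the profile value
    at a position is the mean over the centered window, skipping
    N-containing trinucleotides.
    """
    table = table or BENDABILITY
    L = genome.length
    if window < 1 or window % 2 == 0:
        raise GenomeError("bendability window must be a positive odd number")
    if L <= window:
        raise GenomeError(f"sequence length {L} not longer than window {window}")
    seq = genome.sequence
    vals = np.full(L, np.nan)
    for c in range(L):  # center base, 0-based
        tri = seq[(c - 1) % L] + seq[c] + seq[(c + 1) % L]
        if tri in table:
            vals[c] = table[tri] + shift
    half = window // 2
    if half == 0:
        return vals
    idx = (np.arange(L)[:, None] + np.arange(-half, half + 1)[None, :]) % L
    win = vals[idx]
    with np.errstate(invalid="ignore"):
        return np.nanmean(win, axis=1)


def ratio_profile(curvature: np.ndarray, bendability: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Elementwise curvature/bendability; masked (NaN) where bendability <= eps."""
    if curvature.shape != bendability.shape:
        raise GenomeError("curvature and bendability profiles are not aligned")
    mask = ~(bendability > eps)
    out = np.full_like(curvature, np.nan)
    valid = ~mask & ~np.isnan(bendability)
    out[valid] = curvature[valid] / bendability[valid]
    if not valid.any():
        raise GenomeError("ratio profile is fully masked")
    return out


def genome_mean_ratio(ratio: np.ndarray) -> float:
    """Mean ratio over unmasked positions."""
    return float(np.nanmean(ratio))


def compute_profile(
    genome: CircularGenome,
    curvature_window: int = 31,
    bendability_window: int = 3,
    bend_shift: float = DEFAULT_BEND_SHIFT,
) -> CurvatureProfile:
    curv = curvature_profile_values(genome, curvature_window)
    bend = bendability_profile_values(genome, bendability_window, shift=bend_shift)
    return CurvatureProfile(curv, bend, ratio_profile(curv, bend))


def local_maxima(profile: np.ndarray, min_separation: int = 100) -> list[int]:
    """1-based positions of strict local maxima of a circular profile.

    A position is a maximum when its value exceeds every value in the
    half-window to its left and is at least every value in the half-window to
    its right (so the leftmost point of a plateau is the one reported).
    Masked (NaN) positions never qualify. Peaks are returned sorted by profile
    value, highest first.
    """
    L = len(profile)
    half = max(1, min_separation // 2)
    vals = np.where(np.isnan(profile), -np.inf, profile)
    peaks = []
    for p in range(L):
        v = vals[p]
        if not np.isfinite(v):
            continue
        left = vals[(p - np.arange(1, half + 1)) % L]
        right = vals[(p + np.arange(1, half + 1)) % L]
        if np.all(v > left) and np.all(v >= right):
            peaks.append(p + 1)
    peaks.sort(key=lambda q: -vals[q - 1])
    return peaks


def peak_bin_density(
    breakpoint_positions,
    peaks,
    genome_length: int,
    halfwidth: int = 50,
) -> dict[int, float]:
    """Breakpoint density (per 0.1 kb) in the +/-halfwidth bin around each peak."""
    out = {}
    for p in peaks:
        start = (p - halfwidth - 1) % genome_length + 1
        end = (p + halfwidth - 1) % genome_length + 1
        out[p] = breakpoint_density(breakpoint_positions, [(start, end)], genome_length)
    return out
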