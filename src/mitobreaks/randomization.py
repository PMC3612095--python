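"""Null models for breakpoint positions and z-score / erfc p-value statistics.

Two null models are provided. The *random* model draws the required number of
breakpoints i.i.d. uniformly on the circular genome (with replacement). The
*partially random* model preserves the observed abundance of breakpoints
within each region class (major arc, minor arc, OH, OL), drawing uniformly
within each region. Significance of an observed statistic P against N
randomized datasets is summarized as z = (P - mean(P_null)) / sd(P_null) with
the unbiased (n-1) standard deviation, and the two-sided normal tail
probability p = erfc(|z| / sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import erfc

from .genome import GenomeError, GenomeRegion

DEFAULT_N_DATASETS = 200
DEFAULT_N_POSITIONS = 1_508


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p: float  # 1.0 reported for degenerate nulls with observed == mean
    n_datasets: int
    model: str = "random"
    degenerate: bool = False

    @property
    def stars(self) -> str:
        if self.degenerate or not np.isfinite(self.p):
            return ""
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p,
            "n_datasets": self.n_datasets,
            "model": self.model,
            "degenerate": self.degenerate,
            "stars": self.stars,
        }


@dataclass(frozen=True)
class NullModelSpec:
    model: str = "random"  # or "partially_random"
    n_positions: int = DEFAULT_N_POSITIONS
    n_datasets: int = DEFAULT_N_DATASETS
    region_counts: Mapping[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("random", "partially_random"):
            raise GenomeError(f"unknown null model {self.model!r}")
        if self.model == "partially_random":
            if self.region_counts is None:
                raise GenomeError("partially_random model requires region_counts")
            total = sum(self.region_counts.values())
            if total != self.n_positions:
                raise GenomeError(
                    f"region counts sum to {total}, expected n_positions={self.n_positions}"
                )


def random_breakpoints(
    spec: NullModelSpec, genome_length: int, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Datasets of i.i.d. uniform positions on 1..L (with replacement)."""
    if spec.n_positions < 1:
        raise GenomeError("n_positions must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    return [
        rng.integers(1, genome_length + 1, size=spec.n_positions)
        for _ in range(spec.n_datasets)
    ]


def _region_positions(region: GenomeRegion, genome_length: int) -> np.ndarray:
    if region.start <= region.end:
        return np.arange(region.start, region.end + 1)
    return np.concatenate(
        [np.arange(region.start, genome_length + 1), np.arange(1, region.end + 1)]
    )


def partially_random_breakpoints(
    spec: NullModelSpec,
    regions: Sequence[GenomeRegion],
    genome_length: int,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Datasets preserving the prescribed per-region-class breakpoint counts."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    assert spec.region_counts is not None
    pools = {}
    for cls, count in spec.region_counts.items():
        members = [r for r in regions if r.region_class == cls]
        pool = (
            np.concatenate([_region_positions(r, genome_length) for r in members])
            if members
            else np.array([], dtype=int)
        )
        if count > 0 and pool.size == 0:
            raise GenomeError(f"region class {cls!r} is empty but has count {count}")
        pools[cls] = pool
    out = []
    for _ in range(spec.n_datasets):
        parts = [
            rng.choice(pools[cls], size=count, replace=True)
            for cls, count in spec.region_counts.items()
            if count > 0
        ]
        out.append(np.concatenate(parts) if parts else np.array([], dtype=int))
    return out


def observed_region_counts(
    positions: Sequence[int], regions: Sequence[GenomeRegion]
) -> dict[str, int]:
    """Per-region-class breakpoint counts of the observed dataset."""
    counts = {r.region_class: 0 for r in regions}
    for p in positions:
        for r in regions:
            if r.contains(p):
                counts[r.region_class] += 1
                break
        else:
            raise GenomeError(f"position {p} not covered by the region partition")
    return counts


def zscore(observed: float, null_samples: Sequence[float]) -> tuple[float, bool]:
    """(z, degenerate): z = (observed - mean)/sd with the sample (n-1) sd."""
    samples = np.asarray(null_samples, dtype=float)
    if samples.size < 2:
        raise GenomeError("need at least 2 null samples for a z-score")
    sd = samples.std(ddof=1)
    if sd == 0:
        # Degenerate null: a statistic conserved by the model. z = 0 when the
        # observation equals the (constant) null; otherwise no finite z exists.
        return (0.0 if observed == samples.mean() else float("nan")), True
    return float((observed - samples.mean()) / sd), False


def pvalue_from_z(z: float) -> float:
    """Two-sided normal tail probability p = erfc(|z|/sqrt(2))."""
    if not np.isfinite(z):
        raise GenomeError("z-score must be finite")
    return float(erfc(abs(z) / math.sqrt(2.0)))


def enrichment_test(
    statistic: Callable[[Sequence[int]], float],
    observed_positions: Sequence[int],
    spec: NullModelSpec,
    genome_length: int,
    regions: Sequence[GenomeRegion] | None = None,
    name: str = "statistic",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Compare a statistic of the observed positions against one null model."""
    if spec.model == "random":
        datasets = random_breakpoints(spec, genome_length, rng=rng)
    else:
        if regions is None:
            raise GenomeError("partially_random model requires the region partition")
        datasets = partially_random_breakpoints(spec, regions, genome_length, rng=rng)
    observed = float(statistic(list(observed_positions)))
    null_vals = [float(statistic(list(ds))) for ds in datasets]
    null_mean = float(np.mean(null_vals))
    null_sd = float(np.std(null_vals, ddof=1))
    z, degenerate = zscore(observed, null_vals)
    p = 1.0 if degenerate else pvalue_from_z(z)
    return EnrichmentResult(
        statistic=name,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        n_datasets=spec.n_datasets,
        model=spec.model,
        degenerate=degenerate,
    )
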