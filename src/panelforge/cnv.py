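"""Read-depth diploid copy-number estimation for tandem gene arrays.

The salivary amylase locus carries a variable number of tandem copies of a
unit containing AMY1A, Region X (the AMY1A-AMY1B intergenic segment) and
AMY1B, followed by a single AMY1C.  Per-region mean depths are normalized by
half the depth of a mappability-selected diploid reference region
("Region Z"), so a normalized value of 2 means two diploid copies.  Summing
the normalized values of the three AMY1 gene regions gives the AMY1 diploid
copy number y; the diplotype model relates it to the Region X diploid count
n as y = 2n + 2 (each extra unit adds one Region X and two AMY1 copies; the
AMY1C baseline contributes the +2).

Also here: the structural-variant call merging rule (reciprocal overlap >=
80%, merged coordinates are the means of the member coordinates) and the
known/novel classification of insertion and deletion calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, t as t_dist

from .types import Region

#: hg19 coordinates of the amylase locus regions (1-based inclusive).
#: Note: the AMY1A interval follows the printed source table; it is wider
#: than the AMY1B/AMY1C gene bodies and inconsistent with the locus
#: schematic -- flagged in the documentation, and any BED is accepted.
AMYLASE_REGIONS: tuple[Region, ...] = (
    Region("chr1", 104_096_436, 104_122_156, "AMY2B"),
    Region("chr1", 104_096_436, 104_207_173, "AMY1A"),
    Region("chr1", 104_230_036, 104_239_302, "AMY1B"),
    Region("chr1", 104_293_027, 104_301_312, "AMY1C"),
    Region("chr1", 104_210_000, 104_211_500, "RegionX"),
    Region("chr1", 104_350_000, 104_400_000, "RegionY"),
    Region("chr1", 104_400_000, 104_450_000, "RegionZ"),
)

AMY1_GENES = ("AMY1A", "AMY1B", "AMY1C")
REFERENCE_REGION = "RegionZ"
UNIT_REGION = "RegionX"


class RegionDepthProfile:
    """Per-sample mean per-base depth over named regions.

    Wraps a samples x regions DataFrame; the region set must include the
    diploid reference region used for normalization.
    """

    def __init__(self, depths: pd.DataFrame,
                 reference: str = REFERENCE_REGION) -> None:
        if reference not in depths.columns:
            raise ValueError(f"profile lacks reference region {reference!r}")
        if (depths.to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")
        self.depths = depths.astype(float)
        self.reference = reference

    @property
    def samples(self) -> list[str]:
        return list(self.depths.index)

    @property
    def regions(self) -> list[str]:
        return list(self.depths.columns)

    def depth(self, sample: str, region: str) -> float:
        if region not in self.depths.columns:
            raise ValueError(f"region {region!r} not in profile")
        return float(self.depths.at[sample, region])


def normalized_cn(sample: str, region: str,
                  profile: RegionDepthProfile) -> float:
    """Diploid copy number: region depth over half the reference depth."""
    ref = profile.depth(sample, profile.reference)
    if ref <= 0:
        raise ValueError(
            f"sample {sample!r} has zero reference-region depth; excluded"
        )
    return 2.0 * profile.depth(sample, region) / ref


def amy1_cn(sample: str, profile: RegionDepthProfile) -> tuple[float, float]:
    """Summed AMY1 diploid copy number y and Region X copy number n."""
    for region in (*AMY1_GENES, UNIT_REGION):
        if region not in profile.regions:
            raise ValueError(f"profile missing region {region!r}")
    y = sum(normalized_cn(sample, g, profile) for g in AMY1_GENES)
    n = normalized_cn(sample, UNIT_REGION, profile)
    return y, n


@dataclass
class UnitModelFit:
    """OLS fit of summed gene copies y on unit-region copies n."""

    slope: float
    intercept: float
    residual_sd: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_samples: int
    pairs: list[tuple[float, float]] = field(repr=False, default_factory=list)

    def contains_diplotype_model(self, slope: float = 2.0,
                                 intercept: float = 2.0) -> bool:
        """Whether the stated unit model lies within both 95% CIs."""
        return (self.slope_ci[0] <= slope <= self.slope_ci[1]
                and self.intercept_ci[0] <= intercept <= self.intercept_ci[1])


def fit_unit_model(pairs: Sequence[tuple[float, float]]) -> UnitModelFit:
    """Ordinary least squares of y (gene copies) on n (unit copies).

    Requires at least two distinct n values; 95% parameter intervals use the
    t distribution with n-2 degrees of freedom.
    """
    n_arr = np.array([p[0] for p in pairs], dtype=float)
    y_arr = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(n_arr).size < 2:
        raise ValueError("rank deficient: unit copy number does not vary")
    res = linregress(n_arr, y_arr)
    k = len(pairs)
    resid = y_arr - (res.slope * n_arr + res.intercept)
    dof = max(k - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    tq = float(t_dist.ppf(0.975, dof)) if k > 2 else float("inf")
    return UnitModelFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        slope_ci=(res.slope - tq * res.stderr, res.slope + tq * res.stderr),
        intercept_ci=(res.intercept - tq * res.intercept_stderr,
                      res.intercept + tq * res.intercept_stderr),
        n_samples=k,
        pairs=list(pairs),
    )


def integer_cn_call(cn: float, parity: Optional[str] = None) -> int:
    """Round a continuous copy-number estimate to an integer call.

    Default: nearest integer, half rounded up.  With ``parity="even"`` the
    nearest even integer, exact ties resolved downward (7.0 -> 6).
    """
    if cn < 0:
        raise ValueError("copy number must be non-negative")
    if parity is None:
        return int(math.floor(cn + 0.5))
    if parity != "even":
        raise ValueError("parity must be None or 'even'")
    return 2 * int(math.ceil(cn / 2.0 - 0.5))


# ---------------------------------------------------------------------------
# SV call merging and novelty


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on one chromosome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_calls_80(calls: Sequence[Interval],
                   threshold: float = 0.80) -> list[Interval]:
    """Merge calls with reciprocal overlap >= threshold, transitively.

    Merged start/end are the arithmetic means of the member coordinates,
    rounded half-up.  Output is sorted, so the result is invariant to the
    input order.
    """
    k = len(calls)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            if reciprocal_overlap(calls[i], calls[j]) >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[Interval]] = {}
    for i in range(k):
        clusters.setdefault(find(i), []).append(calls[i])
    merged = []
    for members in clusters.values():
        start = int(math.floor(np.mean([m.start for m in members]) + 0.5))
        end = int(math.floor(np.mean([m.end for m in members]) + 0.5))
        merged.append(Interval(start, end))
    return sorted(merged, key=lambda iv: (iv.start, iv.end))


@dataclass(frozen=True)
class SVCall:
    chrom: str
    start: int
    end: int
    svtype: str  # "insertion" or "deletion"

    def __post_init__(self) -> None:
        if self.svtype not in ("insertion", "deletion"):
            raise ValueError("svtype must be 'insertion' or 'deletion'")


def classify_sv_novelty(call: SVCall,
                        known_catalogue: Iterable[SVCall]) -> str:
    """Classify a call as "known" or "novel" against a catalogue.

    Insertions are known when the nearest catalogued insertion breakpoint on
    the same chromosome is within 10 bp; deletions are known when some
    catalogued deletion covers >= 50% of the call's length.
    """
    same = [c for c in known_catalogue
            if c.chrom == call.chrom and c.svtype == call.svtype]
    if call.svtype == "insertion":
        for c in same:
            if abs(c.start - call.start) <= 10:
                return "known"
        return "novel"
    length = call.end - call.start + 1
    for c in same:
        ov = min(call.end, c.end) - max(call.start, c.start) + 1
        if ov > 0 and ov / length >= 0.50:
            return "known"
    return "novel"
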