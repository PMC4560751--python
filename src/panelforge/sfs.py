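"""Folded site frequency spectra, hypergeometric projection, and the
fraction of very-rare variants (FVRV).

The number of genotyped individuals differs from site to site after the
per-sample depth filter, so per-site allele counts are projected down to a
uniform sample size with the hypergeometric projection: a site with minor
count i among 2n called chromosomes contributes, to the class j of a target
sample of 2m chromosomes, the probability that a random 2m-subset carries
exactly j minor alleles,

    P(j | i, 2n, 2m) = C(i, j) C(2n - i, 2m - j) / C(2n, 2m).

Summing these expected contributions over sites gives a fractional folded
SFS at the uniform size.  FVRV is the share of that spectrum's mass at
MAF <= 0.1%; stronger purifying selection on a functional category shows up
as a higher FVRV.  The projection target defaults to 90% of the cohort,
which by construction equals the minimum number of genotyped individuals
after the 10% site-missingness filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import fisher_exact, hypergeom

from .types import MISSING, GenotypeMatrix

MAF_BINS = ("very_rare", "rare", "low", "common")


@dataclass(frozen=True)
class SiteCount:
    """Minor-allele copies at a site and the called sample size there."""

    minor_count: int
    called_n: int  # genotyped individuals (2 * called_n chromosomes)

    def __post_init__(self) -> None:
        if not (0 <= self.minor_count <= self.called_n):
            raise ValueError("folded minor count must lie in [0, called_n]")


@dataclass
class FoldedSFS:
    """Fractional folded spectrum at a uniform sample size.

    ``counts[j - 1]`` is the expected number of segregating sites with minor
    count j, j = 1..sample_size individuals (2m chromosomes).
    """

    sample_size: int  # m individuals; 2m chromosomes
    counts: np.ndarray
    category: str = ""
    n_excluded: int = 0  # sites with called_n < m, not projectable

    @property
    def two_m(self) -> int:
        return 2 * self.sample_size

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class FVRVResult:
    category: str
    n_very_rare: float
    n_total: float
    fraction: float
    ci_low: float
    ci_high: float


def projection_sample_size(n_cohort: int, fraction: float = 0.90) -> int:
    """Uniform projection target: floor(fraction * cohort size)."""
    return int(math.floor(fraction * n_cohort))


def site_counts(matrix: GenotypeMatrix) -> list[SiteCount]:
    """Per-site folded minor-allele counts; monomorphic sites are dropped."""
    gt = matrix.genotype
    called = gt != MISSING
    n_i = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    minor = np.minimum(alt, 2 * n_i - alt)
    keep = (minor > 0) & (n_i > 0)
    return [SiteCount(int(m), int(n))
            for m, n in zip(minor[keep], n_i[keep])]


def project_site(i: int, two_n: int, two_m: int,
                 fold: bool = True) -> np.ndarray:
    """Hypergeometric downsampling vector P(j | i, 2n, 2m) over j = 0..2m.

    With ``fold=True`` the folded transform is re-applied after projection
    (mass at j > m is reflected onto 2m - j).
    """
    if two_m > two_n:
        raise ValueError(f"cannot project {two_n} chromosomes up to {two_m}")
    if not (0 <= i <= two_n):
        raise ValueError("allele count outside [0, 2n]")
    j = np.arange(two_m + 1)
    p = hypergeom.pmf(j, two_n, i, two_m)
    if fold:
        folded = np.zeros(two_m + 1)
        for jj in range(two_m + 1):
            folded[min(jj, two_m - jj)] += p[jj]
        p = folded
    return p


def project_sfs(sites: Sequence[SiteCount], m: int,
                category: str = "") -> FoldedSFS:
    """Project per-site counts to a uniform size of ``m`` individuals.

    Sites with fewer than ``m`` called individuals cannot be downsampled and
    are excluded (their number is reported on the result).  Projection is
    linear: the spectrum of a concatenation is the sum of the spectra.
    """
    two_m = 2 * m
    counts = np.zeros(m)
    n_excluded = 0
    # group identical (i, n) pairs: one pmf evaluation per distinct pair
    tally: dict[tuple[int, int], int] = {}
    for s in sites:
        if s.called_n < m:
            n_excluded += 1
            continue
        tally[(s.minor_count, s.called_n)] = (
            tally.get((s.minor_count, s.called_n), 0) + 1
        )
    for (i, n_i), mult in tally.items():
        p = project_site(i, 2 * n_i, two_m, fold=True)
        # j = 0 (monomorphic leakage) excluded; folded support is j <= m
        counts += mult * p[1:m + 1]
    return FoldedSFS(sample_size=m, counts=counts, category=category,
                     n_excluded=n_excluded)


def maf_bin(j: int, two_m: int, very_rare: float = 0.001,
            rare: float = 0.005, low: float = 0.05) -> str:
    """Bin a minor count by MAF: very_rare <= 0.1% < rare <= 0.5% < low <= 5%
    < common (upper bounds inclusive)."""
    if j < 1:
        raise ValueError("minor count must be >= 1")
    f = j / two_m
    if f <= very_rare:
        return "very_rare"
    if f <= rare:
        return "rare"
    if f <= low:
        return "low"
    return "common"


def clopper_pearson(k: int, n: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def fvrv(sfs: FoldedSFS, very_rare: float = 0.001) -> FVRVResult:
    """Fraction of very-rare variants with a 95% Clopper-Pearson CI.

    The point estimate uses the raw fractional projected masses; the CI is
    computed on masses rounded half-to-even to integers (exact intervals
    need integer successes/trials).
    """
    total = sfs.total
    if total <= 0:
        raise ValueError("empty spectrum: FVRV undefined")
    j = np.arange(1, sfs.sample_size + 1)
    vr_mask = (j / sfs.two_m) <= very_rare
    n_vr = float(sfs.counts[vr_mask].sum())
    frac = n_vr / total
    k_int, n_int = _round_half_even(n_vr), _round_half_even(total)
    k_int = min(k_int, n_int)
    if n_int > 0:
        lo, hi = clopper_pearson(k_int, n_int)
        lo, hi = min(lo, frac), max(hi, frac)
    else:
        lo, hi = 0.0, 1.0
    return FVRVResult(category=sfs.category, n_very_rare=n_vr, n_total=total,
                      fraction=frac, ci_low=lo, ci_high=hi)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_fractions(a: FVRVResult, b: FVRVResult) -> float:
    """Two-sided Fisher's exact test: very-rare vs not, category a vs b.

    Fractional masses are rounded half-to-even before the exact test.
    """
    if a.n_total <= 0 or b.n_total <= 0:
        raise ValueError("both categories need positive totals")
    ka, na = _round_half_even(a.n_very_rare), _round_half_even(a.n_total)
    kb, nb = _round_half_even(b.n_very_rare), _round_half_even(b.n_total)
    ka, kb = min(ka, na), min(kb, nb)
    return fisher_2x2(ka, na - ka, kb, nb - kb)


def sfs_by_category(matrix: GenotypeMatrix, m: int) -> dict[str, FoldedSFS]:
    """Project the matrix's sites per functional category."""
    by_cat: dict[str, list[SiteCount]] = {}
    gt = matrix.genotype
    called = gt != MISSING
    n_i = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    minor = np.minimum(alt, 2 * n_i - alt)
    for idx, site in enumerate(matrix.sites):
        if minor[idx] <= 0 or n_i[idx] == 0:
            continue
        by_cat.setdefault(site.functional_category.value, []).append(
            SiteCount(int(minor[idx]), int(n_i[idx]))
        )
    return {cat: project_sfs(sc, m, category=cat)
            for cat, sc in sorted(by_cat.items())}
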