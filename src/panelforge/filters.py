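"""The genotype QC filter cascade (steps 2-6 of panel construction).

Order of operations on a raw cohort genotype matrix:

  step 2  per-sample depth calibration: genotype precision against SNP-array
          truth is computed per read-depth bin, the longest contiguous run of
          bins with precision > 0.998 defines each sample's retained depth
          interval, and calls outside it become missing;
  step 3  site missingness: sites not genotyped in > 10% of samples are
          dropped;
  step 4  repeat-class precision: repeat classes whose pooled precision
          against the array is <= 0.997 are dropped wholesale;
  step 5  caller intersection: sites absent from the high-sensitive caller's
          superset are dropped;
  step 6  exact Hardy-Weinberg test: sites with p < 1e-5 are dropped.

Precision counts a call concordant when the sequencing genotype equals the
array genotype at a cell where sequencing calls a variant (het or hom-alt)
and the array is non-missing; recall counts array-variant cells recovered
with an equal genotype.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import RunConfig
from .types import MISSING, ArrayTruth, GenotypeMatrix

logger = logging.getLogger(__name__)

#: open upper depth bound used when a retained interval includes the top bin
DEPTH_UNBOUNDED: int = 2**31 - 1


class UncalibratableSampleError(ValueError):
    """No depth bin reaches the precision floor for this sample."""


@dataclass(frozen=True)
class DepthRange:
    sample: str
    d_lo: int
    d_hi: int

    def __post_init__(self) -> None:
        if self.d_lo > self.d_hi:
            raise ValueError("d_lo must not exceed d_hi")


@dataclass
class StepReport:
    step: str
    sites_in: int
    sites_out: int
    extra: dict = field(default_factory=dict)

    @property
    def fraction_removed(self) -> float:
        return 0.0 if self.sites_in == 0 else (
            (self.sites_in - self.sites_out) / self.sites_in
        )

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "sites_in": self.sites_in,
            "sites_out": self.sites_out,
            "fraction_removed": self.fraction_removed,
            **self.extra,
        }


@dataclass
class FilterReport:
    steps: list[StepReport] = field(default_factory=list)
    cells_masked: int = 0
    samples_dropped: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "steps": [s.to_dict() for s in self.steps],
            "cells_masked": self.cells_masked,
            "samples_dropped": self.samples_dropped,
        }, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Step 2: depth calibration


def depth_concordance(
    matrix: GenotypeMatrix,
    truth: ArrayTruth,
    sample: str,
    min_bin_sites: int = 500,
    depth_cap: int = 150,
) -> pd.DataFrame:
    """Per-depth-bin precision/recall against array truth for one sample.

    Depth bins are integer depths capped at ``depth_cap`` (all higher depths
    pooled into the top bin).  Bins with fewer than ``min_bin_sites`` calls
    are merged with the nearest lower bin before precision is computed.

    Returns a frame with columns d_lo, d_hi, n_calls, n_concordant,
    precision, n_array_variant, n_recovered, recall.
    """
    j = matrix.samples.index(sample)
    ngs = matrix.genotype[:, j]
    dep = np.minimum(matrix.depth[:, j], depth_cap)
    tru = truth.genotype[:, j]
    covered = tru != MISSING
    if not covered.any():
        raise ValueError(f"no array truth cells for sample {sample!r}")

    is_call = covered & ((ngs == 1) | (ngs == 2))
    is_conc = is_call & (ngs == tru)
    is_arrv = covered & ((tru == 1) | (tru == 2))
    is_recv = is_arrv & (ngs == tru)

    nbins = depth_cap + 1
    calls = np.bincount(dep[is_call], minlength=nbins)
    conc = np.bincount(dep[is_conc], minlength=nbins)
    arrv = np.bincount(dep[is_arrv], minlength=nbins)
    recv = np.bincount(dep[is_recv], minlength=nbins)

    observed = np.flatnonzero((calls > 0) | (arrv > 0))
    groups: list[list[int]] = []
    current: list[int] = []
    acc = 0
    for d in observed:
        current.append(int(d))
        acc += int(calls[d])
        if acc >= min_bin_sites:
            groups.append(current)
            current, acc = [], 0
    if current:
        if groups:
            groups[-1].extend(current)  # trailing small group merges downward
        else:
            groups.append(current)

    rows = []
    for grp in groups:
        c = int(calls[grp].sum())
        k = int(conc[grp].sum())
        av = int(arrv[grp].sum())
        rv = int(recv[grp].sum())
        d_hi = DEPTH_UNBOUNDED if grp[-1] >= depth_cap else grp[-1]
        rows.append({
            "d_lo": grp[0], "d_hi": d_hi,
            "n_calls": c, "n_concordant": k,
            "precision": (k / c) if c > 0 else np.nan,
            "n_array_variant": av, "n_recovered": rv,
            "recall": (rv / av) if av > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def select_depth_range(
    table: pd.DataFrame,
    sample: str = "",
    min_precision: float = 0.998,
) -> DepthRange:
    """Longest contiguous run of depth bins with precision strictly above the
    floor; ties broken toward the run carrying more calls."""
    if len(table) == 0:
        raise ValueError("empty concordance table")
    passing = (table["n_calls"] > 0) & (table["precision"] > min_precision)
    best: Optional[tuple[int, int, int]] = None  # (start, stop, n_calls)
    start = None
    vals = passing.to_numpy()
    for idx in range(len(vals) + 1):
        if idx < len(vals) and vals[idx]:
            if start is None:
                start = idx
        else:
            if start is not None:
                run_calls = int(table["n_calls"].iloc[start:idx].sum())
                length = idx - start
                if best is None:
                    best = (start, idx, run_calls)
                else:
                    b_len = best[1] - best[0]
                    if length > b_len or (length == b_len
                                          and run_calls > best[2]):
                        best = (start, idx, run_calls)
                start = None
    if best is None:
        raise UncalibratableSampleError(
            f"sample {sample!r}: no depth bin exceeds precision "
            f"{min_precision}"
        )
    return DepthRange(
        sample=sample,
        d_lo=int(table["d_lo"].iloc[best[0]]),
        d_hi=int(table["d_hi"].iloc[best[1] - 1]),
    )


def apply_depth_filter(
    matrix: GenotypeMatrix,
    ranges: dict[str, Optional[DepthRange]],
) -> tuple[GenotypeMatrix, int]:
    """Mask genotype calls with depth outside each sample's retained interval.

    Samples mapped to ``None`` (uncalibratable) are dropped from the cohort.
    Returns the filtered matrix and the number of masked cells.
    """
    for s in matrix.samples:
        if s not in ranges:
            raise ValueError(f"no depth range or exclusion flag for {s!r}")
    keep = [s for s in matrix.samples if ranges[s] is not None]
    out = matrix.subset_samples(keep)
    gt = out.genotype.copy()
    masked = 0
    for j, s in enumerate(out.samples):
        r = ranges[s]
        bad = (out.depth[:, j] < r.d_lo) | (out.depth[:, j] > r.d_hi)
        bad &= gt[:, j] != MISSING
        masked += int(bad.sum())
        gt[bad, j] = MISSING
    return out.with_genotype(gt), masked


# ---------------------------------------------------------------------------
# Steps 3-5


def locus_missingness_filter(
    matrix: GenotypeMatrix, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Drop sites missing in strictly more than ``max_missing`` of samples."""
    if matrix.n_samples == 0:
        return matrix.copy()
    frac = matrix.missing_mask().mean(axis=1)
    return matrix.subset_sites(frac <= max_missing)


def repeat_class_precision(
    matrix: GenotypeMatrix, truth: ArrayTruth
) -> pd.DataFrame:
    """Pooled genotype precision against array truth per repeat class."""
    classes = np.array([s.repeat_class.value for s in matrix.sites])
    covered = truth.covered_mask()
    is_call = covered & np.isin(matrix.genotype, (1, 2))
    is_conc = is_call & (matrix.genotype == truth.genotype)
    rows = []
    for cls in sorted(set(classes)):
        rmask = classes == cls
        n_calls = int(is_call[rmask].sum())
        n_conc = int(is_conc[rmask].sum())
        rows.append({
            "repeat_class": cls,
            "n_sites": int(rmask.sum()),
            "n_calls": n_calls,
            "n_concordant": n_conc,
            "precision": (n_conc / n_calls) if n_calls else np.nan,
        })
    return pd.DataFrame(rows)


def repeat_class_filter(
    matrix: GenotypeMatrix,
    truth: ArrayTruth,
    min_precision: float = 0.997,
) -> GenotypeMatrix:
    """Drop sites in repeat classes with pooled precision <= ``min_precision``.

    Classes with no truth overlap are retained with a logged warning.
    """
    table = repeat_class_precision(matrix, truth)
    removed = set()
    for r in table.itertuples(index=False):
        if r.n_calls == 0:
            logger.warning(
                "repeat class %r has no array-truth calls; retained",
                r.repeat_class,
            )
        elif r.precision <= min_precision:
            removed.add(r.repeat_class)
    keep = np.array([s.repeat_class.value not in removed
                     for s in matrix.sites])
    return matrix.subset_sites(keep)


def tool_intersection_filter(
    matrix: GenotypeMatrix,
    sensitive_sites: Iterable[tuple[str, int, str, str]],
) -> GenotypeMatrix:
    """Retain only sites also discovered by the high-sensitive caller."""
    sens = set(sensitive_sites)
    keep = np.array([s.key in sens for s in matrix.sites], dtype=bool)
    if matrix.n_sites == 0:
        keep = np.zeros(0, dtype=bool)
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# Step 6: exact Hardy-Weinberg test


@lru_cache(maxsize=200_000)
def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Levene-Haldane).

    Conditional on the observed allele counts, the heterozygote count h has
    probability

        P(h) = n! / (n_AA! h! n_aa!) * 2^h / C(2n, n_a)-normalizer,

    over all attainable h of the right parity.  The p-value is the summed
    probability of configurations no more probable than the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_hom_alt + n_het          # one allele's count
    n_minor = min(n_a, 2 * n - n_a)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to a constant: -log((n_a-h)/2)! - log h! - log((2n-n_a-h)/2)! + h log 2
    log_p = (
        hs * math.log(2.0)
        - gammaln((n_minor - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((2 * n - n_minor - hs) / 2 + 1)
    )
    log_p -= logsumexp(log_p)
    obs = log_p[np.searchsorted(hs, n_het)]
    p = float(np.exp(log_p[log_p <= obs + 1e-10]).sum())
    return min(p, 1.0)


def hwe_filter(
    matrix: GenotypeMatrix, alpha: float = 1e-5
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop sites whose exact HWE p-value is strictly below ``alpha``.

    All-missing sites have an undefined p (reported as NaN) and are retained
    with a warning.  Returns (filtered matrix, per-site p-values).
    """
    gt = matrix.genotype
    p = np.ones(matrix.n_sites)
    keep = np.ones(matrix.n_sites, dtype=bool)
    for i in range(matrix.n_sites):
        row = gt[i]
        counts = (int((row == 0).sum()), int((row == 1).sum()),
                  int((row == 2).sum()))
        if sum(counts) == 0:
            logger.warning("site %d is all-missing; HWE undefined, retained", i)
            p[i] = np.nan
            continue
        p[i] = hwe_exact_test(*counts)
        keep[i] = not (p[i] < alpha)
    return matrix.subset_sites(keep), p


# ---------------------------------------------------------------------------
# Concordance metric and cascade driver


def genotype_r2(calls: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages over cells where both
    sides are non-missing; NaN when either side has zero variance."""
    calls = np.asarray(calls).ravel()
    truth = np.asarray(truth).ravel()
    ok = (calls != MISSING) & (truth != MISSING)
    x, y = calls[ok].astype(float), truth[ok].astype(float)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def overall_precision(matrix: GenotypeMatrix, truth: ArrayTruth) -> float:
    """Pooled genotype precision of variant calls against truth cells."""
    covered = truth.covered_mask()
    is_call = covered & np.isin(matrix.genotype, (1, 2))
    n = int(is_call.sum())
    if n == 0:
        return float("nan")
    return float((matrix.genotype[is_call] == truth.genotype[is_call]).sum() / n)


def run_cascade(
    matrix: GenotypeMatrix,
    truth: ArrayTruth,
    sensitive_sites: Iterable[tuple[str, int, str, str]],
    config: Optional[RunConfig] = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply filter steps 2-6 in order and report per-step site counts."""
    cfg = config or RunConfig()
    report = FilterReport()
    if matrix.n_sites == 0:
        for step in ("depth", "missingness", "repeat_class",
                     "tool_intersection", "hwe"):
            report.steps.append(StepReport(step, 0, 0))
        return matrix.copy(), report

    # step 2
    ranges: dict[str, Optional[DepthRange]] = {}
    for s in matrix.samples:
        try:
            table = depth_concordance(
                matrix, truth, s,
                min_bin_sites=cfg.min_bin_sites, depth_cap=cfg.depth_bin_cap,
            )
            ranges[s] = select_depth_range(
                table, s, min_precision=cfg.depth_precision_min
            )
        except (UncalibratableSampleError, ValueError) as exc:
            logger.warning("dropping sample %r: %s", s, exc)
            ranges[s] = None
    filtered, masked = apply_depth_filter(matrix, ranges)
    dropped = [s for s in matrix.samples if ranges[s] is None]
    keep_cols = np.array([ranges[s] is not None for s in matrix.samples])
    truth2 = ArrayTruth(truth.genotype[:, keep_cols])
    report.cells_masked = masked
    report.samples_dropped = dropped
    report.steps.append(StepReport(
        "depth", matrix.n_sites, filtered.n_sites,
        {"cells_masked": masked, "samples_dropped": len(dropped)},
    ))

    # step 3
    before = filtered.n_sites
    site_keep = (filtered.missing_mask().mean(axis=1)
                 <= cfg.max_missing_fraction) if filtered.n_samples else \
        np.ones(before, dtype=bool)
    filtered = filtered.subset_sites(site_keep)
    truth2 = truth2.subset_sites(site_keep)
    report.steps.append(StepReport("missingness", before, filtered.n_sites))

    # step 4
    before = filtered.n_sites
    table = repeat_class_precision(filtered, truth2)
    removed_classes = {
        r.repeat_class for r in table.itertuples(index=False)
        if r.n_calls > 0 and r.precision <= cfg.repeat_precision_min
    }
    site_keep = np.array(
        [s.repeat_class.value not in removed_classes for s in filtered.sites],
        dtype=bool,
    ) if before else np.zeros(0, dtype=bool)
    filtered = filtered.subset_sites(site_keep)
    truth2 = truth2.subset_sites(site_keep)
    report.steps.append(StepReport(
        "repeat_class", before, filtered.n_sites,
        {"removed_classes": sorted(removed_classes)},
    ))

    # step 5
    before = filtered.n_sites
    sens = set(sensitive_sites)
    site_keep = np.array([s.key in sens for s in filtered.sites],
                         dtype=bool) if before else np.zeros(0, dtype=bool)
    filtered = filtered.subset_sites(site_keep)
    truth2 = truth2.subset_sites(site_keep)
    report.steps.append(StepReport("tool_intersection", before,
                                   filtered.n_sites))

    # step 6
    before = filtered.n_sites
    filtered, _pvals = hwe_filter(filtered, alpha=cfg.hwe_alpha)
    report.steps.append(StepReport("hwe", before, filtered.n_sites))

    return filtered, report


# ---------------------------------------------------------------------------
# Per-individual variant load


def per_individual_load(
    matrix: GenotypeMatrix,
    site_predicate: Callable[..., bool],
    zygosity: str = "any",
) -> dict:
    """Count qualifying variant genotypes per sample.

    ``site_predicate(site)`` selects sites (by annotation, frequency bin,
    etc.); ``zygosity`` is "het", "hom", or "any".  Returns per-sample
    counts plus their mean and standard deviation (population s.d.).
    """
    if zygosity not in ("het", "hom", "any"):
        raise ValueError("zygosity must be 'het', 'hom' or 'any'")
    mask = np.array([bool(site_predicate(s)) for s in matrix.sites],
                    dtype=bool) if matrix.n_sites else np.zeros(0, dtype=bool)
    gt = matrix.genotype[mask]
    if zygosity == "het":
        hits = gt == 1
    elif zygosity == "hom":
        hits = gt == 2
    else:
        hits = (gt == 1) | (gt == 2)
    counts = hits.sum(axis=0) if gt.size else np.zeros(matrix.n_samples,
                                                       dtype=int)
    return {
        "counts": {s: int(c) for s, c in zip(matrix.samples, counts)},
        "mean": float(np.mean(counts)) if matrix.n_samples else 0.0,
        "sd": float(np.std(counts)) if matrix.n_samples else 0.0,
    }
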