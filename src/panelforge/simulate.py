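"""Synthetic cohort generator: every input the pipeline consumes, with the
statistical structure the analyses assume.

What it emulates
----------------
* per-site minor-allele counts drawn from the folded expected SFS of a
  configurable demographic model (default: a 10x recent exponential
  expansion, matching the excess of rare variants a deep population panel
  shows);
* Hardy-Weinberg genotypes conditional on the drawn allele count (alleles
  are placed on chromosomes uniformly at random, so the sample spectrum
  reproduces the drawn class exactly and genotype counts follow the
  Levene-Haldane conditional law);
* per-cell read depths, negative-binomially dispersed around a per-sample
  mean (depth-zero cells are uncallable and come out missing);
* genotype errors whose rate depends on depth (worse at the extremes) and
  on the site's repeat class (worse in low-complexity repeats), each error
  replacing the true genotype with a uniformly chosen different code;
* a fraction of sites carrying a systematic excess-heterozygote calling
  artifact (the signature the Hardy-Weinberg filter hunts);
* an error-free SNP-array truth subset ascertained at common,
  non-repetitive, non-artifact sites (arrays are designed at well-behaved
  known SNPs);
* a "high-sensitive" second-caller superset: all true sites plus decoys;
* amylase-locus depth tracks with planted copy units (y = 2n + 2);
* a multi-platform validation panel with planted true/false statuses.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cnv import AMYLASE_REGIONS, RegionDepthProfile
from .demography import DemographicModel, expected_sfs
from .types import (
    MISSING,
    ArrayTruth,
    FunctionalCategory,
    GenotypeMatrix,
    RepeatClass,
    VariantSite,
)
from .validation import ValidationRecord


def _default_model() -> DemographicModel:
    # generic recent-expansion stand-in: 10x growth over the last 1,000
    # generations from an ancestral diploid size of 10,000
    return DemographicModel.expansion(10_000.0, 10.0, 1_000.0)


DEFAULT_CATEGORY_PROPORTIONS: dict[str, float] = {
    "intergenic": 0.55, "intron": 0.295, "utr3": 0.010, "utr5": 0.005,
    "synonymous": 0.005, "nonsynonymous": 0.007, "stop_gained": 0.0005,
    "mirna": 0.0005, "lincrna": 0.020, "other": 0.107,
}

#: per-category tilt of the spectrum toward singletons (selection surrogate);
#: 0 = neutral, larger = rarer.  Ordering mirrors increasing functional
#: constraint.
DEFAULT_RARE_SHIFT: dict[str, float] = {
    "intergenic": 0.0, "other": 0.0, "lincrna": 0.01, "intron": 0.02,
    "synonymous": 0.04, "utr3": 0.04, "utr5": 0.06, "nonsynonymous": 0.12,
    "mirna": 0.2, "stop_gained": 0.4,
}

DEFAULT_REPEAT_PROPORTIONS: dict[str, float] = {
    "none": 0.55, "Alu": 0.15, "ERVK": 0.01, "Low_complexity": 0.01,
    "Satellite": 0.003, "Simple_repeat": 0.01, "TcMar-Mariner": 0.01,
    "other": 0.257,
}

#: multiplier on the base genotype-error rate per repeat class; the
#: low-complexity classes are the ones the repeat filter should catch
DEFAULT_REPEAT_ERROR_MULTIPLIERS: dict[str, float] = {
    "none": 1.0, "other": 1.0, "Alu": 4.0, "ERVK": 4.0,
    "TcMar-Mariner": 4.0, "Low_complexity": 60.0, "Satellite": 60.0,
    "Simple_repeat": 60.0,
}

#: probability a site is in the reference catalogue, by sample MAF bin
DEFAULT_KNOWN_PROBABILITY: dict[str, float] = {
    "very_rare": 0.10, "rare": 0.35, "low": 0.75, "common": 0.95,
}

DEFAULT_COPY_UNIT_PROBS: dict[int, float] = {
    0: 0.02, 1: 0.08, 2: 0.22, 3: 0.33, 4: 0.22, 5: 0.09, 6: 0.04,
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic cohort.

    The cohort mirrors a deep whole-genome panel: 1,070 diploid samples at a
    mean depth of 32.4x.  ``n_sites`` is the simulated segregating-site
    count (a desk-scale slice of a genome's worth of variants).
    """

    model: DemographicModel = field(default_factory=_default_model)
    n_samples: int = 1070
    n_sites: int = 20_000
    mean_depth: float = 32.4
    depth_cv: float = 0.08           # between-sample spread of mean depth
    nb_dispersion: float = 8.0       # NB size parameter; larger = tighter
    base_error: float = 5e-5         # per-cell genotype error at normal depth
    low_depth_cutoff: int = 8
    low_depth_multiplier: float = 20.0
    high_depth_cutoff: int = 80
    high_depth_multiplier: float = 5.0
    repeat_error_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_ERROR_MULTIPLIERS))
    hwe_artifact_fraction: float = 0.005
    hwe_artifact_delta: float = 0.5  # per-cell forced-het probability
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS))
    rare_shift: dict = field(default_factory=lambda: dict(DEFAULT_RARE_SHIFT))
    repeat_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_PROPORTIONS))
    known_probability: dict = field(
        default_factory=lambda: dict(DEFAULT_KNOWN_PROBABILITY))
    array_truth_fraction: float = 0.30   # of sites, capped by eligibility
    array_common_maf: float = 0.05       # ascertainment floor for the array
    array_ascertained: bool = True       # False: truth at a uniform site subset
    sensitive_decoy_rate: float = 0.39   # decoy sites per true site
    copy_unit_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_COPY_UNIT_PROBS))
    cnv_base_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error", "hwe_artifact_fraction",
                     "hwe_artifact_delta", "array_truth_fraction",
                     "array_common_maf", "depth_cv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 1 or self.n_sites < 0:
            raise ValueError("n_samples must be >= 1 and n_sites >= 0")
        if abs(sum(self.category_proportions.values()) - 1.0) > 1e-6:
            raise ValueError("category proportions must sum to 1")
        if abs(sum(self.repeat_proportions.values()) - 1.0) > 1e-6:
            raise ValueError("repeat proportions must sum to 1")
        if abs(sum(self.copy_unit_probs.values()) - 1.0) > 1e-6:
            raise ValueError("copy-unit probabilities must sum to 1")
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth behind one simulated cohort."""

    minor_counts: np.ndarray          # drawn per-site minor copies
    true_genotype: np.ndarray         # pre-error genotype matrix
    error_mask: np.ndarray            # cells flipped by the error model
    artifact_cell_mask: np.ndarray    # cells forced het by the artifact
    artifact_sites: np.ndarray        # bool per site
    truth_sites: np.ndarray           # bool per site (array coverage)
    decoy_sites: list                 # site keys present only in the superset
    sample_mean_depth: np.ndarray


# ---------------------------------------------------------------------------
# genotype placement conditional on allele count


def _levene_haldane_het_pmf(n_minor: int, n: int) -> tuple[np.ndarray,
                                                           np.ndarray]:
    """Support and pmf of the heterozygote count given ``n_minor`` minor
    alleles among ``2n`` chromosomes under random pairing."""
    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    log_p = (
        hs * math.log(2.0)
        - gammaln((n_minor - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((2 * n - n_minor - hs) / 2 + 1)
    )
    log_p -= log_p.max()
    p = np.exp(log_p)
    return hs, p / p.sum()


def _draw_genotypes_for_count(n_minor: int, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Genotype vector for ``n`` diploids carrying exactly ``n_minor`` minor
    alleles, alleles paired uniformly at random (conditional HWE)."""
    hs, p = _levene_haldane_het_pmf(n_minor, n)
    n_het = int(rng.choice(hs, p=p))
    n_hom = (n_minor - n_het) // 2
    g = np.zeros(n, dtype=np.int8)
    idx = rng.choice(n, size=n_het + n_hom, replace=False)
    g[idx[:n_het]] = 1
    g[idx[n_het:]] = 2
    return g


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: Optional[SimConfig] = None, **overrides):
    """Generate (GenotypeMatrix, ArrayTruth, sensitive site set, SimTruth).

    Keyword overrides are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        from dataclasses import asdict
        merged = {**asdict(config), **overrides}
        merged["model"] = overrides.get("model", config.model)
        config = SimConfig(**merged)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, s = cfg.n_samples, cfg.n_sites
    two_n = 2 * n

    # class weights: folded expected SFS, tilted per category toward rarity
    eta = (expected_sfs(cfg.model, two_n).folded() if two_n >= 2
           else np.ones(1))
    freqs = np.arange(1, eta.size + 1) / two_n

    cats = list(cfg.category_proportions)
    cat_idx = rng.choice(len(cats), size=s,
                         p=np.array(list(cfg.category_proportions.values())))
    reps = list(cfg.repeat_proportions)
    rep_idx = rng.choice(len(reps), size=s,
                         p=np.array(list(cfg.repeat_proportions.values())))

    tilt_cache: dict[str, np.ndarray] = {}
    minor_counts = np.empty(s, dtype=np.int64)
    for ci, cat in enumerate(cats):
        sigma = float(cfg.rare_shift.get(cat, 0.0))
        if cat not in tilt_cache:
            w = eta * np.exp(-sigma * freqs / 0.001)
            tilt_cache[cat] = w / w.sum()
        rows = np.flatnonzero(cat_idx == ci)
        if rows.size:
            minor_counts[rows] = rng.choice(
                eta.size, size=rows.size, p=tilt_cache[cat]) + 1

    # true genotypes: exact allele placement conditional on the drawn count
    true_gt = np.zeros((s, n), dtype=np.int8)
    for i in range(s):
        true_gt[i] = _draw_genotypes_for_count(int(minor_counts[i]), n, rng)

    # sites and annotations
    sample_maf = minor_counts / two_n
    known_p = np.empty(s)
    for i in range(s):
        f = sample_maf[i]
        b = ("very_rare" if f <= 0.001 else "rare" if f <= 0.005
             else "low" if f <= 0.05 else "common")
        known_p[i] = cfg.known_probability[b]
    is_known = rng.random(s) < known_p
    bases = ("A", "C", "G", "T")
    positions = np.sort(rng.choice(10**8, size=s, replace=False)) + 1
    sites = []
    for i in range(s):
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        sites.append(VariantSite(
            chrom="1", pos=int(positions[i]), ref_allele=ref, alt_allele=alt,
            is_known=bool(is_known[i]),
            functional_category=FunctionalCategory(cats[cat_idx[i]]),
            repeat_class=RepeatClass(reps[rep_idx[i]]),
        ))

    # depths
    sample_mean = cfg.mean_depth * np.exp(
        rng.normal(0.0, cfg.depth_cv, size=n) - cfg.depth_cv**2 / 2)
    r = cfg.nb_dispersion
    depth = rng.negative_binomial(
        r, r / (r + sample_mean)[None, :], size=(s, n)).astype(np.int32)

    # artifact layer: excess-het calling artifact at a site fraction
    artifact_sites = rng.random(s) < cfg.hwe_artifact_fraction
    artifact_cells = np.zeros((s, n), dtype=bool)
    observed = true_gt.copy()
    if artifact_sites.any():
        forced = rng.random((s, n)) < cfg.hwe_artifact_delta
        artifact_cells = forced & artifact_sites[:, None]
        observed[artifact_cells] = 1

    # depth- and repeat-dependent random genotype errors
    rep_mult = np.array([cfg.repeat_error_multipliers.get(c, 1.0)
                         for c in reps])[rep_idx]
    p_err = np.full((s, n), cfg.base_error) * rep_mult[:, None]
    p_err[depth < cfg.low_depth_cutoff] *= cfg.low_depth_multiplier
    p_err[depth > cfg.high_depth_cutoff] *= cfg.high_depth_multiplier
    np.clip(p_err, 0.0, 1.0, out=p_err)
    error_mask = rng.random((s, n)) < p_err
    if error_mask.any():
        shift = rng.integers(1, 3, size=int(error_mask.sum()))
        observed[error_mask] = ((observed[error_mask] + shift) % 3).astype(np.int8)

    # depth-zero cells are uncallable
    observed[depth == 0] = MISSING

    matrix = GenotypeMatrix(sites, [f"S{i:04d}" for i in range(n)],
                            observed, depth)

    # array truth: error-free genotypes at ascertained sites
    if cfg.array_ascertained:
        eligible = (sample_maf >= cfg.array_common_maf) & ~artifact_sites
    else:
        eligible = np.ones(s, dtype=bool)
    target = int(round(cfg.array_truth_fraction * s))
    elig_idx = np.flatnonzero(eligible)
    if elig_idx.size > target:
        elig_idx = rng.choice(elig_idx, size=target, replace=False)
    truth_sites = np.zeros(s, dtype=bool)
    truth_sites[elig_idx] = True
    truth_gt = np.full((s, n), MISSING, dtype=np.int8)
    truth_gt[truth_sites] = true_gt[truth_sites]
    truth = ArrayTruth(truth_gt)

    # high-sensitive superset: every true site plus decoys
    sensitive = set(m.key for m in sites)
    n_decoys = int(round(cfg.sensitive_decoy_rate * s))
    used = set(int(p) for p in positions)
    decoys = []
    while len(decoys) < n_decoys:
        pos = int(rng.integers(1, 10**8 + 1))
        if pos in used:
            continue
        used.add(pos)
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        decoys.append(("1", pos, ref, alt))
    sensitive.update(decoys)

    sim_truth = SimTruth(
        minor_counts=minor_counts,
        true_genotype=true_gt,
        error_mask=error_mask,
        artifact_cell_mask=artifact_cells,
        artifact_sites=artifact_sites,
        truth_sites=truth_sites,
        decoy_sites=decoys,
        sample_mean_depth=sample_mean,
    )
    return matrix, truth, sensitive, sim_truth


# ---------------------------------------------------------------------------
# amylase tracks


def simulate_amylase_tracks(
    n_samples: int = 1070,
    copy_unit_probs: Optional[dict[int, float]] = None,
    base_depth: float = 30.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[RegionDepthProfile, np.ndarray]:
    """Amylase-locus depth tracks with planted copy units.

    Each sample carries ``n`` diploid copies of the (AMY1A, Region X, AMY1B)
    unit plus the fixed AMY1C pair, so its summed AMY1 diploid copy number
    is y = 2n + 2.  Expected mean depth of a region is (copies / 2) x the
    sample's base depth; with ``poisson_noise`` the total aligned bases per
    region are Poisson.

    Returns the profile and the planted per-sample unit counts n.
    """
    probs = copy_unit_probs or DEFAULT_COPY_UNIT_PROBS
    rng = np.random.default_rng(seed)
    units = np.array(sorted(probs))
    n_units = rng.choice(units, size=n_samples,
                         p=np.array([probs[u] for u in sorted(probs)]))
    region_len = {r.name: r.length for r in AMYLASE_REGIONS}

    def copies(region: str, nu: int) -> float:
        if region in ("AMY1A", "AMY1B", "RegionX"):
            return float(nu)
        return 2.0  # AMY1C, AMY2B, RegionY, RegionZ stay diploid

    rows = {}
    for region in region_len:
        lam = np.array([copies(region, int(nu)) / 2.0 * base_depth
                        for nu in n_units])
        if poisson_noise:
            total = rng.poisson(lam * region_len[region])
            rows[region] = total / region_len[region]
        else:
            rows[region] = lam
    profile = pd.DataFrame(rows, index=[f"S{i:04d}" for i in range(n_samples)])
    return RegionDepthProfile(profile), n_units


# ---------------------------------------------------------------------------
# validation panel


def simulate_validation_panel(
    n_sites: int = 322,
    true_fdr: float = 0.02,
    nocall_rate: float = 0.10,
    platform_error_rate: float = 0.0,
    known_fraction: float = 0.45,
    seed: int = 0,
) -> tuple[list[ValidationRecord], list[str]]:
    """Validation records with planted statuses.

    Each planted-true (or planted-false) site yields independent outcomes on
    the two platforms: no-call with probability ``nocall_rate``, otherwise
    the correct verdict flipped with probability ``platform_error_rate``.
    Sanger is run exactly when the two platforms return discordant verdicts
    and always reports the truth.
    """
    for name, v in (("true_fdr", true_fdr), ("nocall_rate", nocall_rate),
                    ("platform_error_rate", platform_error_rate),
                    ("known_fraction", known_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records, planted = [], []
    for i in range(n_sites):
        status = "false" if rng.random() < true_fdr else "true"
        planted.append(status)

        def assay() -> str:
            if rng.random() < nocall_rate:
                return "nocall"
            if rng.random() < platform_error_rate:
                return "false" if status == "true" else "true"
            return status

        ma, am = assay(), assay()
        sanger = "absent"
        if ma != "nocall" and am != "nocall" and ma != am:
            sanger = status
        records.append(ValidationRecord(
            site=("1", i + 1, "A", "G"), massarray=ma, amplicon=am,
            sanger=sanger, is_known=bool(rng.random() < known_fraction),
        ))
    return records, planted
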