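"""Core domain objects shared by every pipeline stage.

The central container is :class:`GenotypeMatrix`: a sites x samples array of
diploid genotype dosages (0 = hom ref, 1 = het, 2 = hom alt, ``MISSING``)
paired with a same-shaped array of per-cell read depths.  Every QC filter
consumes and returns this object.  Site-level metadata (functional category,
repeat class, known/novel flag) lives on :class:`VariantSite`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

#: Sentinel genotype code for a missing (not genotyped) cell.
MISSING: int = -1


class FunctionalCategory(str, Enum):
    INTERGENIC = "intergenic"
    INTRON = "intron"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    UTR5 = "utr5"
    UTR3 = "utr3"
    STOP_GAINED = "stop_gained"
    MIRNA = "mirna"
    LINCRNA = "lincrna"
    OTHER = "other"


class RepeatClass(str, Enum):
    NONE = "none"
    ALU = "Alu"
    ERVK = "ERVK"
    LOW_COMPLEXITY = "Low_complexity"
    SATELLITE = "Satellite"
    SIMPLE_REPEAT = "Simple_repeat"
    TCMAR_MARINER = "TcMar-Mariner"
    OTHER = "other"


class ChromatinState(str, Enum):
    """ENCODE-style seven-state chromatin segmentation labels."""

    TSS = "TSS"   # predicted promoter region including TSS
    PF = "PF"     # promoter-flanking
    E = "E"       # enhancer
    WE = "WE"     # weak enhancer / open chromatin
    CTCF = "CTCF"
    T = "T"       # transcribed
    R = "R"       # repressed / low activity


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site with its annotation labels.

    ``pos`` is 1-based.  ``is_known`` flags presence in the reference variant
    catalogue (dbSNP-equivalent).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    is_known: bool = False
    functional_category: FunctionalCategory = FunctionalCategory.OTHER
    repeat_class: RepeatClass = RepeatClass.NONE
    chromatin_state: Optional[ChromatinState] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


class GenotypeMatrix:
    """Sites x samples genotype dosages with per-cell read depth.

    Parameters
    ----------
    sites
        Ordered site metadata, one per row.
    samples
        Ordered sample identifiers, one per column.
    genotype
        int array, entries in {0, 1, 2, MISSING}.
    depth
        int array of non-negative read depths, same shape as ``genotype``.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        samples: Sequence[str],
        genotype: np.ndarray,
        depth: np.ndarray,
    ) -> None:
        genotype = np.asarray(genotype, dtype=np.int8)
        depth = np.asarray(depth, dtype=np.int32)
        n_sites, n_samples = len(sites), len(samples)
        if genotype.shape != (n_sites, n_samples):
            raise ValueError(
                f"genotype shape {genotype.shape} != ({n_sites}, {n_samples})"
            )
        if depth.shape != genotype.shape:
            raise ValueError("depth and genotype shapes differ")
        if (depth < 0).any():
            raise ValueError("depths must be non-negative")
        valid = np.isin(genotype, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")
        self.sites = list(sites)
        self.samples = list(samples)
        self.genotype = genotype
        self.depth = depth

    # ---- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_sites, self.n_samples)

    def site_keys(self) -> list[tuple[str, int, str, str]]:
        return [s.key for s in self.sites]

    def missing_mask(self) -> np.ndarray:
        return self.genotype == MISSING

    # ---- transforms ----------------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sites), list(self.samples),
            self.genotype.copy(), self.depth.copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_sites,):
            raise ValueError("site mask has wrong length")
        sites = [s for s, keep in zip(self.sites, mask) if keep]
        return GenotypeMatrix(sites, list(self.samples),
                              self.genotype[mask], self.depth[mask])

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s in keep_set]
        return GenotypeMatrix(
            list(self.sites), [self.samples[i] for i in idx],
            self.genotype[:, idx], self.depth[:, idx],
        )

    def with_genotype(self, genotype: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sites), list(self.samples),
                              genotype, self.depth)

    def annotate(self, updates: dict[tuple[str, int, str, str], dict]) -> None:
        """Replace site metadata fields in place, keyed by (chrom,pos,ref,alt)."""
        new_sites = []
        for s in self.sites:
            upd = updates.get(s.key)
            new_sites.append(replace(s, **upd) if upd else s)
        self.sites = new_sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and [s.key for s in self.sites] == [s.key for s in other.sites]
            and np.array_equal(self.genotype, other.genotype)
            and np.array_equal(self.depth, other.depth)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_sites} sites x {self.n_samples} samples)"


class ArrayTruth:
    """SNP-array truth genotypes at a subset of (site, sample) cells.

    Stored as a full-shaped int8 array aligned with a companion
    :class:`GenotypeMatrix`; cells without array data carry ``MISSING``.
    """

    def __init__(self, genotype: np.ndarray) -> None:
        genotype = np.asarray(genotype, dtype=np.int8)
        if not np.isin(genotype, (0, 1, 2, MISSING)).all():
            raise ValueError("truth codes must be 0/1/2 or MISSING")
        self.genotype = genotype

    @property
    def shape(self) -> tuple[int, int]:
        return self.genotype.shape

    def covered_mask(self) -> np.ndarray:
        return self.genotype != MISSING

    def subset_sites(self, mask: np.ndarray) -> "ArrayTruth":
        return ArrayTruth(self.genotype[np.asarray(mask, dtype=bool)])


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
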