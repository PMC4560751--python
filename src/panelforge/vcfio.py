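"""Readers and writers for the on-disk formats the pipeline touches.

Only GT and DP are interpreted from VCF FORMAT fields; everything else is
ignored (the downstream filters use genotype and depth only).  Internal
coordinates are 1-based inclusive; BED input is converted at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .types import (
    MISSING,
    ArrayTruth,
    FunctionalCategory,
    GenotypeMatrix,
    Region,
    RepeatClass,
    VariantSite,
)

logger = logging.getLogger(__name__)

_GT_CODE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
}


def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF with per-sample GT and DP into a GenotypeMatrix.

    ``./.`` maps to the missing code; an absent DP maps to depth 0.
    Multi-allelic records raise with an instruction to decompose first.
    """
    sites: list[VariantSite] = []
    gt_rows: list[list[int]] = []
    dp_rows: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        record_no = 0
        try:
            for rec in vcf:
                record_no += 1
                alts = rec.alts or ()
                if len(alts) != 1:
                    raise ValueError(
                        f"multi-allelic record at {rec.chrom}:{rec.pos} "
                        "(data line {0}): decompose to biallelic records "
                        "before loading".format(record_no)
                    )
                sites.append(
                    VariantSite(chrom=rec.chrom, pos=rec.pos,
                                ref_allele=rec.ref, alt_allele=alts[0])
                )
                gts, dps = [], []
                for s in samples:
                    call = rec.samples[s]
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        gts.append(MISSING)
                    else:
                        code = _GT_CODE.get(tuple(gt))
                        if code is None:
                            raise ValueError(
                                f"unsupported genotype {gt} at "
                                f"{rec.chrom}:{rec.pos} sample {s}"
                            )
                        gts.append(code)
                    dp = call.get("DP")
                    dps.append(0 if dp is None else int(dp))
                gt_rows.append(gts)
                dp_rows.append(dps)
        except ValueError:
            raise
        except Exception as exc:  # pysam parse failure
            raise ValueError(
                f"malformed VCF record at data line {record_no + 1} "
                f"of {path}: {exc}"
            ) from exc
    n = len(sites)
    genotype = (np.array(gt_rows, dtype=np.int8)
                if n else np.empty((0, len(samples)), dtype=np.int8))
    depth = (np.array(dp_rows, dtype=np.int32)
             if n else np.empty((0, len(samples)), dtype=np.int32))
    return GenotypeMatrix(sites, samples, genotype, depth)


def write_genotype_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT:DP; missing genotypes become ``./.``."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"),
                                     ("Description", "Read depth")])
    seen: dict[str, None] = {}
    for s in matrix.sites:
        seen.setdefault(s.chrom, None)
    for chrom in seen or {"1": None}:
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)
    code_gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for j, sample in enumerate(matrix.samples):
                rec.samples[sample]["GT"] = code_gt[int(matrix.genotype[i, j])]
                rec.samples[sample]["DP"] = int(matrix.depth[i, j])
            out.write(rec)


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read a 4-column BED (0-based half-open) into 1-based inclusive regions."""
    regions: list[Region] = []
    names: set[str] = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{line_no}: expected 4 BED columns")
        chrom, start_s, end_s, name = fields[:4]
        start, end = int(start_s), int(end_s)
        if start >= end:
            raise ValueError(
                f"{path}:{line_no}: empty or inverted interval {start}-{end}"
            )
        if name in names:
            raise ValueError(f"{path}:{line_no}: duplicate region name {name!r}")
        names.add(name)
        regions.append(Region(chrom=chrom, start=start + 1, end=end, name=name))
    return regions


# ---------------------------------------------------------------------------
# Annotation tables

ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "category",
                      "repeat_class", "known"]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df


def join_annotations(matrix: GenotypeMatrix, table: pd.DataFrame) -> None:
    """Attach annotation labels to matrix sites by (chrom, pos, ref, alt).

    Unmatched sites keep the defaults (other/none/known=False) with a logged
    warning; annotation is treated as given, never inferred.
    """
    lookup = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): r
        for r in table.itertuples(index=False)
    }
    updates: dict = {}
    n_unmatched = 0
    for site in matrix.sites:
        row = lookup.get(site.key)
        if row is None:
            n_unmatched += 1
            updates[site.key] = {
                "functional_category": FunctionalCategory.OTHER,
                "repeat_class": RepeatClass.NONE,
                "is_known": False,
            }
        else:
            updates[site.key] = {
                "functional_category": FunctionalCategory(str(row.category)),
                "repeat_class": RepeatClass(str(row.repeat_class)),
                "is_known": bool(row.known),
            }
    if n_unmatched:
        logger.warning(
            "%d of %d sites had no annotation row; defaulted to "
            "(other, none, known=False)", n_unmatched, matrix.n_sites,
        )
    matrix.annotate(updates)


def read_array_truth(path: str | Path, matrix: GenotypeMatrix) -> ArrayTruth:
    """Read a site x sample TSV of array genotypes aligned to ``matrix``.

    Rows keyed by chrom/pos/ref/alt; columns after the key are sample ids.
    Cells are 0/1/2 or ``.`` for missing.  Sites or samples absent from the
    companion matrix raise (every truth cell must map to a matrix cell).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    site_index = {k: i for i, k in enumerate(matrix.site_keys())}
    sample_index = {s: j for j, s in enumerate(matrix.samples)}
    truth = np.full(matrix.shape, MISSING, dtype=np.int8)
    for r in df.itertuples(index=False):
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        if key not in site_index:
            raise ValueError(f"truth site {key} not present in genotype matrix")
        i = site_index[key]
        for c in sample_cols:
            if c not in sample_index:
                raise ValueError(f"truth sample {c!r} not present in matrix")
            val = getattr(r, c)
            if str(val) != ".":
                truth[i, sample_index[c]] = int(val)
    return ArrayTruth(truth)


def write_array_truth(truth: ArrayTruth, matrix: GenotypeMatrix,
                      path: str | Path) -> None:
    covered = truth.covered_mask().any(axis=1)
    keys = matrix.site_keys()
    rows = []
    for i in np.flatnonzero(covered):
        row = dict(zip(("chrom", "pos", "ref", "alt"), keys[i]))
        for j, s in enumerate(matrix.samples):
            g = int(truth.genotype[i, j])
            row[s] = "." if g == MISSING else g
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_depths(path: str | Path) -> pd.DataFrame:
    """Read a per-sample per-region mean-depth TSV (first column ``sample``)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("region depth table needs a 'sample' column")
    return df.set_index("sample")
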