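"""Multi-platform validation bookkeeping and FDR estimation.

Candidate variants are re-assayed on two orthogonal platforms
(mass-spectrometry genotyping and amplicon sequencing); discordant verdicts
are arbitrated by Sanger sequencing, whose result is taken as truth.  A site
whose contributing platform yields a no-call is itself a no-call.  The FDR
is the number of false sites over true plus false (no-calls excluded), with
a 95% Clopper-Pearson interval on the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .sfs import clopper_pearson

PLATFORM_OUTCOMES = ("true", "false", "nocall", "absent")
SANGER_OUTCOMES = ("true", "false", "absent")


@dataclass(frozen=True)
class ValidationRecord:
    """Per-site outcomes: two primary platforms plus optional Sanger."""

    site: tuple
    massarray: str = "absent"
    amplicon: str = "absent"
    sanger: str = "absent"
    is_known: bool = False

    def __post_init__(self) -> None:
        if self.massarray not in PLATFORM_OUTCOMES:
            raise ValueError(f"bad massarray outcome {self.massarray!r}")
        if self.amplicon not in PLATFORM_OUTCOMES:
            raise ValueError(f"bad amplicon outcome {self.amplicon!r}")
        if self.sanger not in SANGER_OUTCOMES:
            raise ValueError(f"bad sanger outcome {self.sanger!r}")
        if (self.massarray == "absent" and self.amplicon == "absent"
                and self.sanger == "absent"):
            raise ValueError("at least one platform must be non-absent")


def resolve_status(record: ValidationRecord,
                   sanger_rescues_nocall: bool = False) -> str:
    """Resolve a record to "true", "false" or "nocall".

    Rules: a no-call on any contributing platform makes the site a no-call
    (with ``sanger_rescues_nocall=True``, as in the indel protocol, a Sanger
    verdict overrides the no-call); agreeing platforms decide directly;
    disagreeing platforms are arbitrated by Sanger, and an unresolved
    disagreement is a no-call.  Sanger alone decides when it is the only
    assay present.
    """
    votes = [v for v in (record.massarray, record.amplicon) if v != "absent"]
    sanger = record.sanger if record.sanger != "absent" else None
    if not votes:
        return sanger if sanger is not None else "nocall"
    if "nocall" in votes:
        if sanger_rescues_nocall and sanger is not None:
            return sanger
        return "nocall"
    if len(set(votes)) == 1:
        return votes[0]
    # platforms disagree
    if sanger is not None:
        return sanger
    return "nocall"


@dataclass(frozen=True)
class FdrEstimate:
    n_true: int
    n_false: int
    n_nocall: int
    fdr: float
    ci_low: float
    ci_high: float


def fdr_from_counts(n_true: int, n_false: int,
                    n_nocall: int = 0) -> FdrEstimate:
    """FDR = false / (true + false); no-calls excluded from the denominator."""
    if n_true < 0 or n_false < 0 or n_nocall < 0:
        raise ValueError("counts must be non-negative")
    denom = n_true + n_false
    if denom < 1:
        raise ValueError("no resolved (true or false) sites: FDR undefined")
    lo, hi = clopper_pearson(n_false, denom)
    return FdrEstimate(n_true=n_true, n_false=n_false, n_nocall=n_nocall,
                       fdr=n_false / denom, ci_low=lo, ci_high=hi)


def fdr_estimate(records: Sequence[ValidationRecord],
                 sanger_rescues_nocall: bool = False) -> FdrEstimate:
    """Resolve every record and estimate the FDR over resolved sites."""
    n_true = n_false = n_nocall = 0
    for rec in records:
        status = resolve_status(rec, sanger_rescues_nocall)
        if status == "true":
            n_true += 1
        elif status == "false":
            n_false += 1
        else:
            n_nocall += 1
    return fdr_from_counts(n_true, n_false, n_nocall)


def combined_fdr(fdr_known: float, fdr_novel: float, f_known: float) -> float:
    """Overall per-site FDR as the known/novel mixture:
    fdr_known * f_known + fdr_novel * (1 - f_known)."""
    for name, v in (("fdr_known", fdr_known), ("fdr_novel", fdr_novel),
                    ("f_known", f_known)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return fdr_known * f_known + fdr_novel * (1.0 - f_known)


def novelty_rate(n_known: int, n_novel: int) -> float:
    """Fraction of calls absent from the reference catalogue."""
    if n_known < 0 or n_novel < 0:
        raise ValueError("counts must be non-negative")
    total = n_known + n_novel
    if total < 1:
        raise ValueError("need at least one classified call")
    return n_novel / total


def novelty_rate_percent(n_known: int, n_novel: int) -> float:
    """Novelty rate as a percentage, rounded to two decimals."""
    return round(100.0 * novelty_rate(n_known, n_novel), 2)
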