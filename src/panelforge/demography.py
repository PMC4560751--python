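"""Expected site frequency spectra under piecewise population histories.

The expected unfolded SFS of a sample of ``2n`` chromosomes under a
piecewise-constant effective-size history N(t) is computed from coalescent
branch-length expectations with the Polanski-Kingman formulation:

    E[xi_b]  =  sum_{j=2}^{2n}  W_{b,j} * c_j ,
    c_j      =  integral_0^inf exp(-C(j,2) * Lambda(t)) dt ,
    Lambda(t) = integral_0^t ds / (2 N(s)) ,

where the weights W obey a three-term recursion in j that is numerically
stable into the tens of thousands of chromosomes, and the c_j integrals have
a closed form on each constant piece.  For a constant-size population this
reduces exactly to Watterson's classic xi_b proportional to 1/b.

A recent exponential-growth epoch is discretized into at most 50
piecewise-constant steps before the integrals are taken.

Only relative spectra matter downstream (mutation rate enters as an overall
factor), so spectra are reported normalized to sum to one unless requested
otherwise.

The module also provides the two quantities a panel designer asks of such a
model: the probability that a variant of population minor-allele frequency f
is seen at least once in a sample of given size, and that probability
averaged over the model's frequency distribution above a minimum MAF (the
variant discovery rate), plus a composite-likelihood fitter for the folded
observed spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

#: maximum piecewise-constant steps used to discretize a growth epoch
GROWTH_STEPS = 50


@dataclass(frozen=True)
class Epoch:
    """One constant-size epoch, going backward in time.

    ``duration`` is in generations (``None`` or inf for the final, oldest
    epoch).  ``size`` is the diploid effective size at the epoch's most
    recent end.
    """

    duration: Optional[float]
    size: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("effective size must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise effective-size history, most recent epoch first.

    ``growth_rate`` (per generation) applies to the most recent epoch only:
    backward in time its size decays as ``size * exp(-growth_rate * t)``,
    i.e. a forward-time exponential expansion ending at ``size`` today.
    """

    epochs: tuple[Epoch, ...]
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("need at least one epoch")
        for e in self.epochs[:-1]:
            if e.duration is None or math.isinf(e.duration):
                raise ValueError("only the final epoch may be unbounded")
        last = self.epochs[-1]
        if last.duration is not None and not math.isinf(last.duration):
            raise ValueError("final epoch must be unbounded")
        if self.growth_rate != 0.0 and (
            self.epochs[0].duration is None or len(self.epochs) < 2
        ):
            raise ValueError("growth requires a bounded most recent epoch")

    # -- constructors --------------------------------------------------------

    @classmethod
    def constant(cls, size: float) -> "DemographicModel":
        return cls(epochs=(Epoch(None, size),))

    @classmethod
    def expansion(cls, ancestral_size: float, fold: float,
                  duration: float) -> "DemographicModel":
        """Exponential expansion to ``fold`` x ancestral size over the last
        ``duration`` generations."""
        if fold <= 0:
            raise ValueError("fold must be positive")
        rate = math.log(fold) / duration
        return cls(
            epochs=(Epoch(duration, ancestral_size * fold),
                    Epoch(None, ancestral_size)),
            growth_rate=rate,
        )

    # -- piecewise-constant view --------------------------------------------

    def as_piecewise(self) -> list[tuple[float, float]]:
        """Discretize to [(duration_gen, size), ...]; growth split into steps."""
        pieces: list[tuple[float, float]] = []
        first = True
        for epoch in self.epochs:
            dur = math.inf if epoch.duration is None else float(epoch.duration)
            if first and self.growth_rate != 0.0:
                steps = GROWTH_STEPS
                dt = dur / steps
                for k in range(steps):
                    t_mid = (k + 0.5) * dt
                    pieces.append(
                        (dt, epoch.size * math.exp(-self.growth_rate * t_mid))
                    )
            else:
                pieces.append((dur, epoch.size))
            first = False
        return pieces

    def to_dict(self) -> dict:
        return {
            "epochs": [{"duration_gen": e.duration, "size": e.size}
                       for e in self.epochs],
            "growth_rate": self.growth_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            epochs=tuple(Epoch(e["duration_gen"], e["size"])
                         for e in d["epochs"]),
            growth_rate=d.get("growth_rate", 0.0),
        )


@dataclass
class ExpectedSFS:
    """Expected unfolded SFS xi_i for i = 1..2n-1 chromosomes."""

    two_n: int
    xi: np.ndarray
    normalized: bool = True

    def folded(self) -> np.ndarray:
        """Minor-allele spectrum eta_j, j = 1..floor(2n/2)."""
        n = self.two_n
        half = n // 2
        eta = np.zeros(half)
        for j in range(1, half + 1):
            if j == n - j:
                eta[j - 1] = self.xi[j - 1]
            else:
                eta[j - 1] = self.xi[j - 1] + self.xi[n - j - 1]
        return eta


def _pk_coalescent_costs(pieces: Sequence[tuple[float, float]],
                         two_n: int) -> np.ndarray:
    """c_j = integral exp(-C(j,2) Lambda(t)) dt for j = 2..2n (closed form)."""
    j = np.arange(2, two_n + 1, dtype=float)
    a = j * (j - 1) / 2.0
    c = np.zeros_like(a)
    lam = 0.0
    for dur, size in pieces:
        if math.isinf(dur):
            c += np.exp(-a * lam) * 2.0 * size / a
            break
        d_lam = dur / (2.0 * size)
        c += np.exp(-a * lam) * -np.expm1(-a * d_lam) * 2.0 * size / a
        lam += d_lam
    return c


def expected_sfs(model: DemographicModel, two_n: int,
                 normalize: bool = True) -> ExpectedSFS:
    """Expected unfolded SFS for a sample of ``two_n`` chromosomes.

    Constant-size histories give exactly xi_i proportional to 1/i.
    Results are memoized per (model, two_n); treat the returned arrays as
    read-only.
    """
    xi = _expected_sfs_cached(model, two_n)
    if normalize:
        return ExpectedSFS(two_n=two_n, xi=xi / xi.sum(), normalized=True)
    return ExpectedSFS(two_n=two_n, xi=xi.copy(), normalized=False)


@lru_cache(maxsize=64)
def _expected_sfs_cached(model: DemographicModel, two_n: int) -> np.ndarray:
    if two_n < 2:
        raise ValueError("need at least two chromosomes")
    c = _pk_coalescent_costs(model.as_piecewise(), two_n)
    n = two_n
    b = np.arange(1, n, dtype=float)
    xi = np.zeros(n - 1)
    w_prev = np.full(n - 1, 6.0 / (n + 1))                       # j = 2
    xi += w_prev * c[0]
    if n >= 3:
        w_cur = 30.0 * (n - 2 * b) / ((n + 1) * (n + 2))         # j = 3
        xi += w_cur * c[1]
        for jj in range(2, n - 1):                               # makes j = jj+2
            w_next = (
                -(1 + jj) * (3 + 2 * jj) * (n - jj)
                / (jj * (2 * jj - 1) * (n + jj + 1)) * w_prev
                + (3 + 2 * jj) * (n - 2 * b) / (jj * (n + jj + 1)) * w_cur
            )
            xi += w_next * c[jj]
            w_prev, w_cur = w_cur, w_next
    return np.clip(xi, 0.0, None)  # guard vanishing negatives


# ---------------------------------------------------------------------------
# Discovery


def discovery_probability(f: float, n_samples: int,
                          min_copies: int = 1) -> float:
    """Probability that a minor allele of population frequency ``f`` shows up
    at least ``min_copies`` times among ``2 * n_samples`` chromosomes.

    For the default single-copy definition this is
    ``1 - (1-f)^{2n} - f^{2n}`` (the second term, the chance the *major*
    allele is the one unseen, is negligible but kept for exactness).
    """
    if not (0.0 < f <= 0.5):
        raise ValueError(f"population MAF must be in (0, 0.5], got {f}")
    two_n = 2 * n_samples
    if min_copies == 1:
        return 1.0 - (1.0 - f) ** two_n - f ** two_n
    # >= min_copies of the minor allele; subtract the all-minor corner too
    return float(binom.sf(min_copies - 1, two_n, f) - f ** two_n)


def discovery_rate(model: DemographicModel, n_samples: int, min_maf: float,
                   two_n_ref: int = 20_000, min_copies: int = 1) -> float:
    """Expected fraction of population variants with MAF >= ``min_maf``
    discovered in a sample of ``n_samples`` diploids.

    The population MAF distribution phi(f) is the folded expected SFS of a
    large reference sample of ``two_n_ref`` chromosomes under ``model``; the
    rate is the phi-weighted mean of :func:`discovery_probability` over the
    tail f >= min_maf, and is invariant to the normalization of phi.
    """
    if not (0.0 < min_maf <= 0.5):
        raise ValueError("min_maf must be in (0, 0.5]")
    phi = expected_sfs(model, two_n_ref).folded()
    freqs = np.arange(1, phi.size + 1) / two_n_ref
    tail = freqs >= min_maf
    if not tail.any():
        raise ValueError(
            f"no frequency class at or above min_maf={min_maf} "
            f"with two_n_ref={two_n_ref}"
        )
    probs = np.array(
        [discovery_probability(f, n_samples, min_copies) for f in freqs[tail]]
    )
    w = phi[tail]
    return float(np.sum(w * probs) / np.sum(w))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class SfsFit:
    model: DemographicModel
    params: dict
    log_likelihood: float
    converged: bool


_DEFAULT_ANCESTRAL = 10_000.0


def _expansion_model(fold: float, tau: float,
                     ancestral: float = _DEFAULT_ANCESTRAL) -> DemographicModel:
    """Expansion family: ``tau`` is the growth duration in units of
    2 * ancestral size generations (the natural coalescent scale)."""
    return DemographicModel.expansion(ancestral, fold, tau * 2.0 * ancestral)


def fit_sfs(
    observed_counts: np.ndarray,
    two_n: int,
    family: str = "expansion",
    fixed: Optional[dict] = None,
    starts: Optional[Sequence[tuple[float, float]]] = None,
) -> SfsFit:
    """Fit a demographic model to a folded observed SFS by maximizing the
    multinomial composite log-likelihood of class proportions.

    Parameters
    ----------
    observed_counts
        Folded class counts for j = 1..floor(two_n/2) (fractional allowed).
    two_n
        Chromosomes in the observed spectrum.
    family
        Only ``"expansion"`` (ancestral constant size plus a single recent
        exponential expansion; free shape parameters ``fold`` and ``tau``,
        the growth duration on the 2N_anc-generation scale).  The overall
        size scale is not identifiable from spectrum proportions and is
        pinned internally.
    fixed
        Optional {"fold": x} and/or {"tau": x} to pin a parameter.

    Derivative-free (Nelder-Mead) optimization from a multi-start grid.
    """
    obs = np.asarray(observed_counts, dtype=float)
    if obs.size < 3:
        raise ValueError("observed SFS needs at least 3 classes")
    if obs.size != two_n // 2:
        raise ValueError(
            f"expected {two_n // 2} folded classes for 2n={two_n}, "
            f"got {obs.size}"
        )
    if family != "expansion":
        raise ValueError(f"unknown model family {family!r}")
    fixed = dict(fixed or {})

    def loglik(fold: float, tau: float) -> float:
        eta = expected_sfs(_expansion_model(fold, tau), two_n).folded()
        p = eta / eta.sum()
        return float(np.sum(obs * np.log(np.clip(p, 1e-300, None))))

    free = [name for name in ("fold", "tau") if name not in fixed]

    def unpack(x: np.ndarray) -> dict:
        params = dict(fixed)
        for name, v in zip(free, x):
            params[name] = math.exp(v)
        return params

    def objective(x: np.ndarray) -> float:
        p = unpack(x)
        if p["fold"] > 1e4 or p["tau"] > 50 or p["tau"] < 1e-6:
            return 1e18
        return -loglik(p["fold"], p["tau"])

    if not free:
        params = dict(fixed)
        return SfsFit(_expansion_model(**params), params,
                      loglik(**params), True)

    if starts is None:
        grid_fold = [1.0, 3.0, 10.0, 50.0]
        grid_tau = [0.02, 0.1, 0.5]
        starts = [(f, t) for f in grid_fold for t in grid_tau]

    best = None
    any_converged = False
    for fold0, tau0 in starts:
        x0 = np.array([math.log({"fold": fold0, "tau": tau0}[n])
                       for n in free])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7,
                                "maxiter": 400})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    fit = SfsFit(
        model=_expansion_model(params["fold"], params["tau"]),
        params=params,
        log_likelihood=-float(best.fun),
        converged=any_converged,
    )
    if not any_converged:
        raise RuntimeError(
            f"SFS fit did not converge from any start; best so far: {fit}"
        )
    return fit
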