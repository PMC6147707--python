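"""Per-species Poisson occurrence models along the canopy-cover gradient.

For each species j, the stem count in a plot with cover F is modelled as
Poisson with rate lambda(j, F) = M_j + C_j * F (identity link, the default) or
lambda = exp(M_j + C_j * F) (log link).  The occurrence probability is then
P(count > 0) = 1 - exp(-lambda), and the response statistic

    Omega_j = ln[ P(j, F=F_low) / P(j, F=F_high) ],   defaults F_low=5, F_high=75 (%),

is positive for species favoured by open canopies and negative for
forest-affiliated species.  A cover model is "informative" when its AICc beats
the intercept-only model by more than 10.  Uncertainty in Omega comes from a
nonparametric bootstrap: plots are resampled with replacement, the model
refitted, and the 95% CI taken at the ranked positions floor((B+1)*0.025) and
ceil((B+1)*0.975) — ranks 25 and 976 of B = 1000.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _poisson
from ._poisson import RATE_FLOOR, check_link
from .landscape import species_columns

logger = logging.getLogger(__name__)

DEFAULT_F_LOW = 5.0
DEFAULT_F_HIGH = 75.0
DEFAULT_MIN_OCCUPIED = 25
DEFAULT_N_BOOT = 1000
INFORMATIVE_DELTA_AICC = 10.0

#: cross-scale ordering used for AICc tie-breaks (most local wins)
SCALE_ORDER = ("local", "1p6", "3p2", "6p4")


class DegenerateFitError(ValueError):
    """Raised when a fit yields occurrence probabilities of exactly zero."""


@dataclass
class SpeciesFit:
    """ML fit of the two-parameter Poisson occurrence model for one species."""

    species: str
    scale: str
    M: float
    C: float
    link: str
    loglik: float
    n_plots: int
    aicc: float
    aicc_intercept: float
    delta_aicc: float
    informative: bool
    cov: np.ndarray = field(repr=False, default=None)  # (2,2) asymptotic cov of (M, C)

    def rate(self, F):
        return _poisson.rate(self.M, self.C, np.asarray(F, dtype=float), self.link)


@dataclass
class OmegaEstimate:
    species: str
    scale: str
    omega: float
    ci_low: float
    ci_high: float
    n_boot: int
    response_class: str
    f_low: float = DEFAULT_F_LOW
    f_high: float = DEFAULT_F_HIGH


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_species(
    plots: pd.DataFrame,
    tree_tips: Iterable[str],
    min_occupied: int = DEFAULT_MIN_OCCUPIED,
) -> list[str]:
    """Species occupying >= ``min_occupied`` plots AND present among tree tips.

    Occupancy counts plots with a positive stem count; the default threshold
    of 25 plots guards against low statistical power.
    """
    tips = set(tree_tips)
    kept = []
    for sp in species_columns(plots):
        n_occ = int((plots[sp].to_numpy() > 0).sum())
        if n_occ >= min_occupied and sp in tips:
            kept.append(sp)
    if not kept:
        raise ValueError(
            f"no species passed selection (min_occupied={min_occupied}, "
            f"{len(tips)} tree tips)"
        )
    return kept


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError(
            "counts must be integers; per-hectare densities must be rounded "
            "explicitly by the caller (round-counts policy), never silently"
        )
    return counts.astype(float)


def fit_poisson(
    counts: np.ndarray,
    F: np.ndarray,
    link: str = "identity",
    species: str = "",
    scale: str = "local",
) -> SpeciesFit:
    """ML fit of (M, C) plus the intercept-only comparison on the same data.

    The identity link is fitted under the positivity constraint (rate clipped
    at 1e-10 during the search); ``loglik`` is the exact Poisson
    log-likelihood at the optimum.  ``delta_aicc`` is AICc(intercept) minus
    AICc(cover model): values above 10 mark the cover model as informative.
    """
    check_link(link)
    counts = _validate_counts(counts)
    F = np.asarray(F, dtype=float)
    if counts.shape != F.shape:
        raise ValueError("counts and F must have the same length")
    if np.any(F < 0) or np.any(F > 100):
        raise ValueError("cover F outside [0, 100]")
    n = counts.size
    if counts.sum() == 0:
        raise ValueError(f"all counts zero for species {species!r}: model undefined")

    M, C, ll, _converged = _poisson.fit_single(counts, F, link)

    # intercept-only ML rate is the sample mean under either link
    mean = counts.mean()
    from scipy.special import gammaln

    ll0 = float(np.sum(counts * np.log(mean) - mean - gammaln(counts + 1.0)))
    a_full = aicc(ll, 2, n)
    a_int = aicc(ll0, 1, n)
    delta = a_int - a_full

    try:
        cov = np.linalg.inv(_poisson.fisher_information(M, C, F, link))
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)

    return SpeciesFit(
        species=species,
        scale=str(scale),
        M=M,
        C=C,
        link=link,
        loglik=ll,
        n_plots=n,
        aicc=a_full,
        aicc_intercept=a_int,
        delta_aicc=delta,
        informative=bool(delta > INFORMATIVE_DELTA_AICC),
        cov=cov,
    )


def occurrence_probability(fit: SpeciesFit, F) -> np.ndarray | float:
    """P(count > 0) = 1 - exp(-lambda(F)), clipping non-positive rates.

    Under the identity link a negative fitted rate is clipped to 1e-10 with a
    warning; the probability lies in [0, 1).
    """
    lam = _poisson.rate(fit.M, fit.C, np.asarray(F, dtype=float), fit.link)
    if fit.link == "identity":
        eta = fit.M + fit.C * np.asarray(F, dtype=float)
        if np.any(eta <= 0):
            logger.warning(
                "identity-link rate <= 0 at some F for species %r; clipped to %g",
                fit.species, RATE_FLOOR,
            )
    p = -np.expm1(-lam)
    return float(p) if np.isscalar(F) or np.ndim(F) == 0 else p


def omega(
    fit: SpeciesFit,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
) -> float:
    """Log-ratio of occurrence probabilities at low vs high cover."""
    if not f_low < f_high:
        raise ValueError("f_low must be < f_high")
    p_low = occurrence_probability(fit, f_low)
    p_high = occurrence_probability(fit, f_high)
    if p_low <= 0.0 or p_high <= 0.0:
        raise DegenerateFitError(
            f"occurrence probability underflowed to zero for {fit.species!r}; "
            "Omega undefined"
        )
    return math.log(p_low / p_high)


def ci_rank_bounds(n_boot: int) -> tuple[int, int]:
    """1-based ranks of the percentile 95% CI bounds: (25, 976) for B=1000."""
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    lo = math.floor((n_boot + 1) * 0.025)
    hi = math.ceil((n_boot + 1) * 0.975)
    return max(lo, 1), min(hi, n_boot)


def classify_response(ci_low: float, ci_high: float) -> str:
    """negative / positive when the CI lies strictly below / above zero.

    A bound exactly at zero counts as including zero, hence neutral.
    """
    if ci_high < 0.0:
        return "negative"
    if ci_low > 0.0:
        return "positive"
    return "neutral"


def species_seed(master_seed: int, species: str) -> list[int]:
    """Seed material derived from the species name by a stable hash.

    Keeps per-species bootstrap streams invariant to species ordering.
    """
    return [int(master_seed), zlib.crc32(species.encode("utf8"))]


def _omega_from_params(M, C, link, f_low, f_high):
    """Vectorised Omega over parameter arrays; NaN where degenerate."""
    lam_lo = _poisson.rate(M, C, f_low, link)
    lam_hi = _poisson.rate(M, C, f_high, link)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_lo = -np.expm1(-lam_lo)
        p_hi = -np.expm1(-lam_hi)
        out = np.log(p_lo) - np.log(p_hi)
    out = np.where((p_lo > 0) & (p_hi > 0), out, np.nan)
    return out


def bootstrap_omega(
    counts: np.ndarray,
    F: np.ndarray,
    link: str = "identity",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence | Sequence[int] | None = None,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
    species: str = "",
    scale: str = "local",
    max_fail_frac: float = 0.2,
) -> OmegaEstimate:
    """Point Omega with a 95% percentile bootstrap CI.

    Draws ``n_boot`` plot-level resamples of the same size as the original
    data, refits the Poisson model on each and recomputes Omega; replicates
    whose refit fails are redrawn (logged) so the replicate count stays fixed.
    More than ``max_fail_frac`` cumulative failures aborts with the species
    named.
    """
    counts_f = _validate_counts(counts)
    F = np.asarray(F, dtype=float)
    n = counts_f.size
    fit = fit_poisson(counts, F, link, species=species, scale=scale)
    point = omega(fit, f_low, f_high)

    rng = np.random.default_rng(seed)
    omegas = np.full(n_boot, np.nan)
    pending = np.arange(n_boot)
    failures = 0
    while pending.size:
        idx = rng.integers(0, n, size=(pending.size, n))
        Yb = counts_f[idx]
        Fb = F[idx]
        res = _poisson.fit_batch(Yb, Fb, link)
        om = _omega_from_params(res.M, res.C, link, f_low, f_high)
        good = res.ok & np.isfinite(om)
        # robust single-dataset refit before declaring a replicate failed
        for r in np.flatnonzero(~good):
            if Yb[r].sum() == 0:
                continue
            Mr, Cr, _, ok_r = _poisson.fit_single(Yb[r], Fb[r], link)
            om_r = _omega_from_params(Mr, Cr, link, f_low, f_high)
            if ok_r and np.isfinite(om_r):
                om[r] = om_r
                good[r] = True
        omegas[pending[good]] = om[good]
        n_bad = int((~good).sum())
        if n_bad:
            failures += n_bad
            logger.info(
                "species %r: redrawing %d failed bootstrap replicates", species, n_bad
            )
            if failures > max_fail_frac * n_boot:
                raise RuntimeError(
                    f"bootstrap for species {species!r} at scale {scale}: "
                    f"{failures} failed replicates exceed "
                    f"{max_fail_frac:.0%} of n_boot={n_boot}"
                )
        pending = pending[~good]

    ranked = np.sort(omegas)
    lo, hi = ci_rank_bounds(n_boot)
    ci_low, ci_high = float(ranked[lo - 1]), float(ranked[hi - 1])
    return OmegaEstimate(
        species=species,
        scale=str(scale),
        omega=point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        response_class=classify_response(ci_low, ci_high),
        f_low=f_low,
        f_high=f_high,
    )


def best_scale(fits: Sequence[SpeciesFit]) -> str | None:
    """Scale with minimum AICc among one species' informative fits.

    Ties break toward the more local scale.  Returns ``None`` when no scale
    is informative (the species is unexplained by cover).
    """
    informative = [f for f in fits if f.informative]
    if not informative:
        return None
    def key(f: SpeciesFit):
        order = SCALE_ORDER.index(f.scale) if f.scale in SCALE_ORDER else len(SCALE_ORDER)
        return (f.aicc, order)
    return min(informative, key=key).scale


def best_scale_summary(fits_by_species: dict[str, Sequence[SpeciesFit]]) -> pd.DataFrame:
    """Per-species best scale plus the fraction of species per scale."""
    rows = []
    for sp, fits in fits_by_species.items():
        rows.append({"species": sp, "best_scale": best_scale(fits)})
    df = pd.DataFrame(rows)
    return df
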