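"""Batched maximum-likelihood fitting of two-parameter Poisson rate models.

The occurrence model ties the Poisson rate to canopy cover F either through an
identity link, lambda = M + C*F (rate clipped below at ``RATE_FLOOR`` so the
log-likelihood stays defined during the search), or a log link,
lambda = exp(M + C*F).  The bootstrap refits the same model hundreds of times
per species, so the solver is a damped Newton iteration vectorised over a batch
of datasets sharing a common length; rows that fail to converge fall back to a
derivative-free simplex search on the identical objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

RATE_FLOOR = 1e-10

_LINKS = ("identity", "log")


def check_link(link: str) -> str:
    if link not in _LINKS:
        raise ValueError(f"link must be one of {_LINKS}, got {link!r}")
    return link


def rate(M, C, F, link: str):
    """Poisson rate lambda(F) for parameters (M, C); arrays broadcast."""
    eta = np.asarray(M) + np.asarray(C) * np.asarray(F)
    if link == "log":
        return np.exp(np.clip(eta, -700.0, 700.0))
    return np.maximum(eta, RATE_FLOOR)


def _core_loglik(M, C, Y, F, link: str):
    """Poisson log-likelihood without the parameter-free log(y!) term."""
    lam = rate(np.atleast_1d(M)[:, None], np.atleast_1d(C)[:, None], F, link)
    return (np.atleast_2d(Y) * np.log(lam) - lam).sum(axis=1)


def poisson_loglik(M, C, Y, F, link: str):
    """Exact Poisson log-likelihood, including the log(y!) term.

    ``Y`` of shape (B, n) against batch parameter vectors ``M``, ``C`` of
    shape (B,); ``F`` of shape (n,) or (B, n).
    """
    Y = np.atleast_2d(Y)
    return _core_loglik(M, C, Y, F, link) - gammaln(Y + 1.0).sum(axis=1)


@dataclass
class BatchFit:
    M: np.ndarray
    C: np.ndarray
    loglik: np.ndarray
    ok: np.ndarray  # converged to a finite optimum


def _grad_hess(M, C, Y, F, link):
    """Per-row gradient and (negated) Hessian blocks of the log-likelihood."""
    eta = M[:, None] + C[:, None] * F
    if link == "log":
        lam = np.exp(np.clip(eta, -700.0, 700.0))
        r = Y - lam
        w = lam
    else:
        lam = np.maximum(eta, RATE_FLOOR)
        active = eta > RATE_FLOOR  # clipped plots contribute no curvature
        r = np.where(active, Y / lam - 1.0, 0.0)
        w = np.where(active, Y / (lam * lam), 0.0)
    g1 = r.sum(axis=1)
    g2 = (r * F).sum(axis=1)
    h11 = w.sum(axis=1)
    h12 = (w * F).sum(axis=1)
    h22 = (w * F * F).sum(axis=1)
    return g1, g2, h11, h12, h22


def fit_batch(
    Y: np.ndarray,
    F: np.ndarray,
    link: str = "identity",
    max_iter: int = 80,
    grad_tol: float = 1e-7,
) -> BatchFit:
    """Fit (M, C) by ML for each row of ``Y`` against covariate rows ``F``.

    Starts from the intercept-only solution (sample mean), takes damped Newton
    steps with per-row backtracking, and flags rows that do not reach a finite
    stationary point.
    """
    check_link(link)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = np.broadcast_to(F, Y.shape)
    B = Y.shape[0]
    log_fact = gammaln(Y + 1.0).sum(axis=1)  # parameter-free, computed once

    mean = Y.mean(axis=1)
    if link == "log":
        M = np.log(np.maximum(mean, RATE_FLOOR))
    else:
        M = np.maximum(mean, RATE_FLOOR)
    C = np.zeros(B)
    ll = _core_loglik(M, C, Y, F, link)
    ok = np.isfinite(ll) & (mean > 0)

    gscale = np.maximum(1.0, np.abs(Y).sum(axis=1))
    stalled = np.zeros(B, dtype=bool)  # line search cannot improve further
    for _ in range(max_iter):
        g1, g2, h11, h12, h22 = _grad_hess(M, C, Y, F, link)
        conv = ((np.maximum(np.abs(g1), np.abs(g2) / 100.0) <= grad_tol * gscale)
                | stalled | ~ok)
        det = h11 * h22 - h12 * h12
        bad = ~np.isfinite(det) | (det <= 0)
        det = np.where(bad, 1.0, det)
        dM = (h22 * g1 - h12 * g2) / det
        dC = (h11 * g2 - h12 * g1) / det
        # a vanishing Newton decrement also counts as converged
        conv |= np.abs(dM * g1 + dC * g2) <= 1e-12 * (1.0 + np.abs(ll))
        if conv.all():
            break
        ok &= ~bad

        # per-row backtracking line search on the exact objective, evaluated
        # only on the rows still searching
        todo = np.flatnonzero(~(conv | bad))
        step = np.ones(todo.size)
        for _ in range(30):
            Mn = M[todo] + step * dM[todo]
            Cn = C[todo] + step * dC[todo]
            lln = _core_loglik(Mn, Cn, Y[todo], F[todo], link)
            better = np.isfinite(lln) & (lln >= ll[todo] - 1e-12)
            idx = todo[better]
            M[idx] = Mn[better]
            C[idx] = Cn[better]
            ll[idx] = lln[better]
            todo = todo[~better]
            step = step[~better] * 0.5
            if todo.size == 0:
                break
        # rows the search cannot improve sit at a numerical optimum; the final
        # gradient check below decides whether that optimum is acceptable
        stalled[todo] = True

    g1, g2, *_ = _grad_hess(M, C, Y, F, link)
    ok &= np.maximum(np.abs(g1), np.abs(g2) / 100.0) <= 1e4 * grad_tol * gscale
    ok &= np.isfinite(ll)
    return BatchFit(M=M, C=C, loglik=ll - log_fact, ok=ok)


def fit_single(y: np.ndarray, F: np.ndarray, link: str = "identity") -> tuple[float, float, float, bool]:
    """Fit one dataset; Newton first, simplex fallback on non-convergence."""
    res = fit_batch(y[None, :], F, link)
    if res.ok[0]:
        return float(res.M[0]), float(res.C[0]), float(res.loglik[0]), True

    Y2 = y[None, :].astype(float)
    log_fact = float(gammaln(Y2 + 1.0).sum())

    def nll(p):
        v = _core_loglik(p[0], p[1], Y2, F, link)[0]
        return -v if np.isfinite(v) else 1e300

    mean = max(y.mean(), RATE_FLOOR)
    x0 = np.array([np.log(mean) if link == "log" else mean, 0.0])
    best = None
    for start in (x0, np.array([res.M[0], res.C[0]])):
        if not np.all(np.isfinite(start)):
            continue
        r = minimize(nll, start, method="Nelder-Mead",
                     options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 1500})
        if best is None or r.fun < best.fun:
            best = r
    return (float(best.x[0]), float(best.x[1]),
            float(-best.fun - log_fact), bool(best.success))


def fisher_information(M: float, C: float, F: np.ndarray, link: str) -> np.ndarray:
    """Expected Fisher information of (M, C) at the given parameters."""
    lam = rate(M, C, F, link)
    if link == "log":
        w = lam
    else:
        w = 1.0 / lam
    X = np.column_stack([np.ones_like(F, dtype=float), F])
    return (X * w[:, None]).T @ X
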