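"""Adaptive correlation cutoffs from Gaussian-mixture decomposition.

The pooled query-vs-background correlation coefficients are modelled as a
mixture of one to three Gaussians: the component(s) with lower means are
read as unrelated-cell-type pairs, the highest-mean component as same-type
pairs.  The cutoff separating the two regimes depends on how many
components best fit the data (BIC):

* one component — the whole pool looks unrelated; cutoff at the 0.75
  quantile of that component;
* two components — cutoff at the weighted-density intersection between the
  two component means (the classification boundary);
* three components — cutoff at the 0.75 quantile of the middle component.

The result is clamped to a configurable band, 0.4-0.6 by default, to guard
against extreme estimates.

The EM fit is deliberately deterministic: components are initialized from a
k-quantile partition of the sorted values, so identical inputs always give
identical fits.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .io_model import CutoffResult, FormatError, MixtureFit

logger = logging.getLogger("clustannot")

#: Fewer pooled coefficients than this and the mixture is unreliable;
#: callers fall back to :func:`default_cutoff`.
MIN_FIT_N = 50

DEFAULT_CLAMP_LO = 0.4
DEFAULT_CLAMP_HI = 0.6

_MAX_ITER = 200
_TOL = 1e-8
_Z75 = norm.ppf(0.75)


class InsufficientValuesError(FormatError):
    """Raised when too few values are available for a mixture fit."""


def _em_fit(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Unequal-variance univariate EM, initialized from a k-quantile split."""
    n = values.size
    order = np.sort(values)
    # Contiguous equal-size groups of the sorted data seed the components.
    splits = np.array_split(order, k)
    means = np.array([g.mean() for g in splits])
    var_floor = max(values.var() * 1e-6, 1e-12)
    sds = np.array([max(g.std(), np.sqrt(var_floor)) for g in splits])
    weights = np.array([g.size / n for g in splits])

    loglik = -np.inf
    x = values[:, None]
    for _ in range(_MAX_ITER):
        # E-step in log space for stability.
        log_comp = (
            np.log(weights)[None, :]
            + norm.logpdf(x, loc=means[None, :], scale=sds[None, :])
        )
        log_total = np.logaddexp.reduce(log_comp, axis=1)
        new_loglik = float(log_total.sum())
        resp = np.exp(log_comp - log_total[:, None])
        # M-step.
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x).sum(axis=0) / nk
        var = (resp * (x - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
        if abs(new_loglik - loglik) < _TOL * (1 + abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    order = np.argsort(means)
    return weights[order], means[order], sds[order], loglik


def fit_mixture(
    values: Sequence[float], kmax: int = 3, seed: int | None = None
) -> MixtureFit:
    """Fit 1..kmax-component Gaussian mixtures and keep the best by BIC.

    ``seed`` is accepted for interface stability but unused: initialization
    is a deterministic quantile partition, so the fit is reproducible from
    the data alone.
    """
    if not 1 <= kmax <= 3:
        raise FormatError("kmax must be 1, 2 or 3")
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < MIN_FIT_N:
        raise InsufficientValuesError(
            f"need >= {MIN_FIT_N} values for a mixture fit, got {arr.size}"
        )
    if arr.std() == 0:
        raise InsufficientValuesError("values are all identical")
    best: MixtureFit | None = None
    for k in range(1, kmax + 1):
        weights, means, sds, loglik = _em_fit(arr, k)
        n_params = 3 * k - 1
        bic = -2.0 * loglik + n_params * np.log(arr.size)
        fit = MixtureFit(
            k=k,
            weights=weights,
            means=means,
            sds=sds,
            loglik=loglik,
            criterion=bic,
            n=arr.size,
        )
        if best is None or fit.criterion < best.criterion:
            best = fit
    assert best is not None
    return best


def _k2_intersection(fit: MixtureFit) -> tuple[float, bool]:
    """Weighted-density intersection of a 2-component fit within the means.

    Returns (x, fallback) where fallback marks the no-real-root case, in
    which the midpoint of the means is used instead.
    """
    w1, w2 = fit.weights
    m1, m2 = fit.means
    s1, s2 = fit.sds

    def diff(x: float) -> float:
        return (np.log(w1) + norm.logpdf(x, m1, s1)) - (
            np.log(w2) + norm.logpdf(x, m2, s2)
        )

    lo, hi = m1, m2
    if hi - lo < 1e-12:
        return 0.5 * (m1 + m2), True
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0:
        return lo, False
    if f_hi == 0:
        return hi, False
    if np.sign(f_lo) == np.sign(f_hi):
        logger.warning(
            "no density intersection between component means; "
            "using their midpoint"
        )
        return 0.5 * (m1 + m2), True
    root = brentq(diff, lo, hi, xtol=1e-12)
    return float(root), False


def derive_cutoff(
    fit: MixtureFit,
    clamp_lo: float = DEFAULT_CLAMP_LO,
    clamp_hi: float = DEFAULT_CLAMP_HI,
) -> CutoffResult:
    """Apply the per-cardinality cutoff rule and clamp to the allowed band."""
    if clamp_lo > clamp_hi:
        raise FormatError("clamp_lo must not exceed clamp_hi")
    fallback = False
    if fit.k == 1:
        raw = float(fit.means[0] + _Z75 * fit.sds[0])
    elif fit.k == 2:
        raw, fallback = _k2_intersection(fit)
    else:  # k == 3: 0.75 quantile of the middle-mean component
        raw = float(fit.means[1] + _Z75 * fit.sds[1])
    cutoff = min(max(raw, clamp_lo), clamp_hi)
    return CutoffResult(
        raw_cutoff=raw,
        cutoff=cutoff,
        k_selected=fit.k,
        clamp_lo=clamp_lo,
        clamp_hi=clamp_hi,
        fallback_used=fallback,
    )


def default_cutoff(
    clamp_lo: float = DEFAULT_CLAMP_LO,
    clamp_hi: float = DEFAULT_CLAMP_HI,
) -> CutoffResult:
    """Midpoint-of-band cutoff used when a mixture fit is not possible."""
    if clamp_lo > clamp_hi:
        raise FormatError("clamp_lo must not exceed clamp_hi")
    mid = 0.5 * (clamp_lo + clamp_hi)
    return CutoffResult(
        raw_cutoff=mid,
        cutoff=mid,
        k_selected=0,
        clamp_lo=clamp_lo,
        clamp_hi=clamp_hi,
        fallback_used=True,
    )


def estimate_cutoff(
    values: Sequence[float],
    clamp_lo: float = DEFAULT_CLAMP_LO,
    clamp_hi: float = DEFAULT_CLAMP_HI,
    kmax: int = 3,
) -> tuple[CutoffResult, MixtureFit | None]:
    """Fit + derive in one call, falling back on degenerate input."""
    try:
        fit = fit_mixture(values, kmax=kmax)
    except InsufficientValuesError as exc:
        logger.warning("mixture fit skipped (%s); using default cutoff", exc)
        return default_cutoff(clamp_lo, clamp_hi), None
    return derive_cutoff(fit, clamp_lo, clamp_hi), fit
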