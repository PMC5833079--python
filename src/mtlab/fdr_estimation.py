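"""FDR *estimation*: Storey q-values and Grenander-density local FDR.

Unlike the step-up controllers in :mod:`mtlab.fdr_control`, these methods
first estimate the proportion of true null hypotheses ``pi0`` from the
p-value distribution itself and then convert each p-value into a
per-hypothesis error estimate:

* Storey's q-value — the smallest positive FDR (``pFDR = E[V/R | R > 0]``)
  attainable when calling that p-value significant.  ``pi0`` is estimated by
  tail counting ``#{p > lambda} / (m (1 - lambda))`` over a grid of tuning
  values ``lambda``, stabilised by a smooth trend evaluated at the largest
  ``lambda``.  When all p-values are small the tail count collapses; the
  estimator then shrinks the upper end of the grid stepwise until a usable
  estimate emerges (the fallback trail is recorded).
* Strimmer's q-value and local FDR — an empirical-Bayes route through the
  Grenander estimator: the maximum-likelihood *nonincreasing* density of the
  p-values, given by the slopes of the least concave majorant (LCM) of their
  empirical CDF.  ``pi0`` is the terminal (smallest) slope, the local FDR is
  ``pi0 / f(p)`` and the q-value is the tail-area ratio ``pi0 * p / F(p)``.

Both estimators need a sizeable vector to be trustworthy; the local FDR is
flagged inapplicable below a configurable minimum size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AdjustedPValues,
    PValueError,
    PValueVector,
    enforce_monotone,
    rank_pvalues,
)

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


class MethodInapplicable(Exception):
    """Raised when an estimator cannot produce a result for this input size."""


@dataclass(frozen=True)
class Pi0Estimate:
    """Estimated proportion of true nulls with its tuning provenance."""

    value: float
    method: str
    lambda_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    fallback_steps: int = 0
    raw_curve: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class QValueSet:
    """Per-hypothesis q-values (original order) plus the pi0 estimate used."""

    qvalues: np.ndarray
    pi0_used: Pi0Estimate
    method_id: str


@dataclass(frozen=True)
class LfdrSet:
    """Per-hypothesis local FDR values (original order)."""

    lfdr: np.ndarray
    pi0_used: Pi0Estimate


@dataclass(frozen=True)
class GrenanderDensity:
    """Piecewise-constant nonincreasing density on [0, 1].

    ``slopes[k]`` is the density on ``[breakpoints[k], breakpoints[k+1])``;
    the slopes are the derivative of the least concave majorant of the
    (null-tail-censored) p-value ECDF, so they are nonincreasing and
    integrate to one.
    """

    breakpoints: np.ndarray
    slopes: np.ndarray

    def cdf(self, p: np.ndarray) -> np.ndarray:
        """The least-concave-majorant CDF, linear between breakpoints."""
        heights = np.concatenate(
            [[0.0], np.cumsum(self.slopes * np.diff(self.breakpoints))]
        )
        return np.interp(np.asarray(p, dtype=float), self.breakpoints, heights)

    def pdf(self, p: np.ndarray) -> np.ndarray:
        """Density at ``p``, right-continuous in the step function.

        A p-value sitting exactly on a breakpoint takes the slope of the
        interval to its *right* (the flatter one); this is the conventional
        constant-interpolation rule and deliberately conservative for the
        smallest p-values, whose left interval is the boundary spike of the
        Grenander estimator.
        """
        idx = np.searchsorted(self.breakpoints, np.asarray(p, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, self.slopes.size - 1)
        return self.slopes[idx]


def _tail_pi0(p: np.ndarray, lam: float) -> float:
    """Tail-count estimate ``#{p > lambda} / (m (1 - lambda))``, clamped to 1."""
    m = p.size
    return min(1.0, np.count_nonzero(p > lam) / (m * (1.0 - lam)))


def storey_pi0(
    pv: PValueVector, lambda_grid: np.ndarray | None = None
) -> Pi0Estimate:
    """Storey's pi0 estimate over a lambda grid with a stepwise fallback.

    The raw curve ``pi0(lambda)`` is smoothed with a cubic trend and read off
    at the largest lambda.  For short inputs (fewer than twice the grid
    size) the cubic fit is degenerate, so the median of the raw curve is
    used instead.  Whenever the estimate is nonpositive or undefined —
    typically because every p-value is small and the tail count vanishes —
    the top of the grid is dropped one step at a time (``fallback_steps``
    counts the shrinkages); if the grid is exhausted the terminal fallback
    ``max(pi0(lambda_min), 1/m)`` is returned with a warning rather than an
    error.
    """
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[-1] >= 1 or grid[0] < 0:
        raise PValueError("lambda grid must be strictly ascending within [0, 1)")
    p = pv.values
    m = pv.m
    fallback_steps = 0
    full_curve = np.array([np.count_nonzero(p > lam) / (m * (1.0 - lam)) for lam in grid])

    work = grid.copy()
    while work.size:
        curve = full_curve[: work.size]
        if work.size == 1:
            est = curve[0]
            method = "storey-point"
        elif m < 2 * grid.size:
            est = float(np.median(curve))
            method = "storey-median"
        else:
            coef = np.polyfit(work, curve, deg=min(3, work.size - 1))
            est = float(np.polyval(coef, work[-1]))
            method = "storey-smoother"
        if np.isfinite(est) and est > 0.0:
            return Pi0Estimate(
                value=min(1.0, est),
                method=method,
                lambda_grid=work,
                fallback_steps=fallback_steps,
                raw_curve=curve,
            )
        work = work[:-1]
        fallback_steps += 1

    logger.warning(
        "pi0 smoother failed on every lambda sub-grid; using the terminal fallback"
    )
    terminal = min(1.0, max(full_curve[0], 1.0 / m))
    return Pi0Estimate(
        value=terminal,
        method="storey-terminal-fallback",
        lambda_grid=grid[:1],
        fallback_steps=fallback_steps,
        raw_curve=full_curve[:1],
    )


def storey_qvalues(pv: PValueVector, pi0: Pi0Estimate | None = None) -> QValueSet:
    """Storey q-values: step-up monotone ``pi0 * m * p_(i) / i``.

    With ``pi0 = 1`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values; any ``pi0 < 1`` makes the q-values uniformly smaller, which is
    where the method's extra power comes from.
    """
    if pi0 is None:
        pi0 = storey_pi0(pv)
    rk = rank_pvalues(pv)
    i = np.arange(1, pv.m + 1)
    q = enforce_monotone(pi0.value * (pv.m * rk.sorted_values / i), "step-up")
    return QValueSet(qvalues=rk.unsort(q), pi0_used=pi0, method_id="qvalue-storey")


def grenander_fit(pv: PValueVector, censor_at: float = 0.5) -> GrenanderDensity:
    """Modified Grenander estimator: LCM of the null-tail-censored ECDF.

    The least concave majorant (upper convex hull) of the ECDF vertices,
    prepended with (0, 0) and closed at (1, 1), gives the maximum-likelihood
    nonincreasing p-value density.  The raw estimator is inconsistent at the
    right boundary — the ECDF reaches 1 at the largest observation, so the
    terminal slope collapses to zero — which would wreck both the
    terminal-slope pi0 and the local FDR.  Following the censoring idea
    behind the modified estimator, ECDF vertices above ``censor_at`` are
    replaced by the null tail line ``1 - eta0 (1 - p)``, where ``eta0`` is
    the tail-count pre-estimate ``#{p > censor_at} / (m (1 - censor_at))``:
    above the censor point the uniform null component dominates and the
    noisy extreme order statistics carry no usable shape information.  When
    ``eta0`` is not clamped the line meets the ECDF at the censor point, so
    the fit below ``censor_at`` is untouched.  Needs at least two distinct
    p-values.
    """
    uniq, counts = np.unique(pv.values, return_counts=True)
    if uniq.size < 2:
        raise MethodInapplicable(
            "Grenander fit needs at least 2 distinct p-values"
        )
    ecdf = np.cumsum(counts) / pv.m
    keep = uniq < censor_at
    ecdf_at_censor = float(ecdf[uniq <= censor_at][-1]) if (uniq <= censor_at).any() else 0.0
    eta0 = min(1.0, max(np.count_nonzero(pv.values > censor_at)
                        / (pv.m * (1.0 - censor_at)), 1.0 / pv.m))
    anchor_y = max(ecdf_at_censor, 1.0 - eta0 * (1.0 - censor_at))
    x = np.concatenate([[0.0], uniq[keep], [censor_at, 1.0]])
    y = np.concatenate([[0.0], ecdf[keep], [anchor_y, 1.0]])

    # upper convex hull scan: keep vertices while slopes stay decreasing
    hull: list[int] = [0]
    for j in range(1, x.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # drop b if it lies below chord a->j (slope to j not smaller)
            if (y[b] - y[a]) * (x[j] - x[b]) <= (y[j] - y[b]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(j)
    bx, by_ = x[hull], y[hull]
    slopes = np.diff(by_) / np.diff(bx)
    return GrenanderDensity(breakpoints=bx, slopes=slopes)


def strimmer_pi0(den: GrenanderDensity, m: int | None = None) -> Pi0Estimate:
    """Terminal-slope pi0: the Grenander density's value on its last interval.

    Under the two-groups model the null component is flat at height ``pi0``
    and dominates near ``p = 1``, so the smallest slope estimates ``pi0``.
    Clamped into ``(0, 1]`` (lower bound ``1/m`` when ``m`` is given).
    """
    floor = 1.0 / m if m else np.finfo(float).tiny
    value = min(1.0, max(float(den.slopes[-1]), floor))
    return Pi0Estimate(value=value, method="grenander-terminal")


def strimmer_lfdr(
    pv: PValueVector,
    den: GrenanderDensity | None = None,
    pi0: Pi0Estimate | None = None,
    min_m: int = 8,
) -> LfdrSet:
    """Local FDR ``min(1, pi0 / f(p))`` from the Grenander density.

    The local FDR is the posterior probability that a hypothesis with this
    exact p-value is a true null.  Because ``f`` is nonincreasing the values
    are automatically nondecreasing in ``p``, reaching 1 on the terminal
    interval where ``f = pi0``.  Inputs shorter than ``min_m`` are refused:
    a density estimate from a handful of points is noise.
    """
    if pv.m < min_m:
        raise MethodInapplicable(f"local FDR needs at least {min_m} p-values, got {pv.m}")
    if den is None:
        den = grenander_fit(pv)
    if pi0 is None:
        pi0 = strimmer_pi0(den, pv.m)
    with np.errstate(divide="ignore"):
        lfdr = np.minimum(1.0, pi0.value / den.pdf(pv.values))
    return LfdrSet(lfdr=lfdr, pi0_used=pi0)


def strimmer_qvalues(
    pv: PValueVector,
    den: GrenanderDensity | None = None,
    pi0: Pi0Estimate | None = None,
) -> QValueSet:
    """Tail-area q-values ``pi0 * p / F(p)`` with the LCM CDF ``F``.

    ``F(p) / p`` is the model estimate of ``Pr(P <= p)`` per unit rejected,
    so the ratio estimates the pFDR of rejecting at ``p``; step-up monotone
    enforcement then yields proper q-values.  At ``p = 0`` the limit
    ``pi0 / f(0)`` is used.
    """
    if den is None:
        den = grenander_fit(pv)
    if pi0 is None:
        pi0 = strimmer_pi0(den, pv.m)
    rk = rank_pvalues(pv)
    p = rk.sorted_values
    F = den.cdf(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(F > 0, pi0.value * p / F, pi0.value / den.slopes[0])
    q = enforce_monotone(raw, "step-up")
    return QValueSet(qvalues=rk.unsort(q), pi0_used=pi0, method_id="qvalue-strimmer")


def storey_qvalues_adjusted(pv: PValueVector, **kw) -> AdjustedPValues:
    """Storey q-values wrapped as :class:`AdjustedPValues` for the registry."""
    qs = storey_qvalues(pv, **kw)
    return AdjustedPValues(
        qs.qvalues, "qvalue-storey",
        constants={"pi0": qs.pi0_used.value, "fallback_steps": qs.pi0_used.fallback_steps},
    )


def strimmer_qvalues_adjusted(pv: PValueVector) -> AdjustedPValues:
    """Strimmer q-values wrapped as :class:`AdjustedPValues` for the registry."""
    qs = strimmer_qvalues(pv)
    return AdjustedPValues(qs.qvalues, "qvalue-strimmer", constants={"pi0": qs.pi0_used.value})


def strimmer_lfdr_adjusted(pv: PValueVector, min_m: int = 8) -> AdjustedPValues:
    """Local FDR values wrapped as :class:`AdjustedPValues` for the registry."""
    ls = strimmer_lfdr(pv, min_m=min_m)
    return AdjustedPValues(ls.lfdr, "lfdr", constants={"pi0": ls.pi0_used.value})
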