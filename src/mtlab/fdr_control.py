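"""FDR-controlling linear step-up procedures.

The false discovery rate is ``E[V/R | R > 0] * Pr(R > 0)``, the expected
proportion of false positives among rejections.  Three controllers are
provided: Benjamini-Hochberg (valid under positive regression dependency),
Benjamini-Yekutieli (valid under arbitrary dependency, paying a
``sum(1/i)`` penalty) and the two-stage adaptive step-up procedure, which
estimates the proportion of true nulls from a first-stage BH pass and
re-runs BH at the correspondingly relaxed level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AdjustedPValues,
    DecisionSet,
    PValueError,
    PValueVector,
    decide,
    enforce_monotone,
    rank_pvalues,
)


def bh_adjust(pv: PValueVector) -> AdjustedPValues:
    """Benjamini-Hochberg step-up: running minimum of ``m * p_(i) / i``."""
    rk = rank_pvalues(pv)
    i = np.arange(1, pv.m + 1)
    adj = enforce_monotone(pv.m * rk.sorted_values / i, "step-up")
    return AdjustedPValues(rk.unsort(adj), "bh")


def by_harmonic_constant(m: int) -> float:
    """``c(m) = sum_{i=1..m} 1/i``, the Benjamini-Yekutieli dependency penalty."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def by_adjust(pv: PValueVector) -> AdjustedPValues:
    """Benjamini-Yekutieli step-up: BH adjusted values scaled by ``c(m)``.

    Controls the FDR under arbitrary p-value dependency; always at least as
    conservative as BH since ``c(m) >= 1``.
    """
    cm = by_harmonic_constant(pv.m)
    bh = bh_adjust(pv)
    return AdjustedPValues(
        np.minimum(1.0, cm * bh.values), "by", constants={"c_m": cm}
    )


@dataclass(frozen=True)
class TwoStageResult:
    """Outcome of the two-stage adaptive step-up procedure.

    ``pi0_hat_stage1 = (m - r1) / m`` is the stage-1 estimate of the
    proportion of true nulls; ``adjusted_alpha`` is the deflated level
    ``alpha / (1 + alpha)`` used in both stages.
    """

    decisions: DecisionSet
    stage1_rejections: int
    pi0_hat_stage1: float
    adjusted_alpha: float


def two_stage(pv: PValueVector, alpha: float) -> TwoStageResult:
    """Two-stage adaptive BH at level ``alpha``.

    Stage 1 runs BH at ``alpha' = alpha / (1 + alpha)`` giving ``r1``
    rejections.  If ``r1`` is 0 or ``m`` that decision is final; otherwise
    stage 2 re-runs BH at ``alpha' * m / (m - r1)``, i.e. at level
    ``alpha' / pi0_hat``.
    """
    if not (0.0 < alpha < 1.0):
        raise PValueError(f"alpha must lie in (0, 1), got {alpha}")
    m = pv.m
    alpha1 = alpha / (1.0 + alpha)
    bh = bh_adjust(pv)
    stage1 = decide(bh, alpha1)
    r1 = stage1.R
    pi0_hat = (m - r1) / m
    if r1 == 0 or r1 == m:
        final = DecisionSet(stage1.reject, alpha=alpha, method_id="tsbh")
    else:
        alpha2 = alpha1 * m / (m - r1)
        final = DecisionSet(bh.values <= alpha2, alpha=alpha, method_id="tsbh")
    return TwoStageResult(
        decisions=final,
        stage1_rejections=r1,
        pi0_hat_stage1=pi0_hat,
        adjusted_alpha=alpha1,
    )


def tsbh_adjust(pv: PValueVector, alpha: float = 0.05) -> AdjustedPValues:
    """Represent two-stage decisions at a fixed ``alpha`` as pseudo-adjusted values.

    The two-stage procedure has no natural single adjusted-p vector because
    its stage-2 level depends on ``alpha``; this helper maps rejections at
    the given ``alpha`` to 0 and non-rejections to 1 so the procedure can sit
    in the common method registry.  The stage-1 pi0 estimate is kept in
    ``constants``.
    """
    res = two_stage(pv, alpha)
    values = np.where(res.decisions.reject, 0.0, 1.0)
    return AdjustedPValues(
        values,
        "tsbh",
        constants={
            "pi0_hat_stage1": res.pi0_hat_stage1,
            "stage1_rejections": res.stage1_rejections,
            "adjusted_alpha": res.adjusted_alpha,
            "alpha": alpha,
        },
    )
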