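"""Family-wise error rate (FWER) procedures.

The FWER is the probability of at least one false positive decision,
``Pr(V > 0)``.  Four classic controllers are provided — Bonferroni, Holm's
step-down, Hochberg's step-up and Hommel's procedure — together with the
effective-number variant of Bonferroni used in genome-wide screens and a
brute-force closed-testing oracle that pins down Hommel's decisions on small
inputs.

The four procedures form a dominance chain on every input: each rejects at
least the hypotheses rejected by its predecessor
(Bonferroni ⊆ Holm ⊆ Hochberg ⊆ Hommel).  Hochberg and Hommel additionally
assume positive regression dependency among the null p-values.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import (
    AdjustedPValues,
    DecisionSet,
    PValueError,
    PValueVector,
    enforce_monotone,
    rank_pvalues,
)


def bonferroni_adjust(pv: PValueVector) -> AdjustedPValues:
    """Bonferroni correction: ``adjusted_i = min(1, m * p_i)``.

    Thresholding the adjusted values at ``alpha`` is identical to comparing
    each raw p-value with the fixed per-test threshold ``alpha / m``.
    """
    return AdjustedPValues(np.minimum(1.0, pv.m * pv.values), "bonferroni")


def effective_number_threshold(alpha: float, n_effective: int) -> float:
    """Per-test threshold ``alpha / n_effective`` for an effective number of tests.

    In dense genome-wide panels the tests are correlated, so the overall
    threshold is divided by the estimated number of *independent* tests
    rather than the nominal test count (e.g. 0.05 / 1,000,000 = 5e-8 for
    European-ancestry GWAS).  Estimating ``n_effective`` itself is the
    caller's business.
    """
    if not (0.0 < alpha < 1.0):
        raise PValueError(f"alpha must lie in (0, 1), got {alpha}")
    if int(n_effective) != n_effective or n_effective < 1:
        raise PValueError(f"n_effective must be a positive integer, got {n_effective}")
    return alpha / n_effective


def holm_adjust(pv: PValueVector) -> AdjustedPValues:
    """Holm's step-down procedure: running maximum of ``(m - i + 1) * p_(i)``."""
    rk = rank_pvalues(pv)
    factors = pv.m - np.arange(pv.m)
    adj = enforce_monotone(factors * rk.sorted_values, "step-down")
    return AdjustedPValues(rk.unsort(adj), "holm")


def hochberg_adjust(pv: PValueVector) -> AdjustedPValues:
    """Hochberg's step-up procedure: running minimum (from the top) of ``(m - i + 1) * p_(i)``."""
    rk = rank_pvalues(pv)
    factors = pv.m - np.arange(pv.m)
    adj = enforce_monotone(factors * rk.sorted_values, "step-up")
    return AdjustedPValues(rk.unsort(adj), "hochberg")


def hommel_adjust(pv: PValueVector) -> AdjustedPValues:
    """Hommel's procedure via the standard shortcut recursion.

    Equivalent to closed testing of all intersection hypotheses with Simes
    local tests (see :func:`closed_testing_oracle`); the most powerful of the
    four FWER procedures under positive regression dependency.
    """
    m = pv.m
    rk = rank_pvalues(pv)
    p = rk.sorted_values
    if m == 1:
        return AdjustedPValues(pv.values.copy(), "hommel")
    i = np.arange(1, m + 1)
    pa = np.full(m, np.min(m * p / i))
    q = pa.copy()
    for size in range(m - 1, 1, -1):
        i1 = np.arange(m - size + 1)          # ranks 1 .. m-size+1
        i2 = np.arange(m - size + 1, m)       # ranks m-size+2 .. m
        q1 = np.min(size * p[i2] / np.arange(2, size + 1))
        q[i1] = np.minimum(size * p[i1], q1)
        q[i2] = q[m - size]
        pa = np.maximum(pa, q)
    adj = np.clip(np.maximum(pa, p), 0.0, 1.0)
    return AdjustedPValues(rk.unsort(adj), "hommel")


def simes_pvalue(p_subset: np.ndarray) -> float:
    """Simes combination p-value ``min_k (k_total * p_(k) / k)`` for an intersection null."""
    p_sorted = np.sort(np.asarray(p_subset, dtype=float))
    k = p_sorted.size
    return float(np.min(k * p_sorted / np.arange(1, k + 1)))


def closed_testing_oracle(pv: PValueVector, alpha: float, max_m: int = 12) -> DecisionSet:
    """Exhaustive closed testing with Simes local tests.

    Rejects hypothesis ``i`` iff *every* intersection hypothesis containing
    ``i`` has Simes p-value ``<= alpha``.  Enumerates all ``2^m - 1``
    non-empty subsets, so refuses inputs larger than ``max_m``.  Used as the
    validation oracle for :func:`hommel_adjust`.
    """
    if not (0.0 < alpha < 1.0):
        raise PValueError(f"alpha must lie in (0, 1), got {alpha}")
    m = pv.m
    if m > max_m:
        raise PValueError(
            f"closed testing enumerates 2^m - 1 subsets; m={m} exceeds the limit {max_m}"
        )
    reject = np.ones(m, dtype=bool)
    idx = range(m)
    for size in range(1, m + 1):
        for subset in combinations(idx, size):
            if simes_pvalue(pv.values[list(subset)]) > alpha:
                reject[list(subset)] = False
    return DecisionSet(reject=reject, alpha=alpha, method_id="closed-testing-simes")
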