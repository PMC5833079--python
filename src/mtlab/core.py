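"""Shared data model for multiple-testing procedures.

Conventions used throughout the package follow the standard decision-table
notation for testing ``m`` hypotheses simultaneously: among ``m0`` true nulls
``U`` are kept and ``V`` rejected (type I errors); among ``m1`` true
alternatives ``T`` are kept (type II errors) and ``S`` rejected; ``R = V + S``
is the total number of rejections at an overall significance threshold
``alpha``.

All procedures in :mod:`mtlab` communicate through *adjusted* significance
measures (adjusted p-values, q-values, local FDR values): a hypothesis is
declared significant when its adjusted measure is ``<= alpha``.  Adjusted
measures are kept monotone in the raw p-value so that every rejection set is
a prefix of the sorted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PValueError(ValueError):
    """Raised when an input p-value vector violates its contract."""


@dataclass(frozen=True)
class PValueVector:
    """A validated vector of two-sided p-values.

    Parameters
    ----------
    values
        Probabilities in ``[0, 1]``; missing values are rejected.
    ids
        Optional opaque feature labels aligned with ``values``.
    """

    values: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise PValueError("p-value vector must be one-dimensional and non-empty")
        bad = np.flatnonzero(~np.isfinite(arr) | (arr < 0.0) | (arr > 1.0))
        if bad.size:
            raise PValueError(
                f"p-value at index {bad[0]} is {arr[bad[0]]!r}; "
                "all values must be finite and in [0, 1]"
            )
        object.__setattr__(self, "values", arr)
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            if len(ids) != arr.size:
                raise PValueError("ids and values have different lengths")
            object.__setattr__(self, "ids", ids)

    @property
    def m(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RankedPValues:
    """Stable ascending ordering of a p-value vector.

    ``order`` maps rank -> original index; ``rank_of`` maps original
    index -> 1-based rank.  Applying ``order`` to the input recovers
    ``sorted_values``; ``sorted_values[rank_of - 1]`` recovers input order.
    """

    sorted_values: np.ndarray
    order: np.ndarray
    rank_of: np.ndarray

    def unsort(self, per_rank: np.ndarray) -> np.ndarray:
        """Map a per-rank vector back to original input order."""
        out = np.empty_like(np.asarray(per_rank, dtype=float))
        out[self.order] = per_rank
        return out


@dataclass(frozen=True)
class AdjustedPValues:
    """Per-hypothesis adjusted significance measures in original input order."""

    values: np.ndarray
    method_id: str
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if np.any((arr < 0.0) | (arr > 1.0)):
            raise PValueError(f"adjusted values for {self.method_id} escape [0, 1]")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class DecisionSet:
    """Per-hypothesis reject/keep flags at a cutoff ``alpha``."""

    reject: np.ndarray
    alpha: float
    method_id: str

    @property
    def R(self) -> int:
        return int(np.count_nonzero(self.reject))

    @property
    def m(self) -> int:
        return int(self.reject.size)


@dataclass(frozen=True)
class ConfusionCounts:
    """Decision-table counts against known truth.

    ``U``/``V`` partition the ``m0`` true nulls (kept/rejected) and
    ``T``/``S`` partition the ``m1`` true alternatives, so that
    ``U + V = m0``, ``T + S = m1`` and ``V + S = R``.
    """

    U: int
    V: int
    T: int
    S: int

    @property
    def m0(self) -> int:
        return self.U + self.V

    @property
    def m1(self) -> int:
        return self.T + self.S

    @property
    def m(self) -> int:
        return self.m0 + self.m1

    @property
    def R(self) -> int:
        return self.V + self.S

    @property
    def power(self) -> float:
        """S / m1, the proportion of true alternatives rejected (nan if m1=0)."""
        return self.S / self.m1 if self.m1 else float("nan")

    @property
    def specificity(self) -> float:
        """U / m0, the proportion of true nulls kept (nan if m0=0)."""
        return self.U / self.m0 if self.m0 else float("nan")


def rank_pvalues(pv: PValueVector) -> RankedPValues:
    """Rank p-values in increasing order with a stable sort.

    Ties keep input order, so tied raw p-values always receive identical
    adjusted values downstream.
    """
    order = np.argsort(pv.values, kind="stable")
    rank_of = np.empty(pv.m, dtype=int)
    rank_of[order] = np.arange(1, pv.m + 1)
    return RankedPValues(sorted_values=pv.values[order], order=order, rank_of=rank_of)


def enforce_monotone(per_rank: np.ndarray, direction: str) -> np.ndarray:
    """Make per-rank adjusted measures monotone in the raw p-value.

    ``step-up`` takes the running minimum from the largest rank downward
    (Benjamini-Hochberg-style procedures); ``step-down`` the running maximum
    from the smallest rank upward (Holm-style).  Output is clamped to [0, 1].
    """
    arr = np.asarray(per_rank, dtype=float)
    if direction == "step-up":
        out = np.minimum.accumulate(arr[::-1])[::-1]
    elif direction == "step-down":
        out = np.maximum.accumulate(arr)
    else:
        raise ValueError(f"direction must be 'step-up' or 'step-down', got {direction!r}")
    return np.clip(out, 0.0, 1.0)


def decide(adj: AdjustedPValues, alpha: float) -> DecisionSet:
    """Threshold adjusted measures: significant means ``adjusted <= alpha``."""
    if not (0.0 < alpha < 1.0):
        raise PValueError(f"alpha must lie in (0, 1), got {alpha}")
    return DecisionSet(reject=adj.values <= alpha, alpha=alpha, method_id=adj.method_id)


def confusion(dec: DecisionSet, truth_null: np.ndarray) -> ConfusionCounts:
    """Tabulate decisions against truth.

    ``truth_null[i]`` is True when hypothesis ``i`` is a true null.
    """
    truth_null = np.asarray(truth_null, dtype=bool)
    if truth_null.size != dec.reject.size:
        raise PValueError(
            f"truth has length {truth_null.size}, decisions {dec.reject.size}"
        )
    rej = dec.reject
    return ConfusionCounts(
        U=int(np.count_nonzero(truth_null & ~rej)),
        V=int(np.count_nonzero(truth_null & rej)),
        T=int(np.count_nonzero(~truth_null & ~rej)),
        S=int(np.count_nonzero(~truth_null & rej)),
    )


def read_pvalues(path) -> PValueVector:
    """Read p-values from a one-column text file or a TSV with `id` and `p` columns."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 1:
        col = df.columns[0]
        try:  # headerless one-column file: the "header" is the first value
            first = float(col)
        except ValueError:
            return PValueVector(df[col].to_numpy(dtype=float))
        vals = np.concatenate([[first], df[col].to_numpy(dtype=float)])
        return PValueVector(vals)
    if not {"id", "p"}.issubset(df.columns):
        raise PValueError("TSV input must provide 'id' and 'p' columns")
    if df["p"].isna().any():
        idx = int(df["p"].isna().idxmax())
        raise PValueError(f"missing p-value for id {df['id'].iloc[idx]!r}")
    return PValueVector(df["p"].to_numpy(dtype=float), ids=tuple(df["id"].astype(str)))


def decisions_frame(
    pv: PValueVector, adj: AdjustedPValues, dec: DecisionSet
) -> pd.DataFrame:
    """Tidy per-hypothesis table: id, p, adjusted, method, reject."""
    ids = pv.ids if pv.ids is not None else [str(i) for i in range(pv.m)]
    return pd.DataFrame(
        {
            "id": ids,
            "p": pv.values,
            "adjusted": adj.values,
            "method": adj.method_id,
            "reject": dec.reject,
        }
    )
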