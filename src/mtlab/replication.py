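"""Discovery -> replication screening on study-level summary statistics.

Mirrors the two-stage design of genome-wide association meta-analyses: a
large *discovery* set of studies is meta-analysed with an inverse
variance-weighted fixed-effect model (with genomic-control inflation
correction), index features with discovery p-value below a stringent
threshold (1e-6 by default) are carried into an independent *replication*
set, and every multiple-testing procedure is applied to the replication
p-values of just those features.

Real consortium data is replaced by a synthetic generator
(:func:`generate_two_set_study`): two non-overlapping study sets share a
common vector of true effects (a minority of features carry signal), and
each study reports ``effect_hat = effect + N(0, SE^2)`` with a standard
error derived from its simulated sample size.  Features are generated
independently, standing in for post-pruning independence of index SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PValueError, PValueVector, decide
from .fdr_estimation import MethodInapplicable
from .registry import STUDY_METHODS, adjusted_values

# median of the chi-squared(1 df) distribution, the null expectation of z^2
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect meta-analysis results per feature."""

    table: pd.DataFrame  # feature_id, effect, se, z, p
    lambda_gc: float = 1.0

    @property
    def pvalues(self) -> PValueVector:
        return PValueVector(
            self.table["p"].to_numpy(), ids=tuple(self.table["feature_id"].astype(str))
        )


def meta_fixed(studies: list[pd.DataFrame]) -> MetaResult:
    """Inverse variance-weighted fixed-effect meta-analysis.

    Each study table carries ``feature_id``, ``effect``, ``se``.  Per
    feature: weights ``w = 1/se^2``, pooled effect ``sum(w * effect) /
    sum(w)``, pooled ``se = 1/sqrt(sum(w))``, ``z = effect/se`` and
    two-sided normal p.  Features missing from a study are dropped pairwise
    for that study only.
    """
    if not studies:
        raise PValueError("meta-analysis needs at least one study")
    frames = []
    for k, df in enumerate(studies):
        df = df[["feature_id", "effect", "se"]].copy()
        bad = df[~(df["se"] > 0)]
        if len(bad):
            raise PValueError(
                f"non-positive standard error for feature "
                f"{bad['feature_id'].iloc[0]!r} in study {k}"
            )
        frames.append(df)
    stacked = pd.concat(frames, ignore_index=True)
    w = 1.0 / stacked["se"] ** 2
    stacked["w"] = w
    stacked["we"] = w * stacked["effect"]
    grp = stacked.groupby("feature_id", sort=True)[["w", "we"]].sum()
    effect = grp["we"] / grp["w"]
    se = 1.0 / np.sqrt(grp["w"])
    z = effect / se
    p = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    table = pd.DataFrame(
        {"feature_id": grp.index, "effect": effect.values, "se": se.values,
         "z": z.values, "p": p}
    ).reset_index(drop=True)
    return MetaResult(table=table)


def genomic_control(meta: MetaResult) -> MetaResult:
    """Genomic-control correction of test-statistic inflation.

    ``lambda_GC`` is the observed median of ``z^2`` over its null
    expectation (the chi-squared(1) median, 0.4549...).  When
    ``lambda_GC > 1`` all standard errors are inflated by
    ``sqrt(lambda_GC)`` and z/p recomputed; deflation is never applied.
    """
    t = meta.table
    lam = float(np.median(t["z"] ** 2) / CHI2_MEDIAN_1DF)
    if lam <= 1.0:
        return MetaResult(table=t.copy(), lambda_gc=lam)
    out = t.copy()
    out["se"] = out["se"] * np.sqrt(lam)
    out["z"] = out["effect"] / out["se"]
    out["p"] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(out["z"])))
    return MetaResult(table=out, lambda_gc=lam)


def select_index(meta: MetaResult, threshold: float = 1e-6) -> list[str]:
    """Feature ids with ``p`` strictly below ``threshold``, in ascending p order."""
    if not (0.0 < threshold < 1.0):
        raise PValueError(f"threshold must lie in (0, 1), got {threshold}")
    hits = meta.table[meta.table["p"] < threshold].sort_values("p")
    return [str(f) for f in hits["feature_id"]]


@dataclass
class ScreenReport:
    """Per-method significance counts on the replication set."""

    counts: dict[str, int]
    significant_ids: dict[str, list[str]]
    selected: list[str]
    direction_consistent: dict[str, bool]
    missing_in_replication: list[str] = field(default_factory=list)
    inapplicable: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": name,
                "n_significant": self.counts[name],
                "feature_ids": ";".join(self.significant_ids[name]),
            }
            for name in sorted(self.counts, key=lambda k: self.counts[k])
        ]
        return pd.DataFrame(rows)


def replication_screen(
    discovery: MetaResult,
    replication: MetaResult,
    threshold: float = 1e-6,
    alpha: float = 0.05,
    methods: tuple[str, ...] = STUDY_METHODS,
) -> ScreenReport:
    """Apply every procedure to the replication p-values of the index features.

    Also flags direction consistency: whether the pooled discovery and
    replication effects of each selected feature share a sign.  Selected
    features absent from the replication set are dropped with a record.
    """
    selected = select_index(discovery, threshold)
    rep = replication.table.set_index(replication.table["feature_id"].astype(str))
    missing = [f for f in selected if f not in rep.index]
    present = [f for f in selected if f in rep.index]

    disc = discovery.table.set_index(discovery.table["feature_id"].astype(str))
    direction = {
        f: bool(np.sign(disc.loc[f, "effect"]) == np.sign(rep.loc[f, "effect"]))
        for f in present
    }
    counts: dict[str, int] = {}
    sig_ids: dict[str, list[str]] = {}
    inapplicable: list[str] = []
    if not present:
        return ScreenReport(
            counts={m: 0 for m in methods},
            significant_ids={m: [] for m in methods},
            selected=selected,
            direction_consistent=direction,
            missing_in_replication=missing,
        )
    pv = PValueVector(rep.loc[present, "p"].to_numpy(), ids=tuple(present))
    for name in methods:
        try:
            dec = decide(adjusted_values(name, pv, alpha), alpha)
        except MethodInapplicable:
            inapplicable.append(name)
            counts[name] = 0
            sig_ids[name] = []
            continue
        counts[name] = dec.R
        sig_ids[name] = [f for f, r in zip(present, dec.reject) if r]
    return ScreenReport(
        counts=counts,
        significant_ids=sig_ids,
        selected=selected,
        direction_consistent=direction,
        missing_in_replication=missing,
        inapplicable=inapplicable,
    )


@dataclass(frozen=True)
class TwoSetStudyConfig:
    """Synthetic two-set screening study.

    Defaults emulate a downsized GWAS consortium: 200 independent features
    of which 20 carry a shared true effect, 10 discovery and 5 replication
    studies (a roughly 2:1 total-sample ratio), per-study sample sizes
    uniform on [4000, 12000] and unit trait variance, so true effects of
    0.05 trait units per allele are comfortably detectable in discovery and
    replicable.
    """

    n_features: int = 200
    n_true: int = 20
    effect_size: float = 0.05
    n_discovery_studies: int = 10
    n_replication_studies: int = 5
    size_range: tuple[int, int] = (4000, 12000)
    trait_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.n_true <= self.n_features):
            raise PValueError("n_true must lie in [0, n_features]")
        if min(self.n_discovery_studies, self.n_replication_studies) < 1:
            raise PValueError("each set needs at least one study")


def generate_two_set_study(
    config: TwoSetStudyConfig | None = None, seed: int = 0
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], np.ndarray]:
    """Simulate discovery and replication study tables with shared truth.

    Returns ``(discovery_studies, replication_studies, truth_null)``.  The
    first ``n_true`` features carry the true effect in both sets; each study
    reports ``effect + N(0, se^2)`` with ``se = trait_sd / sqrt(n_study)``.
    """
    cfg = config or TwoSetStudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, cfg.n_features)))
    ids = [f"feat{j:04d}" for j in range(cfg.n_features)]
    effects = np.zeros(cfg.n_features)
    effects[: cfg.n_true] = cfg.effect_size
    truth_null = effects == 0.0

    def make_set(n_studies: int, label: str) -> list[pd.DataFrame]:
        out = []
        for k in range(n_studies):
            n = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
            se = cfg.trait_sd / np.sqrt(n)
            est = effects + rng.normal(0.0, se, size=cfg.n_features)
            out.append(
                pd.DataFrame(
                    {
                        "study_id": f"{label}{k:02d}",
                        "feature_id": ids,
                        "effect": est,
                        "se": se,
                    }
                )
            )
        return out

    return (
        make_set(cfg.n_discovery_studies, "disc"),
        make_set(cfg.n_replication_studies, "repl"),
        truth_null,
    )
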