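"""Simulation harness: power and specificity of the procedures at small m.

The study design crosses the number of hypotheses ``m`` in
{4, 8, 16, 32, 64, 1000} with the true-null proportion ``pi0`` in
{25%, 50%, 75%, 100%} and the alternative mean ``beta`` in {1.0, 2.5}.
Each repetition draws independent test statistics from N(0, 1) for the
``round(pi0 * m)`` nulls and N(beta, 1) for the rest, transforms them to
two-sided p-values, and applies every registered procedure at a 0.05
cutoff.  Per scenario the harness reports each method's average power
(S / m1), average specificity (U / m0) and the number of repetitions with
at least one false positive, plus the per-repetition pi0 estimates of the
Storey and Grenander estimators.

Repetitions are seeded from a single base seed through
``numpy.random.SeedSequence`` keyed on (scenario, repetition), so a run is
reproducible and any single repetition can be replayed in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfusionCounts, PValueError, PValueVector, confusion, decide
from .fdr_estimation import MethodInapplicable, grenander_fit, storey_pi0, strimmer_pi0
from .registry import STUDY_METHODS, adjusted_values

logger = logging.getLogger(__name__)

GRID_M = (4, 8, 16, 32, 64, 1000)
GRID_PI0 = (0.25, 0.50, 0.75, 1.00)
GRID_BETA = (1.0, 2.5)


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid."""

    m: int
    pi0: float
    beta: float
    reps: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.reps < 1 or self.beta < 0:
            raise PValueError("scenario requires m >= 1, reps >= 1, beta >= 0")
        if not (0.0 <= self.pi0 <= 1.0):
            raise PValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if abs(self.pi0 * self.m - round(self.pi0 * self.m)) > 1e-9:
            logger.warning(
                "pi0 * m = %.3f is not integral; rounding the null count",
                self.pi0 * self.m,
            )

    @property
    def m0(self) -> int:
        return int(round(self.pi0 * self.m))

    @property
    def m1(self) -> int:
        return self.m - self.m0


@dataclass
class RepetitionOutcome:
    """Per-method confusion counts and pi0 estimates for one repetition."""

    counts: dict[str, ConfusionCounts]
    applicable: dict[str, bool]
    pi0_estimates: dict[str, float]


@dataclass
class ScenarioSummary:
    """Averages over repetitions for one grid cell."""

    scenario: SimulationScenario
    mean_power: dict[str, float]
    mean_specificity: dict[str, float]
    fp_reps: dict[str, int]
    applicable_reps: dict[str, int]
    pi0_estimates: dict[str, list[float]] = field(default_factory=dict)


def _rep_rng(scn: SimulationScenario, rep_index: int) -> np.random.Generator:
    # independent, replayable stream per (scenario, repetition)
    key = (scn.seed, scn.m, int(round(scn.pi0 * 100)), int(round(scn.beta * 10)), rep_index)
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_scenario(
    scn: SimulationScenario, rep_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one repetition: z-statistics and aligned truth labels.

    Returns ``(z, truth_null)`` where the first ``m0`` entries are N(0, 1)
    draws (true nulls) and the rest N(beta, 1) draws.
    """
    rng = _rep_rng(scn, rep_index)
    z = rng.standard_normal(scn.m)
    z[scn.m0:] += scn.beta
    truth_null = np.zeros(scn.m, dtype=bool)
    truth_null[: scn.m0] = True
    return z, truth_null


def z_to_pvalue(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value ``2 * (1 - Phi(|z|))``."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise PValueError("test statistics must be finite")
    return np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))


def evaluate_rep(
    pvals: np.ndarray,
    truth_null: np.ndarray,
    methods: tuple[str, ...] = STUDY_METHODS,
    alpha: float = 0.05,
) -> RepetitionOutcome:
    """Apply every method to one p-value vector and tabulate decisions.

    A method that signals inapplicability (e.g. the local FDR on a handful
    of p-values) is recorded as missing rather than an error, mirroring how
    such gaps are reported in practice.
    """
    pv = PValueVector(np.asarray(pvals, dtype=float))
    counts: dict[str, ConfusionCounts] = {}
    applicable: dict[str, bool] = {}
    for name in methods:
        try:
            adj = adjusted_values(name, pv, alpha)
        except MethodInapplicable:
            applicable[name] = False
            continue
        applicable[name] = True
        counts[name] = confusion(decide(adj, alpha), truth_null)

    pi0_estimates: dict[str, float] = {}
    pi0_estimates["storey"] = storey_pi0(pv).value
    try:
        pi0_estimates["strimmer"] = strimmer_pi0(grenander_fit(pv), pv.m).value
    except MethodInapplicable:
        pass
    return RepetitionOutcome(counts=counts, applicable=applicable, pi0_estimates=pi0_estimates)


def run_scenario(
    scn: SimulationScenario, methods: tuple[str, ...] = STUDY_METHODS
) -> ScenarioSummary:
    """Run all repetitions of one grid cell and summarize."""
    outcomes = []
    for rep in range(scn.reps):
        z, truth_null = simulate_scenario(scn, rep)
        outcomes.append(evaluate_rep(z_to_pvalue(z), truth_null, methods, scn.alpha))
    return summarize_scenario(scn, outcomes)


def summarize_scenario(
    scn: SimulationScenario, outcomes: list[RepetitionOutcome]
) -> ScenarioSummary:
    """Average power/specificity over applicable repetitions.

    Power is undefined (nan) when the scenario has no true alternatives;
    the false-positive count is the number of applicable repetitions with
    ``V >= 1``.
    """
    if not outcomes:
        raise PValueError("need at least one repetition to summarize")
    methods = sorted({name for o in outcomes for name in o.applicable})
    mean_power: dict[str, float] = {}
    mean_spec: dict[str, float] = {}
    fp_reps: dict[str, int] = {}
    n_app: dict[str, int] = {}
    for name in methods:
        cc = [o.counts[name] for o in outcomes if o.applicable.get(name)]
        n_app[name] = len(cc)
        if not cc:
            mean_power[name] = float("nan")
            mean_spec[name] = float("nan")
            fp_reps[name] = 0
            continue
        mean_power[name] = (
            float(np.mean([c.power for c in cc])) if scn.m1 > 0 else float("nan")
        )
        mean_spec[name] = (
            float(np.mean([c.specificity for c in cc])) if scn.m0 > 0 else float("nan")
        )
        fp_reps[name] = int(sum(c.V >= 1 for c in cc))
    pi0_est: dict[str, list[float]] = {}
    for est in ("storey", "strimmer"):
        vals = [o.pi0_estimates[est] for o in outcomes if est in o.pi0_estimates]
        if vals:
            pi0_est[est] = vals
    return ScenarioSummary(
        scenario=scn,
        mean_power=mean_power,
        mean_specificity=mean_spec,
        fp_reps=fp_reps,
        applicable_reps=n_app,
        pi0_estimates=pi0_est,
    )


def run_grid(
    ms: tuple[int, ...] = GRID_M,
    pi0s: tuple[float, ...] = GRID_PI0,
    betas: tuple[float, ...] = GRID_BETA,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    methods: tuple[str, ...] = STUDY_METHODS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full scenario grid.

    When ``pi0 = 1`` the alternative mean is a dead parameter, so that cell
    is computed once and reported for both beta values.  Returns a tidy
    summary frame (m, pi0, beta, method, power, specificity, fp_reps,
    applicable_reps) and a per-repetition pi0-estimate frame.
    """
    rows = []
    pi0_rows = []
    for m in ms:
        for pi0 in pi0s:
            cell_betas = betas[:1] if pi0 == 1.0 else betas
            summaries = {}
            for beta in cell_betas:
                scn = SimulationScenario(
                    m=m, pi0=pi0, beta=beta, reps=reps, alpha=alpha, seed=seed
                )
                logger.info("scenario m=%d pi0=%.2f beta=%.1f", m, pi0, beta)
                summaries[beta] = run_scenario(scn, methods)
            for beta in betas:
                summ = summaries.get(beta, summaries[cell_betas[0]])
                for name in sorted(summ.mean_power):
                    rows.append(
                        {
                            "m": m,
                            "pi0": pi0,
                            "beta": beta,
                            "method": name,
                            "power": summ.mean_power[name],
                            "specificity": summ.mean_specificity[name],
                            "fp_reps": summ.fp_reps[name],
                            "applicable_reps": summ.applicable_reps[name],
                        }
                    )
                for est, vals in summ.pi0_estimates.items():
                    for rep, v in enumerate(vals):
                        pi0_rows.append(
                            {
                                "m": m,
                                "pi0": pi0,
                                "beta": beta,
                                "estimator": est,
                                "rep": rep,
                                "pi0_hat": v,
                            }
                        )
    return pd.DataFrame(rows), pd.DataFrame(pi0_rows)
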