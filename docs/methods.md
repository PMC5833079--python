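# Methods

## Decision model

All procedures share one decision model. For `m` simultaneously tested
hypotheses, the unknown truth partitions them into `m0` true nulls and `m1`
true alternatives; a decision rule at level `α` keeps `U` and rejects `V` of
the nulls, keeps `T` and rejects `S` of the alternatives, with `R = V + S`
rejections in total. Power is `S/m1`, specificity `U/m0`. Every method is
represented internally as a vector of *adjusted* significance measures in
original input order; "significant" uniformly means adjusted value `≤ α`
(the inclusive convention — the boundary case is vanishingly rare with
continuous statistics, but a single convention keeps the nesting properties
exactly testable). Ties in the raw p-values are resolved by a stable sort,
and because every adjusted measure is a function of the sorted vector
followed by monotone enforcement (running minimum from the top for step-up
procedures, running maximum from the bottom for step-down), tied p-values
always receive identical adjusted values and every rejection set is a prefix
of the sorted p-values. Missing or out-of-range p-values are rejected at
input; there is no imputation.

## FWER procedures

Bonferroni, Holm and Hochberg are the textbook single-step/step-down/step-up
rules on `(m − i + 1)·p_(i)`. Hommel's procedure is computed by the standard
shortcut recursion over intersection sizes `j = m…2`, maintaining
per-hypothesis Simes minima; its correctness is pinned not by transcribing a
formula but by exhaustive closed testing: `closed_testing_oracle` enumerates
all `2^m − 1` intersection hypotheses, applies the Simes test
`min_k |I|·p_(k)/k ≤ α` to each, and rejects a hypothesis iff every
intersection containing it is rejected. The suite verifies
recursion ≡ oracle over random vectors with `m ≤ 8` at three levels. The
oracle refuses `m > 12` (enumeration cost), which is ample for validation.
No effort was spent optimising Hommel beyond O(m²): the package targets
small-to-moderate `m`, and the full study grid including `m = 1000` runs in
seconds.

The effective-number Bonferroni variant takes the number of independent
tests as a user input; estimating it (LD- or PCA-based) is out of scope
because it requires the correlation structure of a concrete panel.

## FDR control

Benjamini–Hochberg adjusts `m·p_(i)/i` step-up. Benjamini–Yekutieli
multiplies the BH values by `c(m) = Σ_{i≤m} 1/i`, computed by direct
summation. The two-stage adaptive procedure follows the canonical form of
its original definition: stage 1 is BH at `α′ = α/(1+α)`; with `r1`
rejections, `r1 = 0` (stop, reject nothing) and `r1 = m` (stop, reject all)
are terminal, otherwise stage 2 is BH at `α′·m/(m − r1)`. Two-stage
decisions depend on `α` beyond the final thresholding, so the result type
carries the decision set plus stage metadata (`r1`, `π0̂ = (m−r1)/m`, `α′`)
rather than pretending to a single adjusted-p vector; in the common method
registry the decisions at the evaluation level are encoded as 0/1
pseudo-adjusted values. Note that statsmodels' `fdr_tsbh` implements a
different variant (stage 2 compared against `α` rather than `α′`, no stop at
`r1 = 0`), so it is deliberately not used as a cross-check for this method;
the step-up controllers and all four FWER methods are cross-checked against
statsmodels exactly.

## Storey's π0 and q-values

The tail-count curve `π0(λ) = #{p > λ}/(m(1−λ))` is evaluated on the
conventional grid λ = 0.05, 0.10, …, 0.95 (configurable). For `m ≥ 38`
(twice the grid size) a cubic polynomial trend (≈3 effective degrees of
freedom) is fit to the curve and read off at the largest λ — the smoother
variant of the estimator. Below that, a cubic fit to 19 near-degenerate
points is noise, so the median of the curve is used instead; with a single
grid point the raw ratio is taken. The estimate is clamped into (0, 1].

When every p-value is small — exactly the situation that makes the reference
q-value implementation error out — all tail counts vanish and no valid
estimate exists. The estimator then shrinks the upper end of the λ grid one
step (0.05) at a time, recording the number of shrinkages in
`fallback_steps`, and if the grid is exhausted returns the terminal fallback
`max(π0(λ_min), 1/m)` with a logged warning, never an exception. Q-values
are the step-up monotone enforcement of `π0̂·m·p_(i)/i`; with `π0̂ = 1` they
are bit-for-bit the BH adjusted values (the two code paths share the same
arithmetic), and any `π0̂ < 1` scales them down — the source of the method's
extra power and of its reduced specificity at small `m`.

## Grenander density, π0 and local FDR

The Grenander estimator — the slopes of the least concave majorant (LCM) of
the p-value ECDF — is the maximum-likelihood nonincreasing density on
[0, 1], computed here by an upper-convex-hull scan over ECDF vertices
(equivalent to pool-adjacent-violators on slopes, O(m log m)).

Two boundary pathologies of the raw estimator require the "modified" form.
First, the ECDF reaches 1 at the largest observation, so the raw LCM's
terminal slope is identically zero whenever `max(p) < 1` — the terminal-slope
π0 estimate would degenerate to ~1/m and the local FDR would declare
everything significant. The fit therefore censors the null tail: a
pre-estimate `η0 = #{p > c}/(m(1−c))` at the censor point `c = 0.5` replaces
all ECDF vertices above `c` by the null line `1 − η0(1−p)`. Under the
two-groups model the region above 0.5 is overwhelmingly null, so the line is
exactly the shape the data carry there, and when `η0` is not clamped the
line meets the ECDF at `c`, leaving the fit below `c` untouched. The
terminal slope of the censored fit is then a stable, consistent π0 estimate
(floored at 1/m). A consequence: the majorant property `F̂ ≥ ECDF` holds
below the censor point; above it the fit follows the null line by design.

Second, the LCM's first slope is the supremum of `ECDF(t)/t`, which for
uniform p-values exceeds any λ with probability exactly 1/λ — a 5% chance of
a spurious slope ≥ 20 at the smallest observation. Density evaluation is
therefore right-continuous: a p-value sitting exactly on a breakpoint takes
the slope of the interval to its right (the convention of constant-mode
interpolation in the reference implementation). The boundary spike interval
then contains no observation in the common case, and the local FDR
`lfdr(p) = min(1, π0̂/f̂(p))` under a pure null flags a false positive in
roughly 0–2 of 100 repetitions at `m = 1000` rather than ~5. Tail-area
q-values are `π0̂·p/F̂(p)` with `F̂` the LCM CDF (at `p = 0` the limit
`π0̂/f̂(0)` is used), made monotone step-up. Since `F̂` is concave with
`F̂(0) = 0`, `F̂(p)/p ≥ f̂(p)` and the q-values tend to sit below the lfdr
values — the documented source of the q-value method's extra power; the
suite checks this as a statistical tendency, not a per-value theorem.

The local FDR is refused (`MethodInapplicable`) for fewer than 2 distinct
p-values or `m < min_m` (default 8): a density estimate from a handful of
points is noise. This mirrors the reported gaps of the reference local-FDR
implementation at very small `m` without claiming to reproduce its exact
failure boundary; inapplicable repetitions are recorded as missing in all
summaries, with the applicable count reported alongside.

## Simulation study

The grid crosses `m ∈ {4, 8, 16, 32, 64, 1000}`, `π0 ∈ {25, 50, 75, 100}%`
and `β ∈ {1.0, 2.5}`, 100 repetitions per cell, cutoff 0.05. Each
repetition draws `round(π0·m)` statistics from N(0, 1) and the rest from
N(β, 1) (all alternatives share the same positive mean; no sign mixing),
transformed to two-sided p-values `2(1 − Φ(|z|))`. Per cell the harness
reports each method's mean power, mean specificity (equally weighted over
repetitions), and the count of repetitions with `V ≥ 1` — both over
applicable repetitions, with the applicable count exported so either
denominator convention can be recovered. When `π0 = 100%`, β is a dead
parameter: the cell is computed once and reported for both β values. Power
is undefined (NaN) there since `m1 = 0`.

Randomness is seeded per (scenario, repetition) through
`numpy.random.SeedSequence` keyed on the base seed and the scenario
parameters, so runs are reproducible end to end and any repetition can be
replayed in isolation. The full grid (42 distinct cells × 100 repetitions ×
8 methods) completes in roughly 20 seconds on one CPU.

## Synthetic discovery→replication screen

The screening workflow emulates a two-stage consortium analysis at desk
scale. The generator produces two non-overlapping study sets sharing one
truth vector: by default 200 independent features of which 20 carry a true
effect of 0.05 trait-SD units, 10 discovery and 5 replication studies with
per-study sample sizes uniform on [4000, 12000] (≈2:1 discovery:replication
sample ratio) and per-study estimates `effect + N(0, SE²)`,
`SE = σ/√n_study`. These defaults were chosen once as a realistic downsized
genetic-consortium screen — effects of a few hundredths of an SD, tens of
thousands of samples, a minority of features with signal — and are fully
configurable. What the generator deliberately does *not* emulate: linkage
disequilibrium between features (independence stands in for post-pruning
index variants, so no clumping step exists), allele/strand bookkeeping,
imputation quality, or between-study heterogeneity. Passing screens here
demonstrate the statistical pipeline, not robustness to those real-data
complications.

The pipeline meta-analyses each feature with inverse-variance weights
(`w = 1/SE²`, pooled effect `Σw·β̂/Σw`, pooled `SE = 1/√Σw`), applies
genomic control on the discovery side — `λ_GC = median(z²)/F⁻¹_{χ²₁}(½)`,
SEs inflated by `√λ_GC` only when `λ_GC > 1` (the SE-scale form; never
deflated) — selects index features at discovery `p < 10⁻⁶` (strict, as a
selection threshold rather than a significance test), and applies every
registered method to the replication p-values of the selected features
only. Replication is meta-analysed without genomic control, matching
standard practice for pre-selected hypotheses. The report carries
per-method counts, membership lists (nested by construction of the
procedures), and discovery/replication effect-sign consistency flags.

## Numerical choices and limitations

- Adjusted values are clamped to [0, 1] after every transformation;
  comparisons use the inclusive `≤ α`.
- `c(m)` by direct summation; no asymptotic approximation.
- The genomic-control null constant is scipy's exact χ²(1 df) median
  (0.454936…), not the rounded 0.45494.
- The λ-fallback step (0.05) and the censor point (0.5) are pragmatic
  defaults, configurable at the call sites; results at `m ≥ 64` are
  insensitive to both within reasonable ranges.
- The Grenander-based estimators here are this package's own simplification
  of the published censored estimator; they satisfy the documented
  structural properties (nonincreasing density, unit mass, censored-majorant
  CDF, terminal-slope π0) but are not claimed to match any external
  implementation decision-for-decision.
- Correlated test statistics are out of scope throughout the simulation
  harness: all statistics are drawn independently, so the study quantifies
  behaviour under independence only.
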