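# mtlab — FWER/FDR control and estimation in low-dimensional multiple testing

When a discovery screen (a GWAS, a metabolomics panel, an expression study)
tests up to millions of hypotheses, and its replication stage re-tests only a
handful, both stages need a correction for multiple testing — but the methods
behave very differently when the number of hypotheses `m` is small. `mtlab`
implements the eight standard procedures side by side and provides the
simulation machinery to measure their power, specificity and
null-proportion estimation accuracy exactly where they are most often
misapplied: at small `m`.

## The procedures

With `m` hypotheses, ordered p-values `p_(1) ≤ … ≤ p_(m)`, overall level `α`
and `π0` the proportion of true nulls:

**Family-wise error rate control** (`Pr(V > 0) ≤ α`, `V` = false positives):

- *Bonferroni*: reject `p_i ≤ α/m`; adjusted `min(1, m·p_i)`. The
  effective-number variant divides by the number of *independent* tests
  instead (e.g. `0.05 / 10⁶ = 5×10⁻⁸` in European-ancestry GWAS).
- *Holm* (step-down) and *Hochberg* (step-up): rank-dependent thresholds
  `α/(m−i+1)`; Hochberg additionally assumes positive regression dependency.
- *Hommel*: closed testing of all intersection hypotheses with Simes local
  tests, via the standard shortcut recursion; the most powerful of the four.
  A brute-force closed-testing oracle (`closed_testing_oracle`) validates it
  for `m ≤ 12`.

**FDR control** (`E[V/R | R>0]·Pr(R>0) ≤ α`):

- *Benjamini–Hochberg*: step-up on `m·p_(i)/i`.
- *Two-stage adaptive*: BH at `α′ = α/(1+α)` estimates `π0̂ = (m−r1)/m`,
  then BH again at `α′/π0̂`.
- *Benjamini–Yekutieli*: BH times `c(m) = Σ 1/i`, valid under arbitrary
  dependency.

**FDR estimation** (per-hypothesis error measures):

- *Storey's q-value*: `π0̂` from tail counts `#{p > λ}/(m(1−λ))` over a λ
  grid with a smooth trend read off at `λ = 0.95`, with a stepwise
  grid-shrinking fallback when all p-values are small;
  `q_(i) = π0̂·m·p_(i)/i` made monotone. With `π0̂ = 1` this *is* BH.
- *Grenander q-value and local FDR*: the maximum-likelihood nonincreasing
  p-value density (slopes of the least concave majorant of the ECDF, with a
  null-tail censoring modification), giving `π0̂` as the terminal slope,
  `lfdr(p) = π0̂/f̂(p)` and `q(p) = π0̂·p/F̂(p)`.

On any input the rejection sets nest: Bonferroni ⊆ Holm ⊆ Hochberg ⊆ Hommel,
BY ⊆ BH ⊆ Storey-q — the test suite enforces these chains property-wise.

The package also ships a discovery→replication screening workflow on
synthetic consortium data: inverse-variance fixed-effect meta-analysis,
genomic-control inflation correction (`λ_GC = median(z²)/0.4549`), index
selection at `p < 10⁻⁶`, and application of all eight methods to the
replication p-values.

## A worked example

`examples/03_power_simulation.py` runs 100 repetitions of the power study at
`π0 = 50%`, effect size `β = 2.5`:

```
m = 8 hypotheses (pi0 = 50%, beta = 2.5, 100 reps)
          method   power  specificity  fp reps
              by   0.395        0.983        6
      bonferroni   0.410        0.988        4
            lfdr   0.427        0.968       10
          hommel   0.445        0.980        7
              bh   0.545        0.965       12
            tsbh   0.583        0.950       15
   qvalue-storey   0.688        0.880       25
 qvalue-strimmer   0.738        0.863       31
```

Power is the average share of true signals detected, specificity the average
share of true nulls kept, `fp reps` the number of repetitions with at least
one false positive. The q-value methods are the most powerful but pay for it
with clearly reduced specificity at small `m` — the central practical message:
prefer FWER methods when re-testing a handful of hypotheses, reserve
`π0`-estimating methods for sizeable data sets.

Other entry points: `examples/01_adjust_pvalues.py` (all adjusters on one
vector), `examples/02_pi0_and_lfdr.py` (π0 estimation and local FDR),
`examples/04_replication_screen.py` (the synthetic two-set screen), and a thin
CLI:

```bash
mtlab adjust --method bh --alpha 0.05 --in pvalues.tsv --out decisions.tsv
mtlab simulate --config study.yaml --out results/
mtlab screen --simulate --seed 7 --out results/
```

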