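"""Power and specificity of all eight procedures on a slice of the study grid.

Runs 100 repetitions at m in {8, 64, 1000} hypotheses with 50% true nulls
and a strong effect (beta = 2.5), printing each method's average power
(share of true signals detected), average specificity (share of true
nulls kept) and the number of repetitions with at least one false
positive.  FDR-estimating methods buy power at the cost of specificity,
most visibly at small m.
"""

from mtlab.simulation import run_grid

summaries, _ = run_grid(ms=(8, 64, 1000), pi0s=(0.5,), betas=(2.5,),
                        reps=100, seed=42)
for m, sub in summaries.groupby("m"):
    print(f"\nm = {m} hypotheses (pi0 = 50%, beta = 2.5, 100 reps)")
    print(f"{'method':>16} {'power':>7} {'specificity':>12} {'fp reps':>8}")
    for _, row in sub.sort_values("power").iterrows():
        power = "  n/a" if row.applicable_reps == 0 else f"{row.power:5.3f}"
        spec = "   n/a" if row.applicable_reps == 0 else f"{row.specificity:6.3f}"
        print(f"{row.method:>16} {power:>7} {spec:>12} {row.fp_reps:>8}")
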