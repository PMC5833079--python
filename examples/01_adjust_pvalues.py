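"""Adjust a handful of p-values with every procedure in the registry.

A replication-style situation: ten features re-tested in an independent
sample, a few with genuine signal.  Prints each method's adjusted
significance measures and how many hypotheses it declares significant at
the 0.05 cutoff — watch the FWER methods (bonferroni ... hommel) reject
fewer hypotheses than the FDR controllers (by, bh, tsbh), which in turn
reject no more than the estimation-based q-values.
"""

import numpy as np

from mtlab import PValueVector, STUDY_METHODS, adjusted_values, decide

p = np.array([2e-5, 1e-4, 8e-4, 0.004, 0.011, 0.028, 0.21, 0.44, 0.68, 0.93])
pv = PValueVector(p, ids=tuple(f"region{i+1}" for i in range(10)))
alpha = 0.05

print(f"{'method':>16}  R  adjusted values")
for name in ("bonferroni", "holm", "hochberg") + STUDY_METHODS[1:]:
    adj = adjusted_values(name, pv, alpha)
    dec = decide(adj, alpha)
    shown = " ".join(f"{v:.3f}" for v in adj.values)
    print(f"{name:>16}  {dec.R}  {shown}")
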