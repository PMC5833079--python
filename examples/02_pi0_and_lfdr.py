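"""Estimate the proportion of true nulls and per-hypothesis error measures.

Simulates 1000 z-statistics of which half carry a mean shift of 2.5, then
runs both pi0 estimators (Storey's lambda-grid tail counts and the
Grenander terminal slope) and derives q-values and local FDR values.  The
printed pi0 estimates should land near the true 0.5; the smallest
p-values get q-values and lfdr far below 0.05, the largest saturate near 1.
"""

import numpy as np

from mtlab import (
    PValueVector,
    grenander_fit,
    storey_pi0,
    storey_qvalues,
    strimmer_lfdr,
    strimmer_pi0,
    strimmer_qvalues,
)
from mtlab.simulation import z_to_pvalue

rng = np.random.default_rng(2018)
z = np.concatenate([rng.standard_normal(500), rng.standard_normal(500) + 2.5])
pv = PValueVector(z_to_pvalue(z))

sto = storey_pi0(pv)
den = grenander_fit(pv)
gre = strimmer_pi0(den, pv.m)
print(f"true pi0 = 0.5")
print(f"Storey pi0-hat    = {sto.value:.3f}  ({sto.method}, fallbacks={sto.fallback_steps})")
print(f"Grenander pi0-hat = {gre.value:.3f}  (terminal slope of the censored LCM)")

q_sto = storey_qvalues(pv, sto).qvalues
q_str = strimmer_qvalues(pv, den, gre).qvalues
lfdr = strimmer_lfdr(pv, den, gre).lfdr
order = np.argsort(pv.values)
print("\n   p-value   q(Storey)  q(Grenander)   lfdr")
for i in np.concatenate([order[:3], order[-2:]]):
    print(f"{pv.values[i]:10.2e} {q_sto[i]:10.3f} {q_str[i]:12.3f} {lfdr[i]:7.3f}")
print(f"\nsignificant at 0.05: q-Storey {np.sum(q_sto <= 0.05)}, "
      f"q-Grenander {np.sum(q_str <= 0.05)}, lfdr {np.sum(lfdr <= 0.05)} of {pv.m}")
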