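"""Why the chi-square log-rank p-value misleads for rare hotspots.

Draws a null cohort of 400 patients with a 4-patient minority group — no
survival difference whatsoever — and compares the classical chi-square
log-rank p-value with the two-sided p from the conditional permutation
null.  With groups this unbalanced the permutation null of the signed
statistic L is discrete, skewed and often multimodal, and the chi-square
approximation can be off by an order of magnitude in either direction.
"""

import numpy as np

from hotspotsurv import (
    asymptotic_p,
    empirical_p,
    exact_null,
    logrank_statistic,
    simulate_survival_sample,
)

rng = np.random.default_rng(2024)

print("replicate    L      p_chisquare  p_empirical")
gaps = []
for i in range(10):
    sample = simulate_survival_sample(rng, n=400, n1=4, censoring_fraction=0.3)
    L, V = logrank_statistic(sample)
    null = exact_null(sample, seed=i, n_perm_per_stratum=2000)
    p_chi = asymptotic_p(L, V)
    p_emp = empirical_p(null, L)
    gaps.append(abs(p_chi - p_emp))
    print(f"{i:>9} {L:>7.2f} {p_chi:>12.4f} {p_emp:>12.4f}")

print(f"\nmean |difference| over 10 null replicates: {np.mean(gaps):.3f}")
print("Both columns test the same null data; every large gap is purely the")
print("chi-square approximation failing at n1=4.  The permutation p is the")
print("one calibrated for screening rare hotspot carriers.")
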