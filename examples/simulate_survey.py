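"""Check estimator calibration by simulation.

Draws 1,000 genotype samples at the parameters estimated from a real
survey sample (N = 42, fR = 0.452, f = -0.627) and re-estimates F_IS from
each; the mean recovered value should sit close to the simulated truth.
Also verifies that the exact Hardy-Weinberg test keeps its size: under
the null (f = 0) no more than ~5% of samples should reject at alpha 0.05
(the exact test is conservative, so the rate is usually below it).
"""

import numpy as np

from capskit import PopulationSimSpec, fis_weir_cockerham, hwe_exact_test, simulate_populations

reps = simulate_populations(PopulationSimSpec(N=42, fR=0.452, f=-0.627, seed=42), 1000)
fis = [f for _, _, f in map(fis_weir_cockerham, reps) if f is not None]
print(f"simulated f = -0.627; mean recovered Fis over {len(fis)} replicates: {np.mean(fis):.3f}")

null = simulate_populations(PopulationSimSpec(N=50, fR=0.3, f=0.0, seed=43), 2000)
p = np.array([hwe_exact_test(c) for c in null])
print(f"null rejection rate at alpha=0.05: {np.mean(p <= 0.05):.3f} (exact test is conservative)")
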