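"""Mendelian transmission law and rare-variant weights.

Builds the conditional offspring-dosage table for every parental genotype
pair, then shows how Beta(1,25) weights grade variants by parental minor
allele frequency.
"""

import numpy as np

from trioskat import TRANSMISSION_TABLE, beta_weights

print("P(offspring dosage | father, mother) and conditional mean:")
for (gf, gm), probs in TRANSMISSION_TABLE.probabilities.items():
    mean = TRANSMISSION_TABLE.means[(gf, gm)]
    var = TRANSMISSION_TABLE.variances[(gf, gm)]
    print(f"  parents ({gf},{gm}): P(0,1,2) = {np.round(probs, 3)}  "
          f"E = {mean:.1f}  Var = {var:.2f}")

print()
print("The mean is always (gf+gm)/2; only heterozygous parents contribute")
print("transmission variance (0.25 each), which is what the kernel test uses.")

freqs = np.array([0.005, 0.01, 0.05, 0.1, 0.3])
w = beta_weights(freqs, a=1.0, b=25.0)
print()
print("Beta(1,25) weights by parental MAF (rarer variants weigh more):")
for f, wj in zip(freqs, w):
    print(f"  MAF {f:5.3f} -> weight {wj:8.4f}")
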