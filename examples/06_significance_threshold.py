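"""Binomial significance thresholds for decoding accuracy.

The theoretical chance level (100/c %) holds only asymptotically; for a finite
cohort the 95th percentile of null accuracy comes from the inverse binomial
CDF: St = binoinv(1 - alpha, n, 1/c) * 100 / n.
"""

from srcnet import chance_level, significance_threshold

print(f"chance level, 2 classes: {chance_level(2):.0f} %")
for n in (238, 119, 40):
    st = significance_threshold(n, 2, alpha=0.05)
    print(f"n = {n:3d}: accuracy must exceed {st:5.2f} % to beat chance at p < 0.05")
print("\nSmaller cohorts need a larger margin over 50% before a decoding"
      "\naccuracy is statistically distinguishable from coin flipping.")
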