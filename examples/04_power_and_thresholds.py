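"""Analytic statistics: Bonferroni thresholds and detectable effect sizes.

The battery tests four measures per ERP component, so each family uses a
corrected threshold alpha/4.  The Fisher-z power approximation gives the
smallest correlation detectable at 80% power for a given sample size.
"""

from salience_cpt import bonferroni_threshold, min_detectable_r

alpha = 0.05
print(f"per-test threshold at alpha={alpha}, m=4: "
      f"{bonferroni_threshold(alpha, 4):.4f}")

print("\nminimum detectable |r| (two-tailed alpha 0.05, power 0.80):")
for n in (20, 31, 50, 100, 200):
    print(f"  n={n:>3}: {min_detectable_r(n):.3f}")
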