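"""Treated-vs-control chromatin texture: the five-feature signature.

Simulates a small study (5 coverslips per arm), segments nuclei from the
DAPI channel, measures the five GLCM texture features per nucleus, averages
them per sample, and reports the percent change of the treated arm over
the control arm plus two-tailed Mann-Whitney p-values.

A clumped (heterochromatin-rich) arm should show ASM, correlation and IDM
falling while entropy and contrast rise — the classic texture signature of
chromatin condensation after DNA-damaging treatment — and the pattern
interpreter should translate that into "homogeneity decreased,
heterogeneity and contrast increased".
"""

from chromatex import texture_arm_study

study = texture_arm_study(n_seeds=5, seed=1)

print("percent change, treated over control:")
for feat, change in study["percent_change"].items():
    print(f"  {feat:12s} {change:+8.1f} %")

print("\ntwo-tailed Mann-Whitney per feature (per-sample means, n=5 vs 5):")
for cmp_ in study["comparisons"]:
    print(f"  {cmp_.parameter:12s} U={cmp_.statistic:5.1f}  p={cmp_.p_value:.4f}  ({cmp_.method})")

p = study["pattern"]
print(f"\nchromatin pattern call: homogeneity {p.homogeneity}, "
      f"heterogeneity {p.heterogeneity}, contrast {p.contrast_pattern}")
print("\nNegative ASM/correlation/IDM changes with positive entropy/contrast mean "
      "the treated nuclei are less uniform, more disordered and more contrasted.")
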