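"""Exact two-tailed Mann-Whitney U for the tiny group sizes of animal studies.

With 3 samples per group there are only C(6,3) = 20 rank assignments, so
p-values come from exact enumeration rather than the normal approximation.
Complete separation of two groups of three gives U = 0 and p = 2/20 = 0.1 —
the smallest two-tailed p attainable at these sizes.
"""

from chromatex import mann_whitney_u, t_test

r = mann_whitney_u([1, 2, 3], [10, 20, 30])
print(f"MWU, complete separation 3 vs 3: U={r.statistic:.0f}, p={r.p_value}, "
      f"method={r.method}")

r = mann_whitney_u([1.2, 3.4, 2.2, 5.0], [4.1, 6.3, 7.2, 8.0, 5.5])
print(f"MWU, overlapping 4 vs 5:        U={r.statistic:.0f}, p={r.p_value:.4f}, "
      f"method={r.method}")

r = t_test([1, 2, 3], [4, 5, 6])
print(f"pooled t-test, 3 vs 3:          t={r.statistic:.3f}, p={r.p_value:.4f}")
print("\nExact Mann-Whitney p-values never dip below what the group sizes can "
      "support, which matters when comparing a handful of xenograft samples.")
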