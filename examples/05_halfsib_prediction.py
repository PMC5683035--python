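"""Across-population prediction between half-sib crosses.

Pairs of populations sharing one parent are genotyped on partially
overlapping panels; prediction uses only the shared markers, re-coded so
+1 means the shared parent's allele in both crosses. When the simulated
trait's QTL lie outside the common-marker set, transferred effects carry
no causal signal and accuracies centre on zero — the hard lesson of
cross-population prediction with few common low-density markers.
"""

from biparpred.study import halfsib_null_study

df = halfsib_null_study(n_pairs=5, master_seed=17)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(f"mean common markers: {df['n_common_markers'].mean():.0f} "
      f"(per-population panels of ~180 SNPs overlap in ~44-100 sites)")
print(f"mean r_MG = {df['r_mg'].mean():.3f}, "
      f"{(df['r_mg'] > 0).mean() * 100:.0f}% of predictions above zero — "
      "centred on zero, unlike within-population prediction")
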