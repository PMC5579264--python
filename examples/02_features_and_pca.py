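"""Acoustic parameters and principal components of DP2 phrases.

Extracts the temporal parameter set (unit durations, inter-unit intervals,
inter-onset intervals, total duration) from synthetic DP2 phrases, then
reduces it with a correlation-matrix PCA keeping components whose
eigenvalue exceeds 1 (Kaiser criterion).
"""

import songkin as sk
from songkin.features import META_COLUMNS

ped = sk.study_pedigree()
phrases = [p for p in sk.simulate_phrases(ped, seed=2)
           if p.phrase_type == "DP2"]

ft = sk.feature_table(phrases, "temporal")
cols = [c for c in ft.columns if c not in META_COLUMNS]
print(f"{len(ft)} phrases x {len(cols)} temporal parameters: {cols}")

pca = sk.pca_kaiser(ft[cols].set_axis(ft["phrase_id"], axis=0))
print(f"retained {pca.n_retained} components "
      f"(eigenvalue > 1) explaining {pca.cum_var_pct:.1f}% of the variance")
for comp in pca.loadings.columns:
    top = pca.loadings[comp].abs().idxmax()
    print(f"  {comp}: highest loading {top} "
          f"({pca.loadings.loc[top, comp]:+.2f})")
# The retained standardized scores are what the distance matrices, Mantel
# tests and pDFA consume downstream.
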