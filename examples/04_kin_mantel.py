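"""Mantel tests: song dissimilarity against genetic distance, and the
father-son kin-category variant.

Simulates a dataset with father-to-son transmission of the temporal
parameters (h = 0.8), builds the normalized individual-level acoustic
dissimilarity matrix and the genetic distance matrix (1 - normalized
relatedness), and runs the matrix permutation tests.
"""

import numpy as np

import songkin as sk
from songkin.features import META_COLUMNS
from songkin.songsim import SongEffectConfig, Transmission

ped = sk.study_pedigree()
cfg = SongEffectConfig(
    transmission={"temporal": Transmission("sexpath", h=0.0, h_father_son=0.8),
                  "frequency": Transmission()})
phrases = [p for p in sk.simulate_phrases(ped, cfg, seed=3)
           if p.phrase_type == "DP2"]

ft = sk.feature_table(phrases, "temporal")
cols = [c for c in ft.columns if c not in META_COLUMNS]
pca = sk.pca_kaiser(ft[cols].set_axis(ft["phrase_id"], axis=0))
d_phrase = sk.phrase_distance(pca.scores)
mapping = dict(zip(ft["phrase_id"].astype(str), ft["individual_id"].astype(str)))
d_ind = sk.normalize01(sk.individual_mean_distance(d_phrase, mapping))

gt = sk.simulate_genotypes(ped, sk.default_loci(), seed=4)
g_dist = sk.relatedness_to_distance(sk.dyadic_ml(gt))

for label, inds in (
        ("overall", list(d_ind.labels)),
        ("males", [i for i in d_ind.labels if ped[i].sex == "M"]),
        ("females", [i for i in d_ind.labels if ped[i].sex == "F"])):
    res = sk.mantel_test(d_ind.submatrix(inds), g_dist.submatrix(inds),
                         n_perm=9999, seed=5)
    print(f"Mantel {label:<8} n={res.n:<3} r={res.r:+.3f} p={res.p:.4f}")

design = sk.parent_offspring_design(ped, "M", "M", present=d_ind.labels)
kin = sk.kin_category_mantel(d_ind, design, n_perm=9999, seed=6)
print(f"father-son kin-category Mantel: n_sons={kin.n} "
      f"r={kin.r:+.3f} p={kin.p:.4f}")
# A positive r with small p says sons' phrases resemble their own father's
# more than other fathers' phrases (and likewise for the population-level
# tests: more related, more acoustically similar).
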