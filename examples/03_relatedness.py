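"""Pairwise relatedness estimation and the estimator-selection simulation.

Simulates 100 dyads of each known relatedness category (parent-offspring,
full-sibling, half-sibling, unrelated) from the locus allele frequencies,
applies four moment estimators and the dyadic likelihood estimator, and
ranks them by pooled correlation with the true r.  Then estimates the
all-pairs matrix for a simulated study population.
"""

import numpy as np

import songkin as sk

loci = sk.default_loci()
report = sk.compare_estimators(loci, n_per_category=100, seed=7)
print("estimator ranking (pooled correlation with true r):")
for est in report.ranking:
    print(f"  {est:<18} {report.correlations[est]:.3f}")
print("\nmean r-hat per known category (best estimator):")
best = report.summary.loc[report.best]
for cat, row in best.iterrows():
    print(f"  {cat:<17} {row['mean']:+.3f} (sd {row['sd']:.3f})")

ped = sk.study_pedigree()
gt = sk.simulate_genotypes(ped, loci, seed=1)
rm = sk.relatedness_matrix(gt, estimator="dyadic_ml")
founders = [i.id for i in ped.founders()]
adults = [rm.matrix.values[rm.matrix.index_of(a), rm.matrix.index_of(b)]
          for i, a in enumerate(founders) for b in founders[i + 1:]]
po = [rm.matrix.values[rm.matrix.index_of(o.id), rm.matrix.index_of(o.father)]
      for o in ped.offspring()]
print(f"\nstudy population ({rm.estimator}): "
      f"median r unrelated adults {np.median(adults):.2f}, "
      f"median r parent-offspring {np.median(po):.2f}")
# True values are 0 and 0.5; with six loci individual estimates scatter
# widely but the category medians separate cleanly.
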