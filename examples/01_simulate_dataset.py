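"""Generate a synthetic study population and its song/genotype dataset.

Builds the default seven-group population (a reproductive pair plus 0-2
offspring per group), drops six-locus microsatellite genotypes through the
pedigree, and renders descending phrases (DP2/DP3) for every individual.
"""

from pathlib import Path

import songkin as sk

out = Path("example_output/dataset")
out.mkdir(parents=True, exist_ok=True)

ped = sk.study_pedigree()
gt = sk.simulate_genotypes(ped, sk.default_loci(), seed=1)
phrases = sk.simulate_phrases(ped, seed=2)

ped.to_csv(out / "pedigree.csv")
gt.to_csv(out / "genotypes.csv")
sk.write_phrases(phrases, out / "phrases.csv", out / "contours.csv")

sons = [o for o in ped.offspring() if o.sex == "M"]
print(f"{len(ped)} individuals in {len(ped.groups)} groups "
      f"({len(ped.offspring())} offspring, {len(sons)} sons)")
print(f"{len(phrases)} phrases "
      f"({sum(p.phrase_type == 'DP2' for p in phrases)} DP2, "
      f"{sum(p.phrase_type == 'DP3' for p in phrases)} DP3)")
first = phrases[0]
u = first.units[0]
print(f"example phrase {first.phrase_id}: unit 1 spans "
      f"[{u.start:.2f}, {u.end:.2f}] s, f0 {u.f0[0]:.0f} -> {u.f0[-1]:.0f} Hz")
# Each group's members share chorus songs (the song id is the pDFA control
# factor); genotypes obey Mendelian transmission at every locus.
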