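"""Simulate a two-cohort trout broodstock and look at what comes out.

Builds the default population: 83 dams x 71 sires in 7 factorial plans bred
from a shared grandparent pool, ~1350 offspring genotyped on a multi-
chromosome SNP map, and seven correlated reproduction traits (spawning date
SD, body weights FW/PW, spawn weight SW, egg number EN, egg weight EW, egg
diameter ED) with cohort / overmature / spawning-week fixed effects.
"""

import numpy as np

from roegen.simdata import GenomeMap, MatingDesign, simulate_study

study = simulate_study(
    seed=1,
    design=MatingDesign.default(total_offspring=1346),
    genome=GenomeMap.uniform(n_chromosomes=10, n_snps_per_chrom=150, length_mb=25.0),
    missing_rate=0.01,
)

ped = study.pedigree
phe = study.phenotypes
print(f"pedigree: {len(ped)} individuals "
      f"({len(ped.founders)} founders, {len(phe)} phenotyped offspring)")
print(f"genotypes: {study.genotypes.n_samples} x {study.genotypes.n_snps} SNPs, "
      f"{100 * study.genotypes.missing_mask().mean():.1f}% missing")
print("\nphenotype summary (trait means should sit near the broodstock values,")
print("e.g. ~187 g spawn weight, ~4700 eggs, ~40 mg egg weight, ~4 mm diameter):")
print(phe[["SD", "FW", "PW", "SW", "EN", "EW", "ED"]].describe().loc[["mean", "std"]].round(2))

u = study.truth.u[ped.index_of(phe["id"])]
h2_real = u.var(axis=0) / (u.var(axis=0) + np.diag(study.model.Ve))
print("\nrealized heritability of the simulated breeding values per trait")
print("(compare with the generating values 0.27-0.44):")
for t, h in zip(study.truth.traits, h2_real):
    print(f"  {t}: {h:.2f}")
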