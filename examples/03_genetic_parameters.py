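"""Estimate heritabilities and genetic correlations with multi-trait AI-REML.

Four 4-trait animal models (body weight + spawning date + one egg-size and
one egg-quantity trait) are fitted on the pedigree relationship matrix A and
averaged; the near-unity pairs (FW-PW, SW-EN, EW-ED) come from dedicated
bivariate models. Cohort, overmature flag and spawning week are fixed effects.
"""

from roegen.kinship import pedigree_relationship_matrix
from roegen.mixedmodel import estimate_parameter_table
from roegen.simdata import GenomeMap, MatingDesign, simulate_study

study = simulate_study(
    seed=3, design=MatingDesign.default(total_offspring=1000),
    genome=GenomeMap.uniform(6, 100, 25.0), missing_rate=0.0,
)
kin_a = pedigree_relationship_matrix(study.pedigree)
params = estimate_parameter_table(study.phenotypes, kin_a,
                                  reml_kwargs={"tol": 1e-6, "max_iter": 60})

print("heritabilities (generating values: SD 0.27, FW 0.30, PW 0.33, SW 0.32,")
print("EN 0.24, EW 0.27, ED 0.44):")
for t in params.traits:
    print(f"  {t}: {params.h2[t]:.2f} (se {params.h2_se[t]:.2f})")

print("\ngenetic correlations (upper triangle):")
print(params.rg.round(2).to_string())
print("\nkey pairs: rg(SW,EN) ~ 0.86 and rg(EW,ED) ~ 0.99 in the generating")
print("model; the body weights should be essentially uncorrelated with the")
print("egg traits.")
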