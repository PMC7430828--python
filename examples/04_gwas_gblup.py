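"""GBLUP-based GWAS with a planted QTL.

A QTL carrying 15% of the genetic variance of egg diameter is planted on
chromosome 3. SNP effects are back-solved from the GEBVs, tested against the
1% Bonferroni thresholds, and the significant peak gets a 1.5-log drop-off
confidence interval (1 Mb sliding window).
"""

import numpy as np

from roegen.gwas_gblup import detect_qtl_gblup, gwas_scan, significance_thresholds
from roegen.kinship import genomic_relationship_matrix
from roegen.mixedmodel import build_design, default_design_for, reml_estimate, solve_mme
from roegen.simdata import GenomeMap, MatingDesign, QtlSpec, TraitModel, simulate_study

genome = GenomeMap.uniform(8, 150, 25.0)
qtl_index = 2 * 150 + 75  # middle of chromosome 3
model = TraitModel.default(qtls=[QtlSpec(snp_index=qtl_index, var_fraction={"ED": 0.15})])
study = simulate_study(seed=4, design=MatingDesign.default(total_offspring=1000),
                       genome=genome, model=model, missing_rate=0.0)

phe = study.phenotypes
gen = study.genotypes_complete.subset(samples=list(phe["id"]))
gk = genomic_relationship_matrix(gen)
X, _ = build_design(phe, default_design_for("ED"))
y = phe["ED"].to_numpy()
vc = reml_estimate(y[:, None], [X], K=gk.G, traits=["ED"], tol=1e-6)
print(f"GBLUP heritability of ED: {vc.h2[0]:.2f}")

fit = solve_mme(y[:, None], [X], list(phe["id"]), gk, vc.Vg, vc.Ve,
                traits=["ED"], compute_pev=True)
scan = gwas_scan(fit, gen, gk, trait="ED")
thr = significance_thresholds(len(scan), n_chromosomes=8)
print(f"thresholds: chromosome-wide {thr.chromosome_wide_1dp}, "
      f"genome-wide {thr.genome_wide_1dp} (-log10 p)")

peak = scan.loc[scan["minus_log10_p"].idxmax()]
truth = genome.to_frame().iloc[qtl_index]
print(f"planted QTL: {truth['chrom']} @ {truth['pos'] / 1e6:.2f} Mb")
print(f"scan peak:   {peak['chrom']} @ {peak['pos'] / 1e6:.2f} Mb, "
      f"-log10 p = {peak['minus_log10_p']:.1f}")

for r in detect_qtl_gblup(scan, gen, gk, n_chromosomes=8):
    print(f"QTL region {r.chrom} [{r.start / 1e6:.2f}, {r.end / 1e6:.2f}] Mb, "
          f"peak {r.peak_stat:.1f}, {r.var_explained_pct:.1f}% of genomic variance")
print("(the region should cover the planted position; note the GBLUP point")
print("estimate shrinks single-SNP effects heavily, so its variance share")
print("understates the planted 15% — the Bayesian scan estimates it better)")
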