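"""Derive the analysis traits from raw spawn measures and run quality control.

ED = 50-egg length / 50; EW = 1000 * spoon weight / spoon count (2.5 ml
spoon); EN = round(1000 * SW / EW); SD = within-cohort week rank capped at 5.
SNPs must pass call rate > 0.97, Hardy-Weinberg p > 1e-4 and MAF > 0.05;
phenotypes more than 4 SD from the trait mean are discarded.
"""

from roegen.qc import (
    apply_outlier_filter,
    count_mendelian_errors,
    derive_reproduction_traits,
    fill_missing_genotypes,
    snp_qc,
)
from roegen.simdata import GenomeMap, MatingDesign, simulate_study

study = simulate_study(
    seed=2, design=MatingDesign.default(total_offspring=600),
    genome=GenomeMap.uniform(6, 100, 25.0), missing_rate=0.01,
)

raw = study.phenotypes.drop(columns=["EW", "EN", "ED"])  # keep only raw measures
derived = derive_reproduction_traits(raw)
print("derived traits from raw spoon/length measures (first 3 fish):")
print(derived[["id", "SW", "EW", "EN", "ED", "SD"]].head(3).round(2).to_string(index=False))

filtered, report = apply_outlier_filter(derived, ["SW", "EW", "EN", "ED"])
print("\noutlier removals per trait (|x - mean| > 4 SD):")
print(report.to_string(index=False))

kept, qc_report = snp_qc(study.genotypes, hwe_samples=study.pedigree.founders)
print(f"\nSNP QC: {qc_report['kept'].sum()} of {len(qc_report)} SNPs retained")
print(qc_report.groupby("kept")[["call_rate", "maf"]].mean().round(3))

mendel = count_mendelian_errors(kept, study.pedigree)
print(f"\nMendelian errors on gene-dropped data (must be 0): {mendel.total_errors}")

filled = fill_missing_genotypes(kept, mode="round")
print(f"after imputation: {filled.missing_mask().sum()} missing entries remain")
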