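"""End-to-end pipeline: simulate (optional) -> QC -> kinship -> genetic
parameters -> GWAS (GBLUP and BayesC-pi) -> cross-validation, driven by a YAML
config. Every stage writes TSV reports stamped with the config hash and seed,
and stages can be run individually (see the CLI)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayescpi as bcp
from . import crossval as cv
from . import gwas_gblup as gg
from . import io as rio
from . import qc as rqc
from .kinship import genomic_relationship_matrix, pedigree_relationship_matrix
from .mixedmodel import build_design, default_design_for, estimate_parameter_table, reml_estimate, solve_mme
from .simdata import GenomeMap, MatingDesign, simulate_study

log = logging.getLogger("roegen")


@dataclass
class PipelineConfig:
    out_dir: str = "roegen_out"
    seed: int = 1
    # either simulate...
    simulate: bool = True
    n_offspring: int = 600
    n_chromosomes: int = 6
    n_snps_per_chrom: int = 120
    chrom_length_mb: float = 25.0
    ld_rho: float = 0.7
    missing_rate: float = 0.01
    # ...or read files
    pedigree_csv: str | None = None
    genotypes: str | None = None
    genotype_format: str | None = None
    phenotypes_csv: str | None = None
    # QC
    run_qc: bool = True
    call_rate_min: float = 0.97
    hwe_p_min: float = 1e-4
    maf_min: float = 0.05
    outlier_sd: float = 4.0
    fill_mode: str = "round"
    # models
    traits: list[str] = field(default_factory=lambda: ["SD", "FW", "PW", "SW", "EN", "EW", "ED"])
    gwas_traits: list[str] = field(default_factory=lambda: ["ED"])
    bayescpi_cycles: int = 20_000
    bayescpi_burn_in: int = 2_000
    crossval_traits: list[str] = field(default_factory=lambda: ["ED"])
    crossval_replicates: int = 10
    reestimate_components: bool = False
    reml_tol: float = 1e-6

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        # analysis parameters only; the output location is not provenance
        d = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return rio.config_hash(d)


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(cfg: PipelineConfig):
    genome = GenomeMap.uniform(cfg.n_chromosomes, cfg.n_snps_per_chrom, cfg.chrom_length_mb)
    design = MatingDesign.default(total_offspring=cfg.n_offspring)
    study = simulate_study(
        cfg.seed, design=design, genome=genome, ld_rho=cfg.ld_rho, missing_rate=cfg.missing_rate
    )
    out = _out(cfg)
    study.pedigree.to_csv(out / "pedigree.csv")
    rio.write_phenotypes(study.phenotypes, out / "phenotypes.csv")
    rio.write_plink(study.genotypes, out / "genotypes")
    rio.write_vcf(study.genotypes, out / "genotypes.vcf")
    rio.write_table(study.truth.u_frame(), out / "truth_breeding_values.tsv",
                    cfg.hash(), cfg.seed)
    log.info("simulated %d individuals x %d SNPs", study.genotypes.n_samples, study.genotypes.n_snps)
    return study


def load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        study = stage_simulate(cfg)
        return study.pedigree, study.genotypes, study.phenotypes
    ped = rio.read_pedigree(cfg.pedigree_csv)
    gen = rio.read_genotypes(cfg.genotypes, cfg.genotype_format)
    phe = rio.read_phenotypes(cfg.phenotypes_csv)
    return ped, gen, phe


def stage_qc(cfg: PipelineConfig, pedigree, genotypes, phenotypes):
    out = _out(cfg)
    if cfg.run_qc:
        kept, report = rqc.snp_qc(
            genotypes, cfg.call_rate_min, cfg.hwe_p_min, cfg.maf_min,
            hwe_samples=pedigree.founders if set(pedigree.founders) <= set(genotypes.samples) else None,
        )
        mendel = rqc.count_mendelian_errors(kept, pedigree)
        report = report.merge(
            mendel.per_snp.rename(columns={"errors": "mendel_errors"}), on="snp", how="left"
        )
        rio.write_table(report, out / "snp_qc.tsv", cfg.hash(), cfg.seed)
    else:
        kept = genotypes
    filled = rqc.fill_missing_genotypes(kept, mode=cfg.fill_mode)
    traits = [t for t in cfg.traits if t in phenotypes.columns]
    phe, removed = rqc.apply_outlier_filter(phenotypes, traits, n_sd=cfg.outlier_sd)
    rio.write_table(removed, out / "phenotype_outliers.tsv", cfg.hash(), cfg.seed)
    return filled, phe


def stage_kinship(cfg: PipelineConfig, pedigree, genotypes):
    kin_a = pedigree_relationship_matrix(pedigree)
    kin_g = genomic_relationship_matrix(genotypes)
    return kin_a, kin_g


def stage_params(cfg: PipelineConfig, pheno, kin_a):
    out = _out(cfg)
    params = estimate_parameter_table(
        pheno, kin_a, reml_kwargs={"tol": cfg.reml_tol, "max_iter": 100}
    )
    tab = pd.DataFrame({"trait": params.traits, "h2": params.h2.values, "h2_se": params.h2_se.values})
    rio.write_table(tab, out / "heritabilities.tsv", cfg.hash(), cfg.seed)
    rio.write_table(params.rg.reset_index(), out / "genetic_correlations.tsv", cfg.hash(), cfg.seed)
    rio.write_table(params.rp.reset_index(), out / "phenotypic_correlations.tsv", cfg.hash(), cfg.seed)
    return params


def _corrected_single_trait(pheno, trait, kin, tol):
    sub = pheno.dropna(subset=[trait]).reset_index(drop=True)
    sub = sub[sub["id"].isin(set(kin.ids))].reset_index(drop=True)
    X, _ = build_design(sub, default_design_for(trait))
    y = sub[trait].to_numpy(dtype=float)
    pos = {s: k for k, s in enumerate(kin.ids)}
    rows = np.array([pos[i] for i in sub["id"]])
    Ksub = kin.G[np.ix_(rows, rows)] if hasattr(kin, "G") else kin.A[np.ix_(rows, rows)]
    vc = reml_estimate(y[:, None], [X], K=Ksub, traits=[trait], tol=tol, max_iter=100)
    vg, ve = float(vc.Vg[0, 0]), float(vc.Ve[0, 0])
    fit = solve_mme(y[:, None], [X], list(sub["id"]), kin, np.array([[vg]]),
                    np.array([[ve]]), traits=[trait], compute_pev=True)
    ystar = y - X @ fit.beta[0]
    return sub, fit, vg, ve, ystar


def stage_gwas_gblup(cfg: PipelineConfig, pheno, genotypes, kin_g):
    out = _out(cfg)
    results = {}
    for trait in cfg.gwas_traits:
        sub, fit, vg, ve, _ = _corrected_single_trait(pheno, trait, kin_g, cfg.reml_tol)
        gsub = genotypes.subset(samples=kin_g.ids)
        scan = gg.gwas_scan(fit, gsub, kin_g, trait=trait)
        regions = gg.detect_qtl_gblup(scan, gsub, kin_g, n_chromosomes=cfg.n_chromosomes)
        rio.write_table(scan, out / f"gwas_gblup_{trait}.tsv", cfg.hash(), cfg.seed)
        rio.write_table(pd.DataFrame([r.as_record() for r in regions]),
                        out / f"qtl_gblup_{trait}.tsv", cfg.hash(), cfg.seed)
        results[trait] = (scan, regions)
    return results


def stage_gwas_bayescpi(cfg: PipelineConfig, pheno, genotypes, kin_g):
    out = _out(cfg)
    config = bcp.BayesCConfig(cycles=cfg.bayescpi_cycles, burn_in=cfg.bayescpi_burn_in)
    results = {}
    for trait in cfg.gwas_traits:
        sub, fit, vg, ve, ystar = _corrected_single_trait(pheno, trait, kin_g, cfg.reml_tol)
        gsub = genotypes.subset(samples=list(sub["id"]))
        post = bcp.bayescpi_sample(ystar, gsub, config=config, seed=cfg.seed, vg_prior=vg)
        scan = bcp.bayes_factors(post)
        regions = bcp.credibility_interval(scan, posterior=post)
        rio.write_table(scan, out / f"gwas_bayescpi_{trait}.tsv", cfg.hash(), cfg.seed)
        rio.write_table(pd.DataFrame([r.as_record() for r in regions]),
                        out / f"qtl_bayescpi_{trait}.tsv", cfg.hash(), cfg.seed)
        results[trait] = (scan, regions)
    return results


def stage_crossval(cfg: PipelineConfig, pheno, kin_a, kin_g):
    out = _out(cfg)
    ids = [i for i in pheno["id"] if i in set(kin_g.ids)]
    cohorts = dict(zip(pheno["id"], pheno["cohort"]))
    scenarios = cv.build_scenarios(ids, cohorts, seed=cfg.seed, n_replicates=cfg.crossval_replicates)
    res = cv.run_crossval(
        pheno, kin_a, kin_g, cfg.crossval_traits, scenarios,
        reestimate_components=cfg.reestimate_components,
        reml_kwargs={"tol": cfg.reml_tol, "max_iter": 100},
    )
    rio.write_table(res.records, out / "crossval_records.tsv", cfg.hash(), cfg.seed)
    rio.write_table(res.summary, out / "crossval_summary.tsv", cfg.hash(), cfg.seed)
    return res


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    out = _out(cfg)
    ped, gen, phe = load_inputs(cfg)
    gen, phe = stage_qc(cfg, ped, gen, phe)
    kin_a, kin_g = stage_kinship(cfg, ped, gen)
    stage_params(cfg, phe, kin_a)
    stage_gwas_gblup(cfg, phe, gen, kin_g)
    stage_gwas_bayescpi(cfg, phe, gen, kin_g)
    stage_crossval(cfg, phe, kin_a, kin_g)
    log.info("pipeline complete -> %s", out)
    return out


def manhattan_plot(scan: pd.DataFrame, stat_col: str, path, threshold: float | None = None):
    """Optional Manhattan plot from a GWAS table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(scan.groupby("chrom", sort=False)):
        ax.scatter(grp["pos"] + offset, grp[stat_col], s=4,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append(offset + grp["pos"].median())
        labels.append(str(chrom))
        offset += grp["pos"].max()
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=6)
    ax.set_ylabel(stat_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
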