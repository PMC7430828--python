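"""Validation experiments: parameter recovery, GWAS calibration and power,
Bayesian signal recovery, and cross-validated prediction on simulated
populations.

These are the package's standard self-checks; the acceptance script and the
test suite both run them. Each experiment simulates its own data from the
default study conditions, runs the relevant pipeline stages, and returns
summary numbers. Problem sizes (offspring counts, SNP panels, replicate and
chain counts) are the experiments' own desk-scale defaults, chosen to give
stable Monte-Carlo estimates.
"""

from __future__ import annotations

import numpy as np

from .bayescpi import BayesCConfig, bayescpi_sample
from .crossval import build_scenarios, run_crossval
from .gwas_gblup import gwas_scan, significance_thresholds
from .kinship import genomic_relationship_matrix, pedigree_relationship_matrix
from .mixedmodel import build_design, default_design_for, reml_estimate, solve_mme
from .simdata import (
    GenomeMap,
    MatingDesign,
    QtlSpec,
    TraitModel,
    gene_drop,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def single_trait_model(h2: float) -> TraitModel:
    """Intercept-only single trait on a unit phenotypic scale."""
    return TraitModel(
        traits=["T"], Vg=np.array([[h2]]), Ve=np.array([[1.0 - h2]]),
        means=np.array([0.0]), overmature_prevalence=0.0,
    )


def two_generation_pedigree(seed: int, n_per_generation: int = 1000) -> "Pedigree":
    """Two phenotyped generations over a founder base.

    Full-sib families within each generation plus parent-offspring links
    across them: the design of choice for heritability-recovery studies, since
    the parent-offspring covariance adds information that pure sib contrasts
    cannot supply.
    """
    import pandas as pd

    from .containers import Pedigree

    rng = np.random.default_rng(seed)
    n_founder_pairs = max(n_per_generation // 5, 2)
    rows = []
    founders = [f"F{k}" for k in range(2 * n_founder_pairs)]
    for f in founders:
        rows.append((f, "0", "0", "F0"))
    g1 = []
    for k in range(n_per_generation):
        pair = k % n_founder_pairs
        g1.append(f"A{k}")
        rows.append((f"A{k}", founders[2 * pair], founders[2 * pair + 1], "C1"))
    perm = rng.permutation(n_per_generation)
    n_pairs_g1 = n_per_generation // 2
    for k in range(n_per_generation):
        pair = k % n_pairs_g1
        s, d = g1[perm[2 * pair]], g1[perm[2 * pair + 1]]
        rows.append((f"B{k}", s, d, "C2"))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"]))


def h2_recovery_experiment(
    seed: int,
    h2_true: float = 0.3,
    n_offspring: int = 2000,
    n_replicates: int = 20,
    tolerance: float = 0.07,
) -> dict:
    """REML recovery of a known heritability on fresh genetic draws.

    One two-generation pedigree (shared eigendecomposition of its A
    submatrix); per replicate new founder haplotypes, gene drop and
    phenotypes, then single-trait AI-REML. Reports the fraction of replicates
    with |h2_hat - h2| within the tolerance.
    """
    seeds = _spawn_seeds(seed, 1 + 3 * n_replicates)
    ped = two_generation_pedigree(seeds[0], n_per_generation=n_offspring // 2)
    genome = GenomeMap.uniform(10, 150, 25.0)
    kin = pedigree_relationship_matrix(ped)
    model = single_trait_model(h2_true)
    eig = None
    estimates = []
    for r in range(n_replicates):
        s_h, s_d, s_p = seeds[1 + 3 * r: 4 + 3 * r]
        fh = simulate_founder_haplotypes(genome, len(ped.founders), seed=s_h)
        gset = gene_drop(ped, fh, seed=s_d)
        phe, _ = simulate_phenotypes(ped, gset, model, seed=s_p)
        if eig is None:
            rows = kin.index(list(phe["id"]))
            eig = tuple(np.linalg.eigh(kin.A[np.ix_(rows, rows)]))
        y = phe["T"].to_numpy()
        vc = reml_estimate(y[:, None], [np.ones((len(y), 1))], eig=eig, tol=1e-6)
        estimates.append(float(vc.h2[0]))
    estimates = np.array(estimates)
    within = np.abs(estimates - h2_true) <= tolerance
    return {
        "h2_true": h2_true,
        "estimates": estimates,
        "mean_h2": float(estimates.mean()),
        "fraction_within": float(within.mean()),
        "n": n_offspring,
    }


def bivariate_rg_experiment(seed: int, n_offspring: int = 2000) -> dict:
    """Bivariate REML recovery of the spawn weight / egg number genetic
    correlation from the default seven-trait generator (target 0.86)."""
    study = simulate_study(
        seed, design=MatingDesign.default(total_offspring=n_offspring),
        genome=GenomeMap.uniform(6, 100, 25.0), missing_rate=0.0,
    )
    phe = study.phenotypes
    kin = pedigree_relationship_matrix(study.pedigree)
    rows = kin.index(list(phe["id"]))
    K = kin.A[np.ix_(rows, rows)]
    Y = phe[["SW", "EN"]].to_numpy()
    Xs = [build_design(phe, default_design_for(t))[0] for t in ["SW", "EN"]]
    vc = reml_estimate(Y, Xs, K=K, traits=["SW", "EN"], tol=1e-6)
    return {"rg_sw_en": float(vc.rg[0, 1]), "se": float(vc.rg_se[0, 1]), "n": n_offspring}


def _gblup_scan_for(study, trait="ED"):
    phe = study.phenotypes
    gen = study.genotypes_complete.subset(samples=list(phe["id"]))
    gk = genomic_relationship_matrix(gen)
    X, _ = build_design(phe, default_design_for(trait))
    y = phe[trait].to_numpy()
    vc = reml_estimate(y[:, None], [X], K=gk.G, traits=[trait], tol=1e-6)
    fit = solve_mme(y[:, None], [X], list(phe["id"]), gk, vc.Vg, vc.Ve,
                    traits=[trait], compute_pev=True)
    return gwas_scan(fit, gen, gk, trait=trait), gen, gk


def gwas_null_calibration(seed: int, n_offspring: int = 1000, n_snps: int = 5000) -> dict:
    """Type-I error of the GBLUP scan on a purely polygenic trait."""
    study = simulate_study(
        seed, design=MatingDesign.default(total_offspring=n_offspring),
        genome=GenomeMap.uniform(10, n_snps // 10, 25.0), missing_rate=0.0,
    )
    scan, _, _ = _gblup_scan_for(study)
    rate = float((scan["minus_log10_p"] > 2.0).mean())
    return {"type1_rate_at_p01": rate, "n_tests": len(scan), "n": n_offspring}


def gwas_power_experiment(
    seed: int,
    n_replicates: int = 20,
    n_offspring: int = 1000,
    qtl_gv_fraction: float = 0.10,
    window_bp: float = 1e6,
) -> dict:
    """Localization power for a planted QTL carrying 10% of the genetic
    variance: fraction of replicates whose genome-wide peak lies within 1 Mb
    of the causal SNP."""
    seeds = _spawn_seeds(seed, n_replicates)
    genome = GenomeMap.uniform(10, 200, 25.0)  # 2000 SNPs at 125 kb spacing
    qtl_j = 5 * 200 + 100
    truth_row = genome.to_frame().iloc[qtl_j]
    hits = []
    for s in seeds:
        model = TraitModel.default(
            qtls=[QtlSpec(snp_index=qtl_j, var_fraction={"ED": qtl_gv_fraction})]
        )
        study = simulate_study(
            s, design=MatingDesign.default(total_offspring=n_offspring),
            genome=genome, model=model, missing_rate=0.0,
        )
        scan, _, _ = _gblup_scan_for(study)
        peak = scan.loc[scan["minus_log10_p"].idxmax()]
        hits.append(
            peak["chrom"] == truth_row["chrom"]
            and abs(peak["pos"] - truth_row["pos"]) <= window_bp
        )
    return {"localization_rate": float(np.mean(hits)), "n_replicates": n_replicates,
            "n": n_offspring}


def bayescpi_signal_experiment(
    seed: int,
    n_offspring: int = 1000,
    n_snps: int = 2000,
    qtl_pv_fraction: float = 0.30,
) -> dict:
    """Posterior inclusion of a causal SNP explaining 30% of the phenotypic
    variance under the desk-scale chain configuration."""
    genome = GenomeMap.uniform(10, n_snps // 10, 25.0)
    qtl_j = n_snps // 2 + 7
    h2 = 0.44  # egg diameter, the most heritable trait
    model = TraitModel.default(
        qtls=[QtlSpec(snp_index=qtl_j, var_fraction={"ED": qtl_pv_fraction / h2})]
    )
    study = simulate_study(
        seed, design=MatingDesign.default(total_offspring=n_offspring),
        genome=genome, model=model, missing_rate=0.0,
    )
    phe = study.phenotypes
    gen = study.genotypes_complete.subset(samples=list(phe["id"]))
    X, _ = build_design(phe, default_design_for("ED"))
    y = phe["ED"].to_numpy()
    ystar = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    post = bayescpi_sample(
        ystar, gen, config=BayesCConfig.desk_scale(), seed=_spawn_seeds(seed, 1)[0]
    )
    null = np.delete(post.inclusion_prob, qtl_j)
    return {
        "causal_inclusion_prob": float(post.inclusion_prob[qtl_j]),
        "median_null_inclusion_prob": float(np.median(null)),
        "n": n_offspring,
    }


def crossval_experiment(
    seed: int,
    n_offspring: int = 650,
    n_replicates: int = 40,
    trait: str = "ED",
) -> dict:
    """BLUP vs GBLUP prediction accuracy and dispersion under the four
    training/validation scenarios, at a reduced population size."""
    study = simulate_study(
        seed, design=MatingDesign.default(total_offspring=n_offspring),
        genome=GenomeMap.uniform(8, 125, 25.0), missing_rate=0.0,
    )
    phe = study.phenotypes
    kin_a = pedigree_relationship_matrix(study.pedigree)
    gen = study.genotypes_complete.subset(samples=list(phe["id"]))
    kin_g = genomic_relationship_matrix(gen)
    cohorts = dict(zip(phe["id"], phe["cohort"]))
    scen = build_scenarios(list(phe["id"]), cohorts, seed=_spawn_seeds(seed, 1)[0],
                           n_replicates=n_replicates)
    res = run_crossval(phe, kin_a, kin_g, [trait], scen)
    rec = res.records
    out = {"n": n_offspring, "n_replicates": n_replicates}
    for scenario in ["T+", "T-", "T1", "T2"]:
        for method in ["BLUP", "GBLUP"]:
            grp = rec.query("scenario == @scenario and method == @method")
            out[f"r_{method}_{scenario}"] = float(grp["r"].mean())
            out[f"b_{method}_{scenario}"] = float(grp["b"].mean())
    for scenario in ["T+", "T-"]:
        wide = rec.query("scenario == @scenario").pivot_table(
            index="replicate", columns="method", values="r")
        out[f"gblup_wins_{scenario}"] = int((wide["GBLUP"] > wide["BLUP"]).sum())
    return out


def threshold_targets() -> dict:
    thr = significance_thresholds(29_799, 30)
    return {
        "chromosome_wide_threshold": thr.chromosome_wide_1dp,
        "genome_wide_threshold": thr.genome_wide_1dp,
    }


def prior_pi_percent(alpha: float = 300.0, beta: float = 29_800.0) -> float:
    return 100.0 * alpha / (alpha + beta)
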