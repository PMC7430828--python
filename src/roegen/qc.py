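"""Trait derivation and quality control.

Derived reproduction traits from raw spawn measures:

* ED (mm) = length of 50 aligned eggs / 50
* EW (mg) = 1000 * spoon weight (g) / spoon count (2.5 ml sampling spoon)
* EN      = round(1000 * SW (g) / EW (mg))
* SD      = rank of the spawning week within cohort, capped at 5

Phenotype outliers are records more than 4 SD from the trait mean. SNP QC
retains markers with call rate > 0.97, Hardy-Weinberg chi-square p > 1e-4 and
minor allele frequency > 0.05 (all strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import MISSING, GenotypeSet, Pedigree


def derive_reproduction_traits(
    raw: pd.DataFrame,
    first_spawning_week_by_cohort: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Derive ED, EW, EN and SD from raw spawn measures.

    Expects columns ``length_50_eggs`` (mm), ``spoon_weight`` (g),
    ``spoon_count``, ``SW`` (g), ``spawning_week`` and ``cohort``. When the
    first spawning week of a cohort is not supplied it is taken as that
    cohort's earliest observed week. Undefined derivations (zero spoon count
    or zero egg weight) yield NaN markers, not exceptions.
    """
    out = raw.copy()
    if "length_50_eggs" in out:
        out["ED"] = out["length_50_eggs"] / 50.0
    if {"spoon_weight", "spoon_count"}.issubset(out.columns):
        count = out["spoon_count"].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ew = 1000.0 * out["spoon_weight"] / count.where(count > 0)
        out["EW"] = ew
        if "SW" in out:
            with np.errstate(divide="ignore", invalid="ignore"):
                en = 1000.0 * out["SW"] / ew.where(ew > 0)
            out["EN"] = np.round(en)
    if {"spawning_week", "cohort"}.issubset(out.columns):
        first = dict(first_spawning_week_by_cohort or {})
        for c, grp in out.groupby("cohort"):
            first.setdefault(c, int(grp["spawning_week"].min()))
        fw = out["cohort"].map(first)
        out["SD"] = np.minimum(out["spawning_week"] - fw + 1, 5).astype(float)
    return out


def filter_outliers(values: np.ndarray | pd.Series, n_sd: float = 4.0) -> np.ndarray:
    """Keep-mask for a single trait: False where |x - mean| > n_sd * SD.

    Single pass; the mean and SD (n-1 denominator) are computed once on the
    non-missing values. Missing values pass through unmasked. A zero-variance
    vector keeps everything.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mu = x[obs].mean()
    sd = x[obs].std(ddof=1)
    keep = np.ones(x.shape, dtype=bool)
    if sd > 0:
        keep[obs] = np.abs(x[obs] - mu) <= n_sd * sd
    return keep


def apply_outlier_filter(
    pheno: pd.DataFrame, trait_cols: list[str], n_sd: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask per-trait outliers to NaN; returns (filtered table, removal report)."""
    out = pheno.copy()
    rows = []
    for tr in trait_cols:
        keep = filter_outliers(out[tr].to_numpy(dtype=float), n_sd=n_sd)
        rows.append({"trait": tr, "n_removed": int((~keep).sum())})
        out.loc[~keep, tr] = np.nan
    return out, pd.DataFrame(rows)


def hwe_chi2_pvalue(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """1-df chi-square test of Hardy-Weinberg proportions from genotype counts."""
    n0, n1, n2 = (np.asarray(v, dtype=float) for v in (n0, n1, n2))
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([n * q**2, 2.0 * n * p * q, n * p**2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pval = chi2.sf(stat, df=1)
    # monomorphic: no deviation testable
    pval = np.where((p <= 0) | (p >= 1), 1.0, pval)
    return np.where(n > 0, pval, np.nan)


def snp_qc(
    genotypes: GenotypeSet,
    call_rate_min: float = 0.97,
    hwe_p_min: float = 1e-4,
    maf_min: float = 0.05,
    hwe_samples: list[str] | None = None,
) -> tuple[GenotypeSet, pd.DataFrame]:
    """Retain SNPs passing call-rate, Hardy-Weinberg and MAF filters (strict >).

    ``hwe_samples`` restricts the Hardy-Weinberg test to a subset (typically
    founders, to avoid family structure inflating the statistic); the default
    uses all samples. Returns the filtered GenotypeSet and a per-SNP report.
    """
    cr = genotypes.call_rate()
    maf = genotypes.maf()
    hw_set = genotypes if hwe_samples is None else genotypes.subset(samples=hwe_samples)
    d = hw_set.dosages
    miss = hw_set.missing_mask()
    n0 = ((d == 0) & ~miss).sum(axis=0)
    n1 = ((d == 1) & ~miss).sum(axis=0)
    n2 = ((d == 2) & ~miss).sum(axis=0)
    hwe_p = hwe_chi2_pvalue(n0, n1, n2)
    maf_f = np.where(np.isnan(maf), 0.0, maf)
    kept = (cr > call_rate_min) & (hwe_p > hwe_p_min) & (maf_f > maf_min)
    report = pd.DataFrame(
        {
            "snp": genotypes.snp_map["snp"],
            "chrom": genotypes.snp_map["chrom"],
            "pos": genotypes.snp_map["pos"],
            "call_rate": cr,
            "maf": maf_f,
            "hwe_p": hwe_p,
            "kept": kept,
        }
    )
    return genotypes.subset(snp_indices=np.nonzero(kept)[0]), report


@dataclass
class MendelReport:
    per_snp: pd.DataFrame  # snp, errors
    median_errors_nonzero: float  # median count over SNPs with >= 1 error

    @property
    def total_errors(self) -> int:
        return int(self.per_snp["errors"].sum())


def count_mendelian_errors(genotypes: GenotypeSet, pedigree: Pedigree) -> MendelReport:
    """Count offspring genotypes incompatible with their genotyped parents.

    Duo rule (one genotyped parent): opposite homozygotes are incompatible.
    Trio rule: the offspring dosage must be attainable as one gamete from each
    parent (heterozygous parents can transmit either allele). The summary
    reports the median error count over SNPs having at least one error, the
    usual screen for assay artefacts at problem SNPs.
    """
    sample_pos = {s: k for k, s in enumerate(genotypes.samples)}
    d = genotypes.dosages
    miss = genotypes.missing_mask()
    trios = []
    for _, row in pedigree.df.iterrows():
        if row["id"] not in sample_pos:
            continue
        o = sample_pos[row["id"]]
        s = sample_pos.get(row["sire"], -1)
        m = sample_pos.get(row["dam"], -1)
        if s >= 0 or m >= 0:
            trios.append((o, s, m))
    n_snps = genotypes.n_snps
    errors = np.zeros(n_snps, dtype=np.int64)
    if not trios:
        warnings.warn("no genotyped parents found; Mendelian check is empty")
        per_snp = pd.DataFrame({"snp": genotypes.snp_map["snp"], "errors": errors})
        return MendelReport(per_snp, float("nan"))

    def _called(k):
        if k < 0:
            return np.zeros(n_snps, dtype=bool), np.zeros(n_snps, dtype=np.int8)
        return ~miss[k], d[k].astype(np.int8)

    for o, s, m in trios:
        oc, og = _called(o)
        sc, sg = _called(s)
        mc, mg = _called(m)
        both = oc & sc & mc
        # trio: offspring dosage outside [lo, hi] attainable from parental gametes
        lo = (sg == 2).astype(np.int8) + (mg == 2).astype(np.int8)
        hi = 2 - (sg == 0).astype(np.int8) - (mg == 0).astype(np.int8)
        bad = both & ((og < lo) | (og > hi))
        for pc, pg in ((sc, sg), (mc, mg)):
            duo = oc & pc & ~both
            bad |= duo & (((pg == 0) & (og == 2)) | ((pg == 2) & (og == 0)))
        errors += bad
    per_snp = pd.DataFrame({"snp": genotypes.snp_map["snp"], "errors": errors})
    nz = errors[errors > 0]
    med = float(np.median(nz)) if nz.size else 0.0
    return MendelReport(per_snp, med)


def fill_missing_genotypes(genotypes: GenotypeSet, mode: str = "round") -> GenotypeSet:
    """Replace missing dosages with 2p (allele-frequency expectation).

    mode "round": nearest of {0, 1, 2} (keeps an integer matrix);
    mode "dosage": fractional fill. A SNP with no called genotype should have
    failed QC and raises.
    """
    if mode not in ("round", "dosage"):
        raise ValueError("mode must be 'round' or 'dosage'")
    miss = genotypes.missing_mask()
    if not miss.any():
        out = genotypes.subset()
        out.fill_mode = mode
        return out
    p = genotypes.allele_freq()
    if np.isnan(p).any():
        bad = genotypes.snp_map["snp"].iloc[int(np.nonzero(np.isnan(p))[0][0])]
        raise ValueError(f"SNP {bad} has no called genotypes; run snp_qc first")
    fill = 2.0 * p
    if mode == "round":
        filled = np.where(miss, np.rint(fill)[None, :], genotypes.dosages).astype(np.int8)
    else:
        filled = np.where(miss, fill[None, :], genotypes.dosages.astype(np.float64))
    return GenotypeSet(genotypes.samples, filled, genotypes.snp_map.copy(), fill_mode=mode)
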