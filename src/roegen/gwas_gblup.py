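"""GBLUP-based GWAS.

SNP effects are back-solved from the genomic breeding values,
a_hat = d Z' [Z d Z']^-1 g_hat with Z the centered dosage matrix, and tested
with sd(a_hat_j) propagated from the prediction-error covariance of g_hat
(equivalently, the variance of the genomic predictor), which makes the per-SNP
z-test equivalent to a single-marker generalized-least-squares scan. A second,
explicit single-marker GLS engine is provided as a cross-check.

Significance follows 1% Bonferroni thresholds: chromosome-wide
-log10(0.01 / (n_snps / n_chromosomes)) and genome-wide -log10(0.01 / n_snps).
QTL confidence intervals absorb SNPs within a sliding 1 Mb window of the
interval edge while their -log10 p stays within 1.5 of the peak.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeSet, QtlRegion
from .kinship import GenomicKinship, centered_dosages
from .mixedmodel import MixedModelFit


class GwasError(ValueError):
    pass


def backsolve_snp_effects(
    ghat: np.ndarray,
    genotypes: GenotypeSet,
    gk: GenomicKinship,
) -> np.ndarray:
    """Back-solve per-SNP allele substitution effects from GEBVs.

    Uses the ridged G consistently: a_hat = d . Z' (denom * G_ridged)^-1 ghat,
    so Z a_hat reproduces ghat up to the ridge perturbation. SNPs with zero
    weight get exactly zero effect.
    """
    Z = centered_dosages(genotypes, freqs=gk.freqs)
    rhs = np.linalg.solve(gk.G * gk.denom, np.asarray(ghat, dtype=float))
    return gk.d * (Z.T @ rhs)


def gwas_scan(
    fit: MixedModelFit,
    genotypes: GenotypeSet,
    gk: GenomicKinship,
    engine: str = "pev",
    trait: str | None = None,
) -> pd.DataFrame:
    """Per-SNP effects, standard errors and -log10 p for one trait.

    engine "pev": sd(a_hat_j) from Var(g_hat) = G*sigma_a^2 - PEV propagated
    through the back-solving transform (requires a single-trait fit with
    ``compute_pev=True``). engine "gls": explicit single-marker generalized
    least squares on the corrected phenotype with V from the fitted
    components (used as an independent cross-check of the p-values).
    """
    k = 0 if trait is None else fit.traits.index(trait)
    sigma_a2 = float(fit.Vg[k, k])
    rows = gk.index(genotypes.samples)
    if not np.array_equal(rows, np.arange(len(gk.ids))):
        raise GwasError("genotypes and G must cover the same animals in the same order")
    ghat = fit.u[:, k]
    Z = centered_dosages(genotypes, freqs=gk.freqs)
    ahat = backsolve_snp_effects(ghat, genotypes, gk)
    if engine == "pev":
        if fit.pev is None:
            raise GwasError("fit lacks PEV; refit with compute_pev=True")
        var_g = sigma_a2 * gk.G - fit.pev  # variance of the predictor g_hat
        # T = d Z' (denom G)^-1 ; Var(a_hat) = T Var(g_hat) T'
        TT = np.linalg.solve(gk.G * gk.denom, Z).T * gk.d[:, None]  # (m, N)
        var_a = np.einsum("mn,nk,mk->m", TT, var_g, TT)
    elif engine == "gls":
        raise GwasError("use gwas_scan_gls for the single-marker engine")
    else:
        raise GwasError(f"unknown engine {engine!r}")
    sd = np.sqrt(np.clip(var_a, 0.0, None))
    flagged = sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(flagged, np.nan, ahat / sd)
    logp = -(norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)
    out = genotypes.snp_map.copy()
    out["effect"] = ahat
    out["sd"] = sd
    out["z"] = z
    out["minus_log10_p"] = logp
    out["flagged"] = flagged
    return out


def gwas_scan_gls(
    y_corrected: np.ndarray,
    genotypes: GenotypeSet,
    gk: GenomicKinship,
    sigma_a2: float,
    sigma_e2: float,
) -> pd.DataFrame:
    """Single-marker GLS scan: y* = x_j b + g + e with V = G sa2 + I se2 fixed."""
    Z = centered_dosages(genotypes, freqs=gk.freqs)
    V = sigma_a2 * gk.G + sigma_e2 * np.eye(len(gk.ids))
    Vinv = np.linalg.inv(V)
    y = np.asarray(y_corrected, dtype=float)
    y = y - y.mean()
    VinvZ = Vinv @ Z
    xtvx = np.einsum("nm,nm->m", Z, VinvZ)
    xtvy = VinvZ.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(xtvx > 0, xtvy / xtvx, np.nan)
        se = np.where(xtvx > 0, 1.0 / np.sqrt(xtvx), np.nan)
    z = b / se
    logp = -(norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)
    out = genotypes.snp_map.copy()
    out["effect"] = b
    out["sd"] = se
    out["z"] = z
    out["minus_log10_p"] = logp
    return out


class Thresholds(NamedTuple):
    chromosome_wide: float
    genome_wide: float
    chromosome_wide_1dp: float
    genome_wide_1dp: float


def significance_thresholds(n_snps: int, n_chromosomes: int = 30) -> Thresholds:
    """1% Bonferroni thresholds on the -log10 p scale.

    Chromosome-wide correction uses the average SNP count per chromosome
    (n_snps / n_chromosomes); genome-wide uses all SNPs.
    """
    if n_snps < 1:
        raise GwasError("need at least one SNP")
    cw = float(-np.log10(0.01 / (n_snps / n_chromosomes)))
    gw = float(-np.log10(0.01 / n_snps))
    return Thresholds(cw, gw, round(cw, 1), round(gw, 1))


def _absorb(pos: np.ndarray, qualifies: np.ndarray, peak_idx: int, window_bp: float) -> tuple[int, int]:
    """Grow [lo, hi] (indices into a per-chromosome scan sorted by bp) by
    absorbing qualifying SNPs within ``window_bp`` of the current edge,
    re-anchoring the window after each absorption; both directions independent."""
    lo = hi = peak_idx
    changed = True
    while changed:
        changed = False
        j = hi + 1
        while j < len(pos) and pos[j] - pos[hi] <= window_bp:
            if qualifies[j]:
                hi = j
                changed = True
                break
            j += 1
    changed = True
    while changed:
        changed = False
        j = lo - 1
        while j >= 0 and pos[lo] - pos[j] <= window_bp:
            if qualifies[j]:
                lo = j
                changed = True
                break
            j -= 1
    return lo, hi


def dropoff_interval(
    scan: pd.DataFrame,
    peak_snp: str,
    drop: float = 1.5,
    window_bp: float = 1e6,
    stat_col: str = "minus_log10_p",
) -> QtlRegion:
    """Confidence interval around a peak: absorb SNPs whose statistic exceeds
    (peak - drop) within a 1 Mb sliding window of the interval edge."""
    hit = scan.index[scan["snp"] == peak_snp]
    if len(hit) == 0:
        raise GwasError(f"peak SNP {peak_snp} not in scan")
    row = scan.loc[hit[0]]
    chrom = row["chrom"]
    sub = scan[scan["chrom"] == chrom].sort_values("pos").reset_index(drop=True)
    peak_idx = int(sub.index[sub["snp"] == peak_snp][0])
    pos = sub["pos"].to_numpy()
    stat = sub[stat_col].to_numpy()
    qualifies = stat > stat[peak_idx] - drop
    lo, hi = _absorb(pos, qualifies, peak_idx, window_bp)
    return QtlRegion(
        chrom=str(chrom),
        peak_snp=str(row["snp"]),
        peak_pos=int(row["pos"]),
        start=int(pos[lo]),
        end=int(pos[hi]),
        peak_stat=float(stat[peak_idx]),
        method="gblup",
        snp_indices=list(sub.index[lo:hi + 1]),
    )


def region_variance_pct(
    effects: np.ndarray, Z: np.ndarray, region_cols: np.ndarray
) -> float:
    """Share (%) of the total genomic variance over animals carried by a set of
    SNPs: var(Z_R a_R) / var(Z a). Used for both GWAS engines so GBLUP- and
    Bayesian-detected regions are scored identically."""
    total = Z @ effects
    part = Z[:, region_cols] @ effects[region_cols]
    vt = float(np.var(total))
    if vt == 0:
        return float("nan")
    return 100.0 * float(np.var(part)) / vt


def detect_qtl_gblup(
    scan: pd.DataFrame,
    genotypes: GenotypeSet,
    gk: GenomicKinship,
    n_chromosomes: int | None = None,
    drop: float = 1.5,
    window_bp: float = 1e6,
) -> list[QtlRegion]:
    """All QTL regions from a GBLUP scan: peaks above the chromosome-wide
    threshold, processed in descending significance, non-overlapping, each with
    its drop-off interval and % of genomic variance. Ties in the peak statistic
    break to the smaller bp position."""
    n_chromosomes = n_chromosomes or scan["chrom"].nunique()
    thr = significance_thresholds(len(scan), n_chromosomes)
    stat = scan["minus_log10_p"].to_numpy()
    order = np.lexsort((scan["pos"].to_numpy(), -stat))
    taken = np.zeros(len(scan), dtype=bool)
    Z = centered_dosages(genotypes, freqs=gk.freqs)
    effects = scan["effect"].to_numpy()
    regions = []
    pos_of = {s: k for k, s in enumerate(scan["snp"])}
    for k in order:
        if not np.isfinite(stat[k]) or stat[k] < thr.chromosome_wide or taken[k]:
            continue
        region = dropoff_interval(scan, scan["snp"].iloc[k], drop=drop, window_bp=window_bp)
        chrom_scan = scan[scan["chrom"] == region.chrom]
        cols = chrom_scan.index[
            (chrom_scan["pos"] >= region.start) & (chrom_scan["pos"] <= region.end)
        ].to_numpy()
        if taken[cols].any():
            continue  # overlaps an already-claimed (stronger) region
        taken[cols] = True
        region.snp_indices = [int(c) for c in cols]
        region.var_explained_pct = region_variance_pct(effects, Z, cols)
        regions.append(region)
    regions.sort(key=lambda r: (r.chrom, r.peak_pos))
    return regions
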