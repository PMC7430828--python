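"""BayesC-pi GWAS: spike-and-slab Gibbs sampling, Bayes factors, credibility
intervals and QTL variance shares.

A fraction pi of SNPs carries a non-zero effect at each MCMC cycle; pi has a
Beta(300, 29800) prior (mean ~1%, matching ~300 effective SNPs out of ~30 K).
The degree of association of SNP i is the Bayes factor
BF = [P_i / (1 - P_i)] / [pi / (1 - pi)] with P_i its posterior inclusion
probability, reported as logBF = 2 ln BF. Evidence thresholds: logBF >= 6 for
a QTL, >= 8 for strong evidence; interval membership needs logBF >= 3 within a
sliding 1 Mb window; a 6 <= logBF < 8 peak is only putative unless its region
explains at least 1% of the genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeSet, QtlRegion
from .kinship import centered_dosages
from ._gibbs import bayesc_gibbs


class BayesCError(RuntimeError):
    pass


@dataclass
class BayesCConfig:
    """Chain configuration. ``full()`` is the production setting (100k cycles);
    ``desk_scale()`` (20k cycles) keeps simulation studies tractable."""

    cycles: int = 100_000
    burn_in: int = 5_000
    thin: int = 20
    pi_alpha: float = 300.0
    pi_beta: float = 29_800.0
    chains: int = 2
    nu_a: float = 4.0
    nu_e: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.cycles):
            raise ValueError("burn_in must be in [0, cycles)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.pi_alpha <= 0 or self.pi_beta <= 0:
            raise ValueError("Beta prior parameters must be > 0")

    @property
    def n_saved(self) -> int:
        return (self.cycles - self.burn_in) // self.thin

    @property
    def pi_prior_mean(self) -> float:
        return self.pi_alpha / (self.pi_alpha + self.pi_beta)

    @classmethod
    def full(cls, **kw) -> "BayesCConfig":
        return cls(**kw)

    @classmethod
    def desk_scale(cls, **kw) -> "BayesCConfig":
        kw.setdefault("cycles", 20_000)
        kw.setdefault("burn_in", 2_000)
        return cls(**kw)


@dataclass
class BayesCPosterior:
    snp_map: pd.DataFrame
    inclusion_prob: np.ndarray  # P_i per SNP
    mean_effect: np.ndarray
    effect_samples: np.ndarray  # (S, m) float32, zero when excluded
    sigma_a2: np.ndarray
    sigma_e2: np.ndarray
    pi: np.ndarray
    beta_samples: np.ndarray
    config: BayesCConfig
    Z: np.ndarray = field(repr=False, default=None)  # centered dosages used
    gebv_mean: np.ndarray | None = None

    @property
    def n_saved(self) -> int:
        return self.effect_samples.shape[0]


def bayescpi_sample(
    y: np.ndarray,
    genotypes: GenotypeSet,
    config: BayesCConfig | None = None,
    seed: int = 0,
    X: np.ndarray | None = None,
    vg_prior: float | None = None,
    h2_prior: float = 0.35,
) -> BayesCPosterior:
    """Run one Gibbs chain on complete genotypes.

    ``y`` may be a corrected phenotype (then the default intercept-only X is
    enough) or a raw one with fixed effects supplied in ``X``. The slab
    variance prior scale is tuned so the implied prior genetic variance
    matches ``vg_prior`` (by default ``h2_prior * var(y)``, the place to plug
    a REML pre-fit). Deterministic given the seed.
    """
    config = config or BayesCConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 50:
        raise BayesCError("need at least 50 individuals")
    if genotypes.n_samples != n:
        raise BayesCError("genotype rows must match phenotype length")
    if genotypes.missing_mask().any():
        raise BayesCError("complete genotypes required; run fill_missing_genotypes")
    Z = np.asfortranarray(centered_dosages(genotypes))
    m = Z.shape[1]
    if X is None:
        X = np.ones((n, 1))
    X = np.asfortranarray(X, dtype=float)
    vary = float(np.var(y, ddof=1))
    vg = vg_prior if vg_prior is not None else h2_prior * vary
    mean_2pq = float(np.mean(np.einsum("nm,nm->m", Z, Z) / n))
    expected_inc = max(config.pi_prior_mean * m, 1.0)
    s2_a = vg / (expected_inc * max(mean_2pq, 1e-12))
    s2_e = max(vary - vg, 0.05 * vary)
    s_a, s_beta, s_sa2, s_se2, s_pi, ksave, ok = bayesc_gibbs(
        X,
        Z,
        y,
        int(config.cycles),
        int(config.burn_in),
        int(config.thin),
        float(config.pi_alpha),
        float(config.pi_beta),
        float(config.nu_a),
        float(s2_a),
        float(config.nu_e),
        float(s2_e),
        int(seed) % 2**31,
    )
    if not ok:
        raise BayesCError("divergent residual variance; check scaling of y")
    s_a = s_a[:ksave]
    incl = s_a != 0.0
    post = BayesCPosterior(
        snp_map=genotypes.snp_map.copy(),
        inclusion_prob=incl.mean(axis=0),
        mean_effect=s_a.mean(axis=0).astype(float),
        effect_samples=s_a,
        sigma_a2=s_sa2[:ksave],
        sigma_e2=s_se2[:ksave],
        pi=s_pi[:ksave],
        beta_samples=s_beta[:ksave],
        config=config,
        Z=np.ascontiguousarray(Z),
    )
    post.gebv_mean = post.Z @ post.mean_effect
    return post


def bayes_factors(posterior: BayesCPosterior, pi_ref: float | None = None) -> pd.DataFrame:
    """Per-SNP Bayes factors against the reference inclusion rate.

    ``pi_ref`` defaults to the prior mean of pi (the formula's single pi);
    the posterior mean of pi is the documented alternative. P_i is clamped to
    [1/S, 1 - 1/S] (S saved samples) so the BF stays finite.
    """
    if pi_ref is None:
        pi_ref = posterior.config.pi_prior_mean
    if not (0.0 < pi_ref < 1.0):
        raise ValueError("pi_ref must be in (0, 1)")
    S = posterior.n_saved
    p = np.clip(posterior.inclusion_prob, 1.0 / S, 1.0 - 1.0 / S)
    bf = (p / (1.0 - p)) / (pi_ref / (1.0 - pi_ref))
    out = posterior.snp_map.copy()
    out["inclusion_prob"] = posterior.inclusion_prob
    out["mean_effect"] = posterior.mean_effect
    out["bf"] = bf
    out["logbf"] = 2.0 * np.log(bf)
    return out


def qtl_variance_explained(
    posterior: BayesCPosterior,
    region_cols: np.ndarray,
) -> tuple[float, int]:
    """% of the genomic variance carried by a SNP set, averaged over samples.

    Per saved sample: var over animals of Z_R a_R divided by var of Z a;
    samples with zero total genomic variance are skipped (count returned).
    """
    region_cols = np.asarray(region_cols, dtype=int)
    A = posterior.effect_samples.astype(np.float64)  # (S, m)
    total = posterior.Z @ A.T  # (n, S)
    part = posterior.Z[:, region_cols] @ A[:, region_cols].T
    v_tot = total.var(axis=0)
    v_part = part.var(axis=0)
    good = v_tot > 0
    skipped = int((~good).sum())
    if not good.any():
        return 0.0, skipped
    return 100.0 * float(np.mean(v_part[good] / v_tot[good])), skipped


def credibility_interval(
    scan: pd.DataFrame,
    posterior: BayesCPosterior | None = None,
    evidence: float = 6.0,
    strong: float = 8.0,
    member: float = 3.0,
    window_bp: float = 1e6,
    var_promotion_pct: float = 1.0,
) -> list[QtlRegion]:
    """QTL credibility intervals from a logBF scan.

    Peaks are local logBF maxima >= ``evidence``, processed greedily in
    descending logBF; each region absorbs SNPs with logBF >= ``member`` within
    a sliding 1 Mb window of its edge. SNPs already claimed by a stronger
    region are not reused. Classification: strong if peak logBF >= ``strong``;
    a 6-8 peak is putative unless its region explains at least 1% of the
    genomic variance (computed when the posterior is supplied).
    """
    from .gwas_gblup import _absorb

    stat = scan["logbf"].to_numpy()
    taken = np.zeros(len(scan), dtype=bool)
    order = np.lexsort((scan["pos"].to_numpy(), -stat))
    regions: list[QtlRegion] = []
    for k in order:
        if stat[k] < evidence or taken[k]:
            continue
        chrom = scan["chrom"].iloc[k]
        sub = scan[scan["chrom"] == chrom].sort_values("pos")
        sub_idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        sstat = stat[sub_idx]
        available = ~taken[sub_idx]
        peak_local = int(np.nonzero(sub_idx == k)[0][0])
        qualifies = (sstat >= member) & available
        qualifies[peak_local] = True
        lo, hi = _absorb(pos, qualifies, peak_local, window_bp)
        cols = sub_idx[lo:hi + 1]
        taken[cols] = True
        region = QtlRegion(
            chrom=str(chrom),
            peak_snp=str(scan["snp"].iloc[k]),
            peak_pos=int(scan["pos"].iloc[k]),
            start=int(pos[lo]),
            end=int(pos[hi]),
            peak_stat=float(stat[k]),
            method="bayescpi",
            snp_indices=[int(c) for c in cols],
        )
        if posterior is not None:
            pct, _ = qtl_variance_explained(posterior, np.asarray(cols))
            region.var_explained_pct = min(pct, 100.0)
        if region.peak_stat >= strong:
            region.classification = "strong"
        elif (
            region.var_explained_pct is not None
            and region.var_explained_pct >= var_promotion_pct
        ):
            region.classification = "strong"
        else:
            region.classification = "putative"
        regions.append(region)
    regions.sort(key=lambda r: (r.chrom, r.peak_pos))
    return regions


def gebv_samples(posterior: BayesCPosterior) -> np.ndarray:
    """(n, S) genomic values per saved sample (for chain-agreement checks)."""
    return posterior.Z @ posterior.effect_samples.astype(np.float64).T


def run_chains(
    y: np.ndarray,
    genotypes: GenotypeSet,
    config: BayesCConfig | None = None,
    seed: int = 0,
    **kw,
) -> list[BayesCPosterior]:
    """Run ``config.chains`` independent chains with derived seeds."""
    config = config or BayesCConfig()
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(config.chains)]
    return [bayescpi_sample(y, genotypes, config=config, seed=s, **kw) for s in seeds]
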