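"""Synthetic broodstock population generator.

Emulates the structure of a two-cohort rainbow trout broodstock: factorial
mating plans (~83 dams x 71 sires in 7 plans), a multi-chromosome SNP map,
founder haplotypes with tunable linkage disequilibrium, Mendelian gene dropping
with Haldane recombination, and seven correlated female reproduction traits
(SD spawning date, FW/PW body weight before/after spawning, SW spawn weight,
EN egg number, EW egg weight in mg, ED egg diameter in mm) with cohort,
overmature-egg and spawning-week fixed effects, an additive polygenic
background and optional major QTL.

True breeding values and QTL effects are returned alongside the phenotypes so
parameter-recovery and power analyses can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeSet, Pedigree

TRAITS = ["SD", "FW", "PW", "SW", "EN", "EW", "ED"]

# Default genetic architecture of the seven traits (heritabilities on the
# diagonal, genetic correlations above, phenotypic correlations below), plus
# trait means and phenotypic SDs on the observed scales (weeks, g, count, mg, mm).
_H2 = np.array([0.27, 0.30, 0.33, 0.32, 0.24, 0.27, 0.44])
_RG_UPPER = {
    ("SD", "FW"): 0.12, ("SD", "PW"): 0.03, ("SD", "SW"): 0.34, ("SD", "EN"): 0.22,
    ("SD", "EW"): 0.46, ("SD", "ED"): 0.51,
    ("FW", "PW"): 0.99, ("FW", "SW"): 0.12, ("FW", "EN"): 0.13, ("FW", "EW"): -0.01,
    ("FW", "ED"): -0.01,
    ("PW", "SW"): -0.06, ("PW", "EN"): -0.02, ("PW", "EW"): -0.10, ("PW", "ED"): -0.12,
    ("SW", "EN"): 0.86, ("SW", "EW"): 0.49, ("SW", "ED"): 0.59,
    ("EN", "EW"): 0.01, ("EN", "ED"): 0.10,
    ("EW", "ED"): 0.99,
}
_RP_LOWER = {
    ("FW", "SD"): 0.04,
    ("PW", "SD"): 0.04, ("PW", "FW"): 0.96,
    ("SW", "SD"): 0.05, ("SW", "FW"): 0.34, ("SW", "PW"): 0.17,
    ("EN", "SD"): 0.10, ("EN", "FW"): 0.31, ("EN", "PW"): 0.17, ("EN", "SW"): 0.83,
    ("EW", "SD"): 0.06, ("EW", "FW"): 0.09, ("EW", "PW"): 0.03, ("EW", "SW"): 0.33,
    ("EW", "EN"): -0.18,
    ("ED", "SD"): 0.13, ("ED", "FW"): 0.12, ("ED", "PW"): 0.05, ("ED", "SW"): 0.38,
    ("ED", "EN"): 0.01, ("ED", "EW"): 0.70,
}
_TRAIT_MEANS = np.array([2.52, 2067.0, 1845.0, 187.0, 4710.0, 39.9, 4.03])
_TRAIT_SDS = np.array([1.54, 448.0, 408.0, 71.0, 1743.0, 6.5, 0.19])


class SimConfigError(ValueError):
    pass


def _corr_to_matrix(pairs: dict, traits: list[str]) -> np.ndarray:
    t = len(traits)
    r = np.eye(t)
    pos = {tr: k for k, tr in enumerate(traits)}
    for (a, b), v in pairs.items():
        r[pos[a], pos[b]] = v
        r[pos[b], pos[a]] = v
    return r


def nearest_psd(m: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Eigenvalue-clipped projection onto the symmetric PSD cone."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eps, None)
    return (v * w) @ v.T


def nearest_psd_keep_diag(m: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """PSD projection that preserves the diagonal exactly.

    Clips eigenvalues at the correlation-matrix level and renormalizes back to
    the original variances, so published heritabilities survive the repair of a
    slightly indefinite covariance assembled from rounded correlations.
    """
    s = np.sqrt(np.diag(m))
    r = m / np.outer(s, s)
    for _ in range(50):
        w = np.linalg.eigvalsh(r)
        if w.min() >= eps * 0.99:
            break
        r = nearest_psd(r, eps)
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r * np.outer(s, s)


FOUNDER_COHORT = "F0"
PARENT_COHORT = "P"


@dataclass
class MatingDesign:
    """Factorial mating plans: within each plan every dam is crossed to every sire.

    With a grandparent layer (the default) the plan parents are themselves bred
    from a common pool of grandsires and granddams, so the two cohorts are
    related through shared ancestry — the structure that lets pedigree
    prediction carry some (reduced) information across cohorts.
    """

    dams_per_plan: list[int]
    sires_per_plan: list[int]
    cohort_of_plan: list[str]
    offspring_per_cross: int = 1
    total_offspring: int | None = None  # round-robin allocation cap across crosses
    n_grandsires: int = 12
    n_granddams: int = 40

    def __post_init__(self) -> None:
        if not (len(self.dams_per_plan) == len(self.sires_per_plan) == len(self.cohort_of_plan)):
            raise SimConfigError("per-plan field lengths differ")
        counts = list(self.dams_per_plan) + list(self.sires_per_plan) + [self.offspring_per_cross]
        if any(int(c) < 1 for c in counts):
            raise SimConfigError("all design counts must be >= 1")
        if self.total_offspring is not None and self.total_offspring < 1:
            raise SimConfigError("total_offspring must be >= 1")
        if self.n_grandsires < 0 or self.n_granddams < 0 or (
            (self.n_grandsires == 0) != (self.n_granddams == 0)
        ):
            raise SimConfigError("grandparent counts must both be 0 (off) or both positive")

    @property
    def has_grandparents(self) -> bool:
        return self.n_grandsires > 0

    @property
    def n_plans(self) -> int:
        return len(self.dams_per_plan)

    @property
    def n_dams(self) -> int:
        return int(sum(self.dams_per_plan))

    @property
    def n_sires(self) -> int:
        return int(sum(self.sires_per_plan))

    @classmethod
    def default(cls, total_offspring: int = 1346) -> "MatingDesign":
        """Seven factorial plans totalling 83 dams and 71 sires in two cohorts."""
        return cls(
            dams_per_plan=[12, 12, 12, 12, 12, 12, 11],
            sires_per_plan=[10, 10, 10, 10, 10, 10, 11],
            cohort_of_plan=["C1", "C1", "C1", "C1", "C2", "C2", "C2"],
            offspring_per_cross=1,
            total_offspring=total_offspring,
        )


@dataclass
class GenomeMap:
    """Chromosome labels, 1-based bp SNP positions, and a uniform cM/Mb rate."""

    chromosomes: list[str]
    snp_positions: list[np.ndarray]  # one strictly increasing int array per chromosome
    cm_per_mb: float = 1.3

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.snp_positions):
            raise SimConfigError("one position array per chromosome required")
        if self.cm_per_mb <= 0:
            raise SimConfigError("cm_per_mb must be > 0")
        self.snp_positions = [np.asarray(p, dtype=np.int64) for p in self.snp_positions]
        for lbl, pos in zip(self.chromosomes, self.snp_positions):
            if len(pos) == 0:
                raise SimConfigError(f"chromosome {lbl} has no SNPs")
            if np.any(pos < 1) or np.any(np.diff(pos) <= 0):
                raise SimConfigError(f"positions on {lbl} must be 1-based strictly increasing")

    @property
    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.snp_positions))

    def chrom_slices(self) -> list[slice]:
        out, start = [], 0
        for pos in self.snp_positions:
            out.append(slice(start, start + len(pos)))
            start += len(pos)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl, pos in zip(self.chromosomes, self.snp_positions):
            for p in pos:
                rows.append((f"{lbl}_{p}", lbl, int(p)))
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 10,
        n_snps_per_chrom: int = 150,
        length_mb: float = 25.0,
        cm_per_mb: float = 1.3,
    ) -> "GenomeMap":
        length_bp = int(length_mb * 1e6)
        pos = np.round((np.arange(n_snps_per_chrom) + 0.5) * length_bp / n_snps_per_chrom)
        pos = pos.astype(np.int64)
        return cls(
            chromosomes=[f"Omy{k + 1}" for k in range(n_chromosomes)],
            snp_positions=[pos.copy() for _ in range(n_chromosomes)],
            cm_per_mb=cm_per_mb,
        )


@dataclass
class QtlSpec:
    """A major QTL at a map SNP; effect given directly or as a fraction of the
    trait's genetic variance (resolved at simulation time from realized 2pq)."""

    snp_index: int
    effects: np.ndarray | None = None  # per-trait allele substitution effects
    var_fraction: dict[str, float] | None = None  # trait -> share of genetic variance


@dataclass
class TraitModel:
    """Joint distribution of the seven analysis traits plus fixed-effect generators."""

    traits: list[str]
    Vg: np.ndarray
    Ve: np.ndarray
    means: np.ndarray
    cohort_effects: dict[str, np.ndarray] = field(default_factory=dict)
    overmature_prevalence: float = 0.10
    overmature_effects: dict[str, float] = field(default_factory=dict)
    week_slopes: dict[str, dict[str, float]] = field(default_factory=dict)  # cohort -> trait -> slope
    first_spawning_week: dict[str, int] = field(default_factory=dict)
    qtls: list[QtlSpec] = field(default_factory=list)
    length50_noise_mm: float = 1.0
    spoon_weight_noise_g: float = 0.02
    egg_packing_fraction: float = 0.60

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.Vg = np.asarray(self.Vg, dtype=float)
        self.Ve = np.asarray(self.Ve, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        for name, m in (("Vg", self.Vg), ("Ve", self.Ve)):
            if m.shape != (t, t):
                raise SimConfigError(f"{name} must be {t}x{t}")
            if not np.allclose(m, m.T, atol=1e-8):
                raise SimConfigError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8 * max(1.0, np.trace(m)):
                raise SimConfigError(f"{name} must be positive semi-definite")
        if not 0.0 <= self.overmature_prevalence <= 1.0:
            raise SimConfigError("overmature prevalence must be in [0, 1]")

    def trait_index(self, trait: str) -> int:
        return self.traits.index(trait)

    @classmethod
    def default(cls, qtls: list[QtlSpec] | None = None) -> "TraitModel":
        """Seven-trait model with the study-scale heritabilities/correlations."""
        rg = _corr_to_matrix(_RG_UPPER, TRAITS)
        rp = _corr_to_matrix(_RP_LOWER, TRAITS)
        sg = np.sqrt(_H2) * _TRAIT_SDS
        Vg = nearest_psd_keep_diag(rg * np.outer(sg, sg), eps=1e-4)
        Vp = rp * np.outer(_TRAIT_SDS, _TRAIT_SDS)
        Ve = nearest_psd_keep_diag(Vp - Vg, eps=1e-4)
        sds = _TRAIT_SDS
        cohort_effects = {
            "C1": np.zeros(len(TRAITS)),
            # year/rearing-batch contrast, a modest fraction of a phenotypic SD
            "C2": np.array([0.1, 0.25, 0.25, -0.15, -0.15, 0.10, 0.05]) * sds,
        }
        overmature_effects = {"FW": 0.2 * sds[1], "SW": -0.3 * sds[3],
                              "EN": -0.3 * sds[4], "ED": -0.2 * sds[6]}
        base = {"FW": 0.06, "PW": 0.06, "SW": -0.05, "EN": -0.05, "EW": 0.08, "ED": 0.08}
        sd_of = dict(zip(TRAITS, sds))
        week_slopes = {
            "C1": {tr: s * sd_of[tr] for tr, s in base.items()},
            "C2": {tr: 1.3 * s * sd_of[tr] for tr, s in base.items()},
        }
        return cls(
            traits=list(TRAITS),
            Vg=Vg,
            Ve=Ve,
            means=_TRAIT_MEANS.copy(),
            cohort_effects=cohort_effects,
            overmature_effects=overmature_effects,
            week_slopes=week_slopes,
            first_spawning_week={"C1": 46, "C2": 47},
            qtls=list(qtls or []),
        )


def simulate_pedigree(design: MatingDesign, seed: int) -> Pedigree:
    """Build grandparents (optional), plan parents, and factorially crossed
    offspring.

    With a grandparent layer the founders are the grandsires/granddams and
    every plan parent descends from a random grandparent pair, relating the
    cohorts through shared ancestry; otherwise the plan parents are the
    founders. Offspring are allocated to crosses round-robin when
    ``total_offspring`` is set, otherwise each cross contributes
    ``offspring_per_cross``. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if design.has_grandparents:
        gsires = [f"GS{k + 1}" for k in range(design.n_grandsires)]
        gdams = [f"GD{k + 1}" for k in range(design.n_granddams)]
        for g in gsires + gdams:
            rows.append((g, "0", "0", FOUNDER_COHORT))

        def parent_row(pid):
            return (pid, gsires[rng.integers(len(gsires))],
                    gdams[rng.integers(len(gdams))], PARENT_COHORT)

    else:
        def parent_row(pid):
            return (pid, "0", "0", FOUNDER_COHORT)

    crosses = []  # (sire_id, dam_id, cohort)
    for p in range(design.n_plans):
        cohort = design.cohort_of_plan[p]
        dams = [f"D{p + 1}_{k + 1}" for k in range(design.dams_per_plan[p])]
        sires = [f"S{p + 1}_{k + 1}" for k in range(design.sires_per_plan[p])]
        for d in dams:
            rows.append(parent_row(d))
        for s in sires:
            rows.append(parent_row(s))
        for d in dams:
            for s in sires:
                crosses.append((s, d, cohort))
    if design.total_offspring is not None:
        order = rng.permutation(len(crosses))
        counts = np.zeros(len(crosses), dtype=np.int64)
        k = 0
        for _ in range(design.total_offspring):
            counts[order[k % len(crosses)]] += 1
            k += 1
    else:
        counts = np.full(len(crosses), design.offspring_per_cross, dtype=np.int64)
    off = 0
    for (s, d, cohort), c in zip(crosses, counts):
        for _ in range(int(c)):
            off += 1
            rows.append((f"O{off}", s, d, cohort))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"]))


@dataclass
class FounderHaplotypes:
    haplotypes: np.ndarray  # (2 * n_founders, n_snps) int8 in {0, 1}
    freqs: np.ndarray  # target allele-1 frequency per SNP
    genome: GenomeMap

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2


def simulate_founder_haplotypes(
    genome: GenomeMap,
    n_founders: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.7,
    seed: int = 0,
    ld_scale_bp: float = 1e5,
) -> FounderHaplotypes:
    """Draw founder haplotypes with first-order Markov LD along each chromosome.

    A latent Gaussian AR(1) process per haplotype is thresholded at each SNP's
    allele-frequency quantile; the latent correlation between adjacent SNPs is
    ``ld_rho ** (gap_bp / ld_scale_bp)``, so LD decays with physical distance
    and ``ld_rho = 0`` gives linkage equilibrium.
    """
    from scipy.stats import norm

    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise SimConfigError("maf_range must be within (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise SimConfigError("ld_rho must be in [0, 1)")
    if genome.n_snps == 0:
        raise SimConfigError("empty genome map")
    rng = np.random.default_rng(seed)
    m = genome.n_snps
    maf = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5
    freqs = np.where(flip, 1.0 - maf, maf)
    nh = 2 * n_founders
    hap = np.empty((nh, m), dtype=np.int8)
    for sl, pos in zip(genome.chrom_slices(), genome.snp_positions):
        k = len(pos)
        z = np.empty((nh, k))
        z[:, 0] = rng.standard_normal(nh)
        gaps = np.diff(pos).astype(float)
        r = np.zeros(k - 1) if ld_rho == 0.0 else ld_rho ** (gaps / ld_scale_bp)
        for j in range(1, k):
            z[:, j] = r[j - 1] * z[:, j - 1] + np.sqrt(1.0 - r[j - 1] ** 2) * rng.standard_normal(nh)
        thresh = norm.ppf(freqs[sl])
        hap[:, sl] = (z < thresh[None, :]).astype(np.int8)
    return FounderHaplotypes(haplotypes=hap, freqs=freqs, genome=genome)


def _meiosis(parent_haps: np.ndarray, genome: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: Haldane crossovers (Poisson on the cM scale)."""
    m = parent_haps.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for sl, pos in zip(genome.chrom_slices(), genome.snp_positions):
        length_cm = pos[-1] / 1e6 * genome.cm_per_mb
        n_x = rng.poisson(length_cm / 100.0)
        start = rng.integers(0, 2)
        if n_x == 0:
            gamete[sl] = parent_haps[start, sl]
        else:
            points = np.sort(rng.uniform(0, pos[-1], size=n_x))
            which = (start + np.searchsorted(points, pos)) % 2
            seg = parent_haps[:, sl]
            gamete[sl] = np.where(which == 0, seg[0], seg[1])
    return gamete


def gene_drop(
    pedigree: Pedigree,
    founders: FounderHaplotypes,
    genome: GenomeMap | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    return_haplotypes: bool = False,
):
    """Drop founder haplotypes through the pedigree with recombination.

    Every non-founder must have both parents in the pedigree (Mendelian
    transmission needs two gametes). Genotype dosage is the haplotype sum, so
    the output contains no Mendelian errors by construction. ``missing_rate``
    masks entries at random to exercise QC/imputation.
    """
    genome = genome or founders.genome
    ped = pedigree.df
    founder_mask = pedigree.is_founder()
    founder_rows = np.nonzero(founder_mask)[0]
    if len(founder_rows) != founders.n_founders:
        raise SimConfigError(
            f"{len(founder_rows)} pedigree founders but haplotypes for {founders.n_founders}"
        )
    single = (ped["sire"].eq("0") ^ ped["dam"].eq("0")).to_numpy()
    if single.any():
        bad = ped["id"].iloc[int(np.nonzero(single)[0][0])]
        raise SimConfigError(f"individual {bad} has exactly one known parent; need both or none")
    rng = np.random.default_rng(seed)
    n, m = len(ped), genome.n_snps
    H = np.zeros((n, 2, m), dtype=np.int8)
    for k, row in enumerate(founder_rows):
        H[row, 0] = founders.haplotypes[2 * k]
        H[row, 1] = founders.haplotypes[2 * k + 1]
    idx = {iid: k for k, iid in enumerate(ped["id"])}
    sires = ped["sire"].to_list()
    dams = ped["dam"].to_list()
    for row in pedigree.topological_order():
        if founder_mask[row]:
            continue
        H[row, 0] = _meiosis(H[idx[sires[row]]], genome, rng)
        H[row, 1] = _meiosis(H[idx[dams[row]]], genome, rng)
    dos = (H[:, 0, :].astype(np.int8) + H[:, 1, :].astype(np.int8))
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos = np.where(mask, np.int8(MISSING), dos)
    gset = GenotypeSet(samples=list(ped["id"]), dosages=dos, snp_map=genome.to_frame())
    if return_haplotypes:
        return gset, H
    return gset


@dataclass
class SimTruth:
    """True simulated quantities kept aside for recovery tests."""

    ids: list[str]
    traits: list[str]
    u: np.ndarray  # (n, t) true breeding values
    Vg: np.ndarray
    Ve: np.ndarray
    Vg_poly: np.ndarray
    qtl_effects: list[tuple[int, np.ndarray]]  # (snp index, per-trait effect)
    qtl_var_pct: dict[str, list[float]]  # trait -> % of genetic variance per QTL

    def u_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.u, columns=[f"u_{t}" for t in self.traits])
        df.insert(0, "id", self.ids)
        return df


def _resolve_qtls(model: TraitModel, genotypes: GenotypeSet) -> tuple[list, np.ndarray, dict]:
    """Turn QTL specs into per-trait effect vectors and the residual polygenic Vg."""
    t = len(model.traits)
    p = genotypes.allele_freq()
    var_qtl = np.zeros((t, t))
    resolved = []
    qtl_var_pct: dict[str, list[float]] = {tr: [] for tr in model.traits}
    for q in model.qtls:
        j = int(q.snp_index)
        if not (0 <= j < genotypes.n_snps):
            raise SimConfigError(f"QTL SNP index {j} outside map")
        two_pq = 2.0 * p[j] * (1.0 - p[j])
        if q.effects is not None:
            beta = np.asarray(q.effects, dtype=float)
        elif q.var_fraction:
            if two_pq <= 0:
                raise SimConfigError(f"QTL SNP {j} is monomorphic")
            beta = np.zeros(t)
            for tr, frac in q.var_fraction.items():
                k = model.trait_index(tr)
                beta[k] = np.sqrt(frac * model.Vg[k, k] / two_pq)
        else:
            raise SimConfigError("QTL needs effects or var_fraction")
        var_qtl += two_pq * np.outer(beta, beta)
        resolved.append((j, beta))
        for k, tr in enumerate(model.traits):
            if model.Vg[k, k] > 0:
                qtl_var_pct[tr].append(100.0 * two_pq * beta[k] ** 2 / model.Vg[k, k])
    if np.any(np.diag(var_qtl) > np.diag(model.Vg) + 1e-12):
        bad = model.traits[int(np.argmax(np.diag(var_qtl) - np.diag(model.Vg)))]
        raise SimConfigError(f"QTL variance exceeds genetic variance for trait {bad}")
    Vg_poly = nearest_psd(model.Vg - var_qtl, eps=0.0)
    return resolved, Vg_poly, qtl_var_pct


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    model: TraitModel,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate trait records for all non-founder individuals.

    True breeding values combine a polygenic part (standardized dosages times
    i.i.d. multivariate normal SNP effects, scaled so cov(u) targets Vg minus
    the major-QTL contribution) with the listed major QTL. Phenotypes add
    cohort, overmature-egg and spawning-week fixed effects and residuals with
    covariance Ve. Raw spawn measures (50-egg length, 2.5 ml spoon weight and
    count, calendar spawning week) are emitted so the trait-derivation code can
    be exercised on this table.
    """
    rng = np.random.default_rng(seed)
    traits = model.traits
    t = len(traits)
    samples = genotypes.samples
    if samples != pedigree.ids:
        genotypes = genotypes.subset(samples=pedigree.ids)
    if genotypes.missing_mask().any():
        raise SimConfigError("phenotype simulation needs complete genotypes")
    n = genotypes.n_samples
    M = genotypes.dosages.astype(np.float64)
    pfreq = M.mean(axis=0) / 2.0
    resolved_qtl, Vg_poly, qtl_var_pct = _resolve_qtls(model, genotypes)
    qtl_idx = {j for j, _ in resolved_qtl}
    scale = np.sqrt(2.0 * pfreq * (1.0 - pfreq))
    usable = (scale > 0) & ~np.isin(np.arange(genotypes.n_snps), list(qtl_idx))
    W = (M[:, usable] - 2.0 * pfreq[usable]) / scale[usable]
    m_poly = W.shape[1]
    if m_poly == 0:
        raise SimConfigError("no polymorphic SNPs for the polygenic background")
    chol_g = np.linalg.cholesky(Vg_poly + 1e-12 * np.eye(t))
    alpha = rng.standard_normal((m_poly, t)) @ chol_g.T / np.sqrt(m_poly)
    u = W @ alpha
    for j, beta in resolved_qtl:
        u += np.outer(M[:, j] - 2.0 * pfreq[j], beta)

    chol_e = np.linalg.cholesky(model.Ve + 1e-12 * np.eye(t))
    e = rng.standard_normal((n, t)) @ chol_e.T
    Y = model.means[None, :] + u + e

    ped = pedigree.df
    is_off = (~pedigree.is_founder()) & (~ped["cohort"].isin([PARENT_COHORT]).to_numpy())
    cohorts = ped["cohort"].to_numpy()
    for c, eff in model.cohort_effects.items():
        Y[cohorts == c] += np.asarray(eff)[None, :]

    overmature = rng.random(n) < model.overmature_prevalence
    for tr, eff in model.overmature_effects.items():
        Y[overmature, model.trait_index(tr)] += eff

    # spawning week is the realized SD measure: rank offset from the cohort's
    # first week, then a covariate for the other traits
    k_sd = model.trait_index("SD") if "SD" in traits else None
    if k_sd is not None:
        rank = np.clip(np.round(Y[:, k_sd]), 1, 8).astype(int)
        first = np.array([model.first_spawning_week.get(c, 1) for c in cohorts])
        week = first + rank - 1
        for c, slopes in model.week_slopes.items():
            rows = cohorts == c
            dev = rank[rows] - float(np.mean(rank[is_off]))
            for tr, slope in slopes.items():
                Y[rows, model.trait_index(tr)] += slope * dev
    else:
        week = np.ones(n, dtype=int)
        rank = week.copy()

    out = pd.DataFrame({"id": ped["id"], "cohort": cohorts})
    out["overmature"] = overmature.astype(int)
    out["spawning_week"] = week
    for k, tr in enumerate(traits):
        out[tr] = Y[:, k]
    if k_sd is not None:
        out["SD"] = np.minimum(rank, 5).astype(float)

    # raw measures consistent with the simulated ED / EW / SW values
    if "ED" in traits and "EW" in traits:
        ed = Y[:, model.trait_index("ED")]
        ew = Y[:, model.trait_index("EW")]
        out["length_50_eggs"] = 50.0 * ed + rng.normal(0.0, model.length50_noise_mm, n)
        egg_vol = np.pi / 6.0 * np.clip(ed, 1e-3, None) ** 3  # mm^3
        count = np.clip(np.round(2500.0 * model.egg_packing_fraction / egg_vol
                                 + rng.normal(0, 2.0, n)), 1, None).astype(int)
        out["spoon_count"] = count
        out["spoon_weight"] = count * np.clip(ew, 1e-3, None) / 1000.0 + rng.normal(
            0.0, model.spoon_weight_noise_g, n
        )
    keep = out[is_off].reset_index(drop=True)
    truth = SimTruth(
        ids=list(ped["id"]),
        traits=list(traits),
        u=u,
        Vg=model.Vg.copy(),
        Ve=model.Ve.copy(),
        Vg_poly=Vg_poly,
        qtl_effects=resolved_qtl,
        qtl_var_pct=qtl_var_pct,
    )
    return keep, truth


@dataclass
class SimulatedStudy:
    pedigree: Pedigree
    genotypes: GenotypeSet  # with injected missingness (if any)
    genotypes_complete: GenotypeSet
    phenotypes: pd.DataFrame
    truth: SimTruth
    genome: GenomeMap
    model: TraitModel


def simulate_study(
    seed: int,
    design: MatingDesign | None = None,
    genome: GenomeMap | None = None,
    model: TraitModel | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.7,
    missing_rate: float = 0.01,
) -> SimulatedStudy:
    """One-call simulation of the default study population."""
    design = design or MatingDesign.default()
    genome = genome or GenomeMap.uniform()
    model = model or TraitModel.default()
    ss = np.random.SeedSequence(seed)
    s_ped, s_hap, s_drop, s_phe, s_miss = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]
    ped = simulate_pedigree(design, seed=s_ped)
    founders = simulate_founder_haplotypes(
        genome, n_founders=len(ped.founders), maf_range=maf_range, ld_rho=ld_rho, seed=s_hap
    )
    complete = gene_drop(ped, founders, genome, seed=s_drop, missing_rate=0.0)
    pheno, truth = simulate_phenotypes(ped, complete, model, seed=s_phe)
    if missing_rate > 0:
        rng = np.random.default_rng(s_miss)
        mask = rng.random(complete.dosages.shape) < missing_rate
        dos = np.where(mask, np.int8(MISSING), complete.dosages)
        observed = GenotypeSet(complete.samples, dos, complete.snp_map.copy())
    else:
        observed = complete
    return SimulatedStudy(ped, observed, complete, pheno, truth, genome, model)
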