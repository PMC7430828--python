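# Methods

## The population model

The synthetic generator emulates a two-cohort rainbow trout broodstock bred in
factorial mating plans. Its default layout is 7 plans totalling 83 dams and 71
sires (six plans of 12 dams × 10 sires, one of 11 × 11), with plans 1–4
assigned to cohort C1 and 5–7 to C2 and a configurable total offspring count
(default 1346) allocated round-robin over the full factorial of crosses. The
plan parents are themselves bred from a shared grandparent pool (default 12
grandsires × 40 granddams), so the two cohorts are related through common
ancestry; without that layer, across-cohort pedigree prediction would carry
literally zero information, rather than the reduced-but-positive information
seen in real multi-cohort broodstocks.

Founder haplotypes are drawn from a first-order Markov model: a latent
Gaussian AR(1) per haplotype, thresholded at each SNP's allele-frequency
quantile. The latent correlation between adjacent SNPs is
`ld_rho ** (gap_bp / ld_scale_bp)` (defaults 0.7 and 100 kb), so LD decays
with physical distance and `ld_rho = 0` gives linkage equilibrium. MAFs are
uniform on a configurable range (default 0.05–0.5). Gene dropping transmits
one recombinant haplotype per parent; crossover counts per chromosome are
Poisson on the cM length implied by a uniform `cm_per_mb` (default 1.3,
roughly the genome-wide average for salmonids), i.e. Haldane's model with no
interference. Genotypes are haplotype sums, so the output contains no
Mendelian errors by construction; missingness (default 1%) is injected
afterwards to exercise QC and imputation.

## Traits

Seven traits are simulated jointly: spawning date (SD, week rank 1–5), body
weight before/after spawning (FW/PW, g), spawn weight (SW, g), egg number
(EN), egg weight (EW, mg) and egg diameter (ED, mm). The default genetic and
phenotypic correlation structure and the trait means/SDs are those of a
commercial broodstock at 2 years of age — heritabilities 0.27 (SD), 0.30 (FW),
0.33 (PW), 0.32 (SW), 0.24 (EN), 0.27 (EW), 0.44 (ED); strong genetic
correlations rg(SW,EN) ≈ 0.86 and rg(EW,ED) ≈ 0.99; body weights essentially
uncorrelated with the egg traits. Correlation matrices assembled from rounded
published-style values are slightly indefinite; they are repaired by
eigenvalue clipping at the correlation level with renormalization, which
preserves the heritabilities exactly and moves the correlations by at most
~0.01 (rg(SW,EN) becomes 0.855, rg(EW,ED) 0.985).

True breeding values are built from standardized dosages times i.i.d.
multivariate normal SNP effects, scaled so cov(u) targets Vg minus the
contribution of any listed major QTL (specified either as explicit per-trait
allele-substitution effects or as a fraction of the trait's genetic variance,
resolved against the realized 2p(1−p) of the chosen SNP; a fraction above 1
is an error). This marker-based construction lets both A- and G-based
analyses apply to the same data. Fixed effects: a cohort contrast, an
overmature-egg Bernoulli flag (default prevalence 10%, effects of ±0.2–0.3
phenotypic SD on FW, SW, EN, ED — magnitudes are not published, so these are
package defaults), and a spawning-week covariate nested within cohort. The
spawning week is derived from the individual's own SD value (the week *is*
the spawning-date measure), so the week covariate genuinely carries
SD-correlated genetic signal, as it does in real data.

Raw spawn measures are emitted alongside: the length of 50 aligned eggs
(50·ED plus 1 mm measurement noise), and the weight and count of eggs in a
2.5 ml sampling spoon consistent with the simulated EW and an egg-packing
fraction of 0.6. One deliberate approximation: EN is simulated jointly from
the trait covariance matrix, while the analysis derivation defines
EN = 1000·SW/EW; both constraints cannot hold exactly at once, so the
raw-derived EN approximates the simulated EN. Parameter-recovery tests use
the simulated trait columns.

What the generator does **not** model: selection, sex chromosomes, inbreeding
depression, dominance/epistasis, genotyping error (beyond missingness), map
errors, or year-specific G×E beyond the cohort shift. Passing tests therefore
show the estimators behave correctly under an additive polygenic model with
this family structure — not that real data meet those assumptions.

## Quality control

ED = length of 50 eggs / 50; EW = 1000 · spoon weight / spoon count;
EN = round(1000 · SW / EW); SD = week − first cohort week + 1, capped at 5.
Undefined derivations (zero spoon count or egg weight) yield missing markers.
Phenotype outliers are records more than 4 SD from the trait mean (single
pass, n−1 denominator, applied per trait over the whole dataset; a per-cohort
variant is a caller choice since the original procedure is ambiguous). SNP
retention requires call rate > 0.97, Hardy-Weinberg χ² p > 1e−4 and
MAF > 0.05, all strict; the HWE test can be restricted to founders to avoid
family structure inflating the statistic. Mendelian checks use trio
compatibility (duo rule for a single genotyped parent) and summarize the
median error count over SNPs with at least one error — "median" interprets an
ambiguous summary statistic in the source procedure. Missing genotypes are
filled with 2p̂ (rounded to {0,1,2} or kept fractional); this is a frequency
fill, not haplotype imputation, and is accurate enough at ~1% missingness
(the G matrix moves by < 0.05 per entry in tests).

## Relationship matrices

A is computed with the tabular method (exact inbreeding through the
recursion). G is VanRaden's method 1 with observed-frequency centering and
optional per-SNP weights d; a ridge of 1e−4 is added to the diagonal so G is
invertible (with observed-frequency centering the vector of ones is an exact
null vector of the unridged G). No blending with A is applied, since the
genomic analyses operate on genotyped animals only.

## Mixed models and REML

Henderson's equations are assembled densely with trait-specific residual
partitions, so multi-trait fits handle trait-wise missing records; the
prediction-error covariance of the genetic effects is available from the
inverted coefficient matrix (single-trait fits). REML works in the eigenbasis
of the kinship among record animals, making each iteration O(n·t³): a few EM
warm-up steps (accepted only if the restricted likelihood does not worsen),
then AI updates with step halving, a positive floor of 1e−6 (standardized
scale) on variance diagonals, and a feasibility check keeping Vg and Ve in
the PSD cone so genetic correlations cannot leave [−1, 1]. Convergence is
declared when the maximum relative parameter change drops below `tol`
(default 1e−8) or the restricted likelihood is stationary (< 1e−6 change over
three consecutive accepted steps); if AI stalls — which happens on near-flat
ridges of 4-trait surfaces — an exact-gradient L-BFGS polish finishes from
the current point. Standard errors come from the inverse AI matrix at the
optimum, with delta-method SEs for h² and rg. Traits are standardized
internally and components returned on the observed scale. REML is
complete-case over the model's traits; the MME solver, not the REML core,
handles missing-record patterns.

The genetic-parameter table runs the four 4-trait combinations
[BW, SD, EW, SW], [BW, SD, EW, EN], [BW, SD, ED, EN], [BW, SD, ED, SW]
(BW = FW by default; the PW set is a parameter) and averages each parameter
over the models containing it; the near-unity pairs FW–PW, SW–EN and EW–ED
are estimated in dedicated bivariate models because joint 4-trait fits with
two nearly identical traits do not converge reliably. SD (an ordinal 1–5
rank) is modelled as Gaussian, as linear animal models in this field do;
threshold models are out of scope. Random full-sib-family and maternal
effects are omitted from the default models.

## GWAS

GBLUP scan: `â = d Z′[Z d Z′]⁻¹ ĝ` with the ridged G used consistently;
`Var(â_j)` is propagated from `Var(ĝ) = G·σ̂²_a − PEV`, which makes
`â_j / sd(â_j)` equivalent to a single-marker GLS test — the explicit GLS
engine is kept as a cross-check (rank correlation of −log10 p > 0.95 in
tests) and the null type-I error at p < 0.01 is calibrated within
[0.005, 0.02]. Thresholds are 1% Bonferroni: chromosome-wide
−log10(0.01/(m/30)) and genome-wide −log10(0.01/m); at the 29,799-SNP study
scale these are 5.0 and 6.5. Confidence intervals absorb SNPs with
−log10 p > peak − 1.5 within a sliding 1 Mb window re-anchored at the current
interval edge, both directions independently; interval bounds are the
outermost absorbed SNPs (1-based, closed); peak ties break to the smaller bp.

BayesCπ: Gibbs cycle sampling fixed effects (flat prior), per-SNP inclusion
indicator and effect (common slab variance), the slab variance and residual
variance (scaled inverse χ², ν = 4), and π from Beta(300 + m_in,
29800 + m − m_in). The slab prior scale is tuned so the implied prior genetic
variance matches a REML pre-fit (or h²·var(y) when none is supplied).
Production chains run 100,000 cycles (burn-in 5,000, thinning 20 → 4,750
saved samples); the desk-scale configuration used by the simulation studies
runs 20,000/2,000. Convergence is checked numerically as the inter-chain
correlation of posterior-mean genomic values (> 0.99 in tests). Bayes factors
use P_i clamped to [1/S, 1 − 1/S] and π_ref fixed at the prior mean (~0.997%);
the posterior-mean alternative is an argument. Credibility intervals: peaks
with logBF ≥ 6 processed greedily in descending order, absorbing logBF ≥ 3
SNPs within the sliding 1 Mb window, without reusing SNPs claimed by a
stronger region; classification is strong at logBF ≥ 8, and a 6–8 peak is
putative unless its region explains ≥ 1% of the genetic variance. The % of
genetic variance of a region is var(Z_R a_R)/var(Z a) over animals, averaged
over saved samples (samples with zero total genomic variance are skipped);
the same estimator — applied to the point estimates — scores GBLUP regions,
where shrinkage makes it conservative.

## Cross-validation

Scenarios follow the 1346-fish reference design and scale proportionally to
other population sizes: T+ trains on 1077/1346 of the animals and validates
on the remaining 269/1346; T− is a 672/1346 subset of the same replicate's
training animals with the identical validation fish; T1/T2 train on one
cohort and validate on the other. 40 Monte-Carlo replicates for T±. Each
replicate refits the model on training records only (pedigree links retained
for BLUP; G always spans all genotyped animals), with variance components
re-estimated per training set by default (switchable to fixed full-data
components). Accuracy divides by √h² from the full-data REML fit under the
method's own kinship; corrected phenotypes use the full-data fixed-effect
solutions. Design columns that become empty or aliased in a training subset
(e.g. the cohort contrast in a single-cohort training set) are pruned by
pivoted QR rather than failing.

## Validation experiments and problem sizes

The experiments module (run by `scripts/acceptance.py` and the acceptance
tests) uses these desk-scale sizes, chosen for stable Monte-Carlo estimates
on a single CPU:

* Heritability recovery: h² = 0.3, 20 replicates of 2,000 phenotyped
  offspring in a two-generation design (1,000 per generation over a 400-founder
  base, 1,500 SNPs). Two phenotyped generations are used deliberately:
  parent–offspring covariance adds information beyond sib contrasts, putting
  the REML standard error near 0.035 so the ±0.07 recovery window is ≈ 2 SE;
  pure sib designs at the same n have SE ≈ 0.042.
* Bivariate rg(SW, EN) recovery: one 2,000-offspring default-design
  population.
* GWAS null calibration: 1,000 offspring × 5,000 SNPs, polygenic only.
* Localization power: 20 replicates of 1,000 offspring × 2,000 SNPs with a
  QTL carrying 10% of the genetic variance of ED; a hit is a genome-wide peak
  within 1 Mb of the causal SNP.
* BayesCπ signal recovery: 1,000 offspring × 2,000 SNPs, causal SNP at 30% of
  phenotypic variance, desk-scale chain.
* Cross-validation: 650 offspring (scenario sizes scaled proportionally),
  40 replicates, trait ED.

## Known limitations

* The PLINK reader infers the counted allele per SNP from the data, so a SNP
  observed monomorphic cannot be harmonized unambiguously across formats.
* PEV extraction (and hence the analytic GWAS standard errors) is implemented
  for single-trait fits; multi-trait scans would need the trait-block PEV.
* Dense linear algebra throughout: comfortable to a few thousand animals and
  tens of thousands of SNPs, not to national-evaluation scale.
* The BayesC slab uses a common variance (no per-SNP variances, no BayesB/R
  variants), and credibility-interval construction is greedy and
  non-overlapping by design.
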