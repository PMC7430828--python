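import numpy as np
import pandas as pd
import pytest

from roegen.bayescpi import (
    BayesCConfig,
    BayesCPosterior,
    bayes_factors,
    bayescpi_sample,
    credibility_interval,
    gebv_samples,
    qtl_variance_explained,
    run_chains,
)
from roegen.mixedmodel import build_design, default_design_for
from roegen.simdata import GenomeMap, MatingDesign, QtlSpec, TraitModel, simulate_study


class TestConfig:
    def test_production_chain_layout(self):
        cfg = BayesCConfig()
        assert cfg.n_saved == 4750  # (100000 - 5000) / 20
        assert cfg.pi_prior_mean == pytest.approx(300 / 30_100)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            BayesCConfig(cycles=100, burn_in=200)
        with pytest.raises(ValueError):
            BayesCConfig(thin=0)
        with pytest.raises(ValueError):
            BayesCConfig(pi_alpha=0)


def _posterior_from_samples(samples, Z, pos=None):
    m = samples.shape[1]
    snp_map = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": ["c1"] * m,
                            "pos": pos or list(range(1, m + 1))})
    cfg = BayesCConfig.desk_scale()
    post = BayesCPosterior(
        snp_map=snp_map,
        inclusion_prob=(samples != 0).mean(axis=0),
        mean_effect=samples.mean(axis=0),
        effect_samples=samples.astype(np.float32),
        sigma_a2=np.ones(len(samples)),
        sigma_e2=np.ones(len(samples)),
        pi=np.full(len(samples), 0.01),
        beta_samples=np.zeros((len(samples), 1)),
        config=cfg,
        Z=Z,
    )
    return post


class TestBayesFactors:
    def test_reference_rate_gives_unit_bf(self):
        samples = np.zeros((100, 1), dtype=np.float32)
        samples[:10, 0] = 1.0  # P_i = 0.1
        post = _posterior_from_samples(samples, np.zeros((5, 1)))
        out = bayes_factors(post, pi_ref=0.1)
        assert out["bf"][0] == pytest.approx(1.0)
        assert out["logbf"][0] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        samples = np.zeros((100, 1), dtype=np.float32)
        samples[:50, 0] = 1.0  # P_i = 0.5
        post = _posterior_from_samples(samples, np.zeros((5, 1)))
        out = bayes_factors(post, pi_ref=0.01)
        assert out["bf"][0] == pytest.approx(99.0)
        assert out["logbf"][0] == pytest.approx(2 * np.log(99.0))

    def test_certain_inclusion_clamped_finite(self):
        samples = np.ones((4750, 1), dtype=np.float32)
        post = _posterior_from_samples(samples, np.zeros((5, 1)))
        out = bayes_factors(post)
        assert np.isfinite(out["logbf"][0])
        p_clamped = 1 - 1 / 4750
        expect = (p_clamped / (1 - p_clamped)) / (post.config.pi_prior_mean /
                                                  (1 - post.config.pi_prior_mean))
        assert out["bf"][0] == pytest.approx(expect)

    def test_logbf_monotone_in_inclusion_probability(self):
        samples = np.zeros((100, 5), dtype=np.float32)
        for j, k in enumerate([5, 20, 50, 80, 95]):
            samples[:k, j] = 1.0
        post = _posterior_from_samples(samples, np.zeros((5, 5)))
        out = bayes_factors(post)
        assert np.all(np.diff(out["logbf"]) > 0)


class TestVarianceExplained:
    def test_full_region_is_total(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(20, 4))
        samples = rng.normal(size=(50, 4)).astype(np.float32)
        post = _posterior_from_samples(samples, Z)
        pct, skipped = qtl_variance_explained(post, np.arange(4))
        assert pct == pytest.approx(100.0)
        assert skipped == 0

    def test_never_included_region_is_zero(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(20, 4))
        samples = rng.normal(size=(50, 4)).astype(np.float32)
        samples[:, 2] = 0.0
        post = _posterior_from_samples(samples, Z)
        pct, _ = qtl_variance_explained(post, np.array([2]))
        assert pct == pytest.approx(0.0)


class TestCredibilityInterval:
    def test_single_strong_snp_region(self):
        scan = pd.DataFrame({
            "snp": ["a", "b", "c"], "chrom": ["c1"] * 3,
            "pos": [1_000_000, 5_000_000, 9_000_000],
            "logbf": [1.0, 9.0, 2.0],
        })
        regions = credibility_interval(scan)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (5_000_000, 5_000_000)
        assert r.classification == "strong"

    def test_chain_of_members_spans_until_gap(self):
        # members every 0.4 Mb chain into the interval; a >= 1 Mb gap breaks it
        pos = [1.0, 1.4, 1.8, 2.2, 3.8, 4.2]
        logbf = [3.5, 4.0, 7.0, 3.2, 3.5, 3.5]
        scan = pd.DataFrame({
            "snp": [f"s{k}" for k in range(6)], "chrom": ["c1"] * 6,
            "pos": (np.array(pos) * 1e6).astype(int), "logbf": logbf,
        })
        regions = credibility_interval(scan)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1_000_000, 2_200_000)

    def test_putative_peak_promoted_by_variance_share(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(50, 3))
        # SNP 1 included with a modest effect in every sample -> its region
        # carries a few % of the genomic variance
        samples = np.zeros((200, 3), dtype=np.float32)
        samples[:, 0] = rng.normal(0, 1.0, 200)
        samples[:, 1] = rng.normal(0, 0.2, 200)
        post = _posterior_from_samples(samples, Z, pos=[1_000_000, 8_000_000, 15_000_000])
        scan = post.snp_map.copy()
        scan["logbf"] = [2.0, 7.0, 1.0]
        regions = credibility_interval(scan, posterior=post)
        assert len(regions) == 1
        assert regions[0].var_explained_pct >= 1.0
        assert regions[0].classification == "strong"

    def test_below_evidence_threshold_yields_nothing(self):
        scan = pd.DataFrame({
            "snp": ["a"], "chrom": ["c1"], "pos": [1], "logbf": [5.9],
        })
        assert credibility_interval(scan) == []


@pytest.fixture(scope="module")
def causal_setup():
    genome = GenomeMap.uniform(4, 125, 25.0)  # 500 SNPs
    qtl = 2 * 125 + 60
    model = TraitModel.default(qtls=[QtlSpec(snp_index=qtl, var_fraction={"ED": 0.68})])
    study = simulate_study(
        seed=5, design=MatingDesign.default(total_offspring=500),
        genome=genome, model=model, missing_rate=0.0,
    )
    phe = study.phenotypes
    gen = study.genotypes_complete.subset(samples=list(phe["id"]))
    X, _ = build_design(phe, default_design_for("ED"))
    y = phe["ED"].to_numpy()
    ystar = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return study, gen, ystar, qtl


class TestSampler:
    def test_pure_noise_posterior_pi_near_prior_mean(self, causal_setup):
        _, gen, ystar, _ = causal_setup
        rng = np.random.default_rng(0)
        ynull = rng.normal(size=len(ystar))
        post = bayescpi_sample(
            ynull, gen, config=BayesCConfig.desk_scale(cycles=6000, burn_in=1000), seed=9
        )
        assert 0.005 <= post.pi.mean() <= 0.02

    def test_causal_snp_recovered(self, causal_setup):
        _, gen, ystar, qtl = causal_setup
        post = bayescpi_sample(
            ystar, gen, config=BayesCConfig.desk_scale(cycles=6000, burn_in=1000), seed=3
        )
        assert post.inclusion_prob[qtl] > 0.8
        null = np.delete(post.inclusion_prob, qtl)
        assert np.median(null) < 0.05

    def test_deterministic_given_seed(self, causal_setup):
        _, gen, ystar, _ = causal_setup
        cfg = BayesCConfig.desk_scale(cycles=1200, burn_in=200)
        a = bayescpi_sample(ystar, gen, config=cfg, seed=7)
        b = bayescpi_sample(ystar, gen, config=cfg, seed=7)
        assert np.array_equal(a.effect_samples, b.effect_samples)
        assert np.array_equal(a.pi, b.pi)

    def test_chains_agree_on_genomic_values(self, causal_setup):
        _, gen, ystar, _ = causal_setup
        cfg = BayesCConfig.desk_scale(chains=2)
        chains = run_chains(ystar, gen, config=cfg, seed=5)
        r = np.corrcoef(chains[0].gebv_mean, chains[1].gebv_mean)[0, 1]
        assert r > 0.99

    def test_saved_sample_count(self, causal_setup):
        _, gen, ystar, _ = causal_setup
        cfg = BayesCConfig.desk_scale(cycles=2000, burn_in=500, thin=10)
        post = bayescpi_sample(ystar, gen, config=cfg, seed=1)
        assert post.n_saved == (2000 - 500) // 10
        assert gebv_samples(post).shape == (gen.n_samples, post.n_saved)

    def test_small_sample_rejected(self, causal_setup):
        _, gen, _, _ = causal_setup
        with pytest.raises(Exception, match="at least 50"):
            bayescpi_sample(np.zeros(10), gen.subset(samples=gen.samples[:10]), seed=0)
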