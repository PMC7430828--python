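import numpy as np
import pandas as pd
import pytest

from roegen.containers import Pedigree, PedigreeError
from roegen.qc import count_mendelian_errors
from roegen.simdata import (
    FounderHaplotypes,
    GenomeMap,
    MatingDesign,
    QtlSpec,
    SimConfigError,
    TraitModel,
    _meiosis,
    gene_drop,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)
from conftest import single_trait_model


class TestMatingDesign:
    def test_default_design_matches_broodstock_structure(self):
        d = MatingDesign.default()
        assert d.n_plans == 7
        assert d.n_dams == 83
        assert d.n_sires == 71

    def test_counts_must_be_positive(self):
        with pytest.raises(SimConfigError):
            MatingDesign([0], [3], ["C1"])
        with pytest.raises(SimConfigError):
            MatingDesign([2], [3], ["C1"], offspring_per_cross=0)


class TestSimulatePedigree:
    def test_parent_generation_has_83_dams_and_71_sires(self):
        ped = simulate_pedigree(MatingDesign.default(), seed=1)
        df = ped.df
        offspring = df[df["cohort"].str.startswith("C")]
        assert offspring["dam"].nunique() == 83
        assert offspring["sire"].nunique() == 71
        assert len(offspring) == 1346

    def test_offspring_parents_come_from_the_same_plan(self):
        ped = simulate_pedigree(MatingDesign.default(), seed=1)
        off = ped.df[ped.df["cohort"].str.startswith("C")]
        # dam D<plan>_<k> and sire S<plan>_<k> must share the plan number
        plans_d = off["dam"].str.extract(r"D(\d+)_")[0]
        plans_s = off["sire"].str.extract(r"S(\d+)_")[0]
        assert (plans_d == plans_s).all()

    def test_minimal_design_gives_full_sibs(self):
        d = MatingDesign([1], [1], ["C1"], offspring_per_cross=2,
                         n_grandsires=0, n_granddams=0)
        ped = simulate_pedigree(d, seed=0)
        assert len(ped) == 4
        off = ped.df[~ped.is_founder()]
        assert len(off) == 2
        assert off["sire"].nunique() == 1 and off["dam"].nunique() == 1

    def test_determinism(self):
        a = simulate_pedigree(MatingDesign.default(), seed=5).df
        b = simulate_pedigree(MatingDesign.default(), seed=5).df
        pd.testing.assert_frame_equal(a, b)

    def test_cycles_are_rejected_by_container(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(pd.DataFrame({
                "id": ["a", "b"], "sire": ["b", "a"], "dam": ["0", "0"],
                "cohort": ["x", "x"],
            }))


class TestFounderHaplotypes:
    def test_no_ld_gives_uncorrelated_adjacent_markers(self):
        genome = GenomeMap.uniform(1, 50, 10.0)
        fh = simulate_founder_haplotypes(genome, 5000, ld_rho=0.0, seed=1)
        h = fh.haplotypes.astype(float)
        cors = [abs(np.corrcoef(h[:, j], h[:, j + 1])[0, 1]) for j in range(20)]
        assert np.mean(cors) < 0.02

    def test_ld_decays_with_distance(self):
        genome = GenomeMap.uniform(1, 100, 10.0)  # 100 kb spacing
        fh = simulate_founder_haplotypes(genome, 3000, ld_rho=0.9, seed=2)
        h = fh.haplotypes.astype(float)
        r2_adj = np.mean([np.corrcoef(h[:, j], h[:, j + 1])[0, 1] ** 2 for j in range(60)])
        r2_far = np.mean([np.corrcoef(h[:, j], h[:, j + 10])[0, 1] ** 2 for j in range(60)])
        assert r2_adj > 0.1
        assert r2_adj > r2_far

    def test_realized_frequencies_near_target(self):
        genome = GenomeMap.uniform(1, 200, 20.0)
        fh = simulate_founder_haplotypes(genome, 500, maf_range=(0.3, 0.3), seed=3)
        maf = np.minimum(fh.haplotypes.mean(axis=0), 1 - fh.haplotypes.mean(axis=0))
        assert maf.min() > 0.2 and maf.max() < 0.4

    def test_invalid_inputs(self):
        genome = GenomeMap.uniform(1, 10, 1.0)
        with pytest.raises(SimConfigError):
            simulate_founder_haplotypes(genome, 10, maf_range=(0.0, 0.5))
        with pytest.raises(SimConfigError):
            simulate_founder_haplotypes(genome, 10, ld_rho=1.0)


class TestGeneDrop:
    def test_homozygous_founders_give_homozygous_descendants(self):
        d = MatingDesign([2], [2], ["C1"], offspring_per_cross=3,
                         n_grandsires=0, n_granddams=0)
        ped = simulate_pedigree(d, seed=0)
        genome = GenomeMap.uniform(2, 30, 10.0)
        hap = np.zeros((2 * 4, genome.n_snps), dtype=np.int8)
        fh = FounderHaplotypes(hap, np.zeros(genome.n_snps), genome)
        gset = gene_drop(ped, fh, seed=1)
        assert (gset.dosages == 0).all()

    def test_single_known_parent_rejected(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["s", "o"], "sire": ["0", "s"], "dam": ["0", "0"],
            "cohort": ["F0", "C1"],
        }))
        genome = GenomeMap.uniform(1, 5, 1.0)
        fh = simulate_founder_haplotypes(genome, 1, seed=0)
        with pytest.raises(SimConfigError, match="exactly one known parent"):
            gene_drop(ped, fh)

    def test_haldane_recombination_fraction(self):
        # two SNPs 1 Mb apart at 1 cM/Mb: r = (1 - exp(-0.02)) / 2 ~ 0.0099
        genome = GenomeMap(["c1"], [np.array([1, 1_000_001])], cm_per_mb=1.0)
        parent = np.array([[0, 0], [1, 1]], dtype=np.int8)  # fully informative
        rng = np.random.default_rng(7)
        n = 120_000
        rec = 0
        for _ in range(n):
            g = _meiosis(parent, genome, rng)
            rec += g[0] != g[1]
        expected = (1 - np.exp(-0.02)) / 2
        assert rec / n == pytest.approx(expected, rel=0.25)

    def test_gene_dropped_trios_have_zero_mendelian_errors(self, complete_study):
        rep = count_mendelian_errors(complete_study.genotypes_complete, complete_study.pedigree)
        assert rep.per_snp["errors"].sum() == 0


class TestSimulatePhenotypes:
    def test_breeding_value_covariance_converges_to_vg(self):
        model = TraitModel.default()
        study = simulate_study(
            seed=31,
            design=MatingDesign.default(total_offspring=5000),
            genome=GenomeMap.uniform(5, 60, 25.0),
            model=model,
            missing_rate=0.0,
        )
        off = ~study.pedigree.is_founder()
        emp = np.cov(study.truth.u[off].T)
        sd_emp, sd_true = np.sqrt(np.diag(emp)), np.sqrt(np.diag(model.Vg))
        assert np.all(np.abs(sd_emp - sd_true) / sd_true < 0.10)

    def test_phenotype_regression_on_true_u_is_unbiased(self):
        model = single_trait_model(h2=0.3)
        design = MatingDesign.default(total_offspring=5000)
        ped = simulate_pedigree(design, seed=41)
        genome = GenomeMap.uniform(4, 50, 25.0)
        fh = simulate_founder_haplotypes(genome, len(ped.founders), seed=42)
        gset = gene_drop(ped, fh, seed=43)
        pheno, truth = simulate_phenotypes(ped, gset, model, seed=44)
        rows = ped.index_of(pheno["id"])
        u = truth.u[rows, 0]
        y = pheno["T"].to_numpy() - pheno["T"].mean()
        slope = np.dot(u, y) / np.dot(u, u)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_qtl_variance_deducted_and_overflow_rejected(self, complete_study):
        gen = complete_study.genotypes_complete
        ped = complete_study.pedigree
        model = TraitModel.default(qtls=[QtlSpec(snp_index=10, var_fraction={"ED": 0.5})])
        _, truth = simulate_phenotypes(ped, gen, model, seed=1)
        k = model.trait_index("ED")
        assert truth.Vg_poly[k, k] < model.Vg[k, k]
        bad = TraitModel.default(qtls=[QtlSpec(snp_index=10, var_fraction={"ED": 1.5})])
        with pytest.raises(SimConfigError, match="exceeds genetic variance"):
            simulate_phenotypes(ped, gen, bad, seed=1)

    def test_raw_measures_consistent_with_traits(self, complete_study):
        phe = complete_study.phenotypes
        assert np.allclose(phe["length_50_eggs"] / 50.0, phe["ED"], atol=0.15)
        ew_derived = 1000.0 * phe["spoon_weight"] / phe["spoon_count"]
        assert np.corrcoef(ew_derived, phe["EW"])[0, 1] > 0.98

    def test_full_reproducibility(self):
        kw = dict(
            design=MatingDesign.default(total_offspring=80),
            genome=GenomeMap.uniform(2, 20, 5.0),
        )
        a = simulate_study(seed=9, **kw)
        b = simulate_study(seed=9, **kw)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.truth.u, b.truth.u)
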