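import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from roegen.containers import MISSING, GenotypeSet, Pedigree
from roegen.kinship import genomic_relationship_matrix
from roegen.qc import (
    count_mendelian_errors,
    derive_reproduction_traits,
    fill_missing_genotypes,
    filter_outliers,
    snp_qc,
)


def make_gset(dosages, positions=None, chrom="c1", samples=None):
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    pos = positions or list(range(1, m + 1))
    snp_map = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": [chrom] * m, "pos": pos})
    return GenotypeSet(samples or [f"i{k}" for k in range(n)], d, snp_map)


class TestDeriveTraits:
    def test_stated_ratios(self):
        raw = pd.DataFrame({
            "length_50_eggs": [50.0], "spoon_weight": [1.0], "spoon_count": [25],
            "SW": [187.0], "spawning_week": [4], "cohort": ["C1"],
        })
        out = derive_reproduction_traits(raw, {"C1": 3})
        assert out["ED"].iloc[0] == 1.0
        assert out["EW"].iloc[0] == 40.0
        assert out["EN"].iloc[0] == 4675
        assert out["SD"].iloc[0] == 2

    def test_spawning_rank_caps_at_five(self):
        raw = pd.DataFrame({"spawning_week": [3, 9, 12], "cohort": ["C1"] * 3})
        out = derive_reproduction_traits(raw, {"C1": 3})
        assert list(out["SD"]) == [1, 5, 5]

    def test_first_week_defaults_to_cohort_minimum(self):
        raw = pd.DataFrame({"spawning_week": [5, 6, 8, 4], "cohort": ["A", "A", "B", "B"]})
        out = derive_reproduction_traits(raw)
        assert list(out["SD"]) == [1, 2, 5, 1]

    def test_zero_spoon_count_yields_undefined_marker(self):
        raw = pd.DataFrame({
            "spoon_weight": [1.0], "spoon_count": [0], "SW": [100.0],
        })
        out = derive_reproduction_traits(raw)
        assert np.isnan(out["EW"].iloc[0]) and np.isnan(out["EN"].iloc[0])


class TestOutlierFilter:
    def test_planted_outlier_removed_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        mu, sd = x[:99].mean(), x[:99].std(ddof=1)
        x[99] = mu + 6 * sd
        keep = filter_outliers(x)
        # hand oracle: recompute on the full vector
        mu_all, sd_all = x.mean(), x.std(ddof=1)
        expect = np.abs(x - mu_all) <= 4 * sd_all
        assert np.array_equal(keep, expect)
        assert (~keep).sum() == 1 and not keep[99]

    def test_all_within_four_sd_kept(self):
        x = np.array([1.0, 2.0, 3.0, 2.5, 1.5])
        assert filter_outliers(x).all()

    def test_zero_variance_keeps_everything(self):
        assert filter_outliers(np.ones(10)).all()

    def test_missing_pass_through(self):
        x = np.array([1.0, np.nan, 2.0, 100.0])
        keep = filter_outliers(x)
        assert keep[1]

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            filter_outliers(np.array([1.0, np.nan]))


class TestSnpQc:
    def test_call_rate_boundary_is_strict(self):
        d = np.ones((100, 2), dtype=np.int8)
        d[::2, :] = 0  # polymorphic
        d[:3, 0] = MISSING  # call rate exactly 0.97 -> removed (strict >)
        d[:2, 1] = MISSING  # 0.98 -> retained
        g = make_gset(d)
        kept, rep = snp_qc(g)
        assert not rep["kept"][0]
        assert rep["kept"][1]

    def test_hwe_perfect_proportions_retained(self):
        d = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)[:, None]
        kept, rep = snp_qc(make_gset(d))
        assert rep["hwe_p"][0] == pytest.approx(1.0)
        assert rep["kept"][0]

    def test_hwe_hand_chi_square(self):
        # genotype counts 60 / 20 / 20 at n=100: p(alt) = 0.3
        d = np.array([0] * 60 + [1] * 20 + [2] * 20, dtype=np.int8)[:, None]
        kept, rep = snp_qc(make_gset(d))
        n, p = 100, 0.3
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        stat = (((np.array([60, 20, 20]) - exp) ** 2) / exp).sum()
        assert rep["hwe_p"][0] == pytest.approx(chi2.sf(stat, 1))
        assert not rep["kept"][0]  # p ~ 1.6e-7 < 1e-4

    def test_monomorphic_removed_not_raised(self):
        d = np.zeros((50, 1), dtype=np.int8)
        kept, rep = snp_qc(make_gset(d))
        assert kept.n_snps == 0 and not rep["kept"][0]

    def test_idempotent(self, small_study):
        once, rep1 = snp_qc(small_study.genotypes)
        twice, rep2 = snp_qc(once)
        assert list(once.snp_map["snp"]) == list(twice.snp_map["snp"])


def _trio_oracle(s, m, o):
    """Transmission-probability oracle: is offspring dosage o possible?"""
    gam = {0: [0], 1: [0, 1], 2: [1]}
    return any(a + b == o for a in gam[s] for b in gam[m])


class TestMendelianErrors:
    def test_trio_enumeration_matches_oracle(self):
        for s, m, o in itertools.product(range(3), repeat=3):
            ped = Pedigree(pd.DataFrame({
                "id": ["s", "m", "o"], "sire": ["0", "0", "s"],
                "dam": ["0", "0", "m"], "cohort": ["F", "F", "C"],
            }))
            g = make_gset(np.array([[s], [m], [o]]), samples=["s", "m", "o"])
            rep = count_mendelian_errors(g, ped)
            expected = 0 if _trio_oracle(s, m, o) else 1
            assert rep.per_snp["errors"].iloc[0] == expected, (s, m, o)

    def test_single_parent_rule(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["s", "o"], "sire": ["0", "s"], "dam": ["0", "0"],
            "cohort": ["F", "C"],
        }))
        # parent hom-ref, offspring hom-alt -> error; het offspring -> fine
        g = make_gset(np.array([[0, 0], [2, 1]]), samples=["s", "o"])
        rep = count_mendelian_errors(g, ped)
        assert list(rep.per_snp["errors"]) == [1, 0]

    def test_median_over_nonzero_snps(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["s", "m", "o"], "sire": ["0", "0", "s"],
            "dam": ["0", "0", "m"], "cohort": ["F", "F", "C"],
        }))
        g = make_gset(np.array([[0, 0, 0], [0, 0, 0], [2, 0, 2]]), samples=["s", "m", "o"])
        rep = count_mendelian_errors(g, ped)
        assert rep.median_errors_nonzero == 1.0

    def test_no_genotyped_parents_warns(self):
        ped = Pedigree(pd.DataFrame({
            "id": ["x"], "sire": ["0"], "dam": ["0"], "cohort": ["C"],
        }))
        g = make_gset(np.array([[1]]))
        with pytest.warns(UserWarning, match="no genotyped parents"):
            rep = count_mendelian_errors(g, ped)
        assert rep.per_snp["errors"].sum() == 0


class TestFillMissing:
    def test_dosage_fill_at_half_frequency(self):
        d = np.array([[0], [2], [MISSING], [1], [1]], dtype=np.int8)
        filled = fill_missing_genotypes(make_gset(d), mode="dosage")
        assert filled.dosages[2, 0] == pytest.approx(1.0)
        assert filled.fill_mode == "dosage"

    def test_no_missing_is_identity(self, complete_study):
        g = complete_study.genotypes_complete
        filled = fill_missing_genotypes(g, mode="round")
        assert np.array_equal(filled.dosages, g.dosages)

    def test_all_missing_snp_raises(self):
        d = np.full((5, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="no called genotypes"):
            fill_missing_genotypes(make_gset(d))

    def test_fill_tracks_truth_and_preserves_g(self, small_study):
        truth = small_study.genotypes_complete
        observed = small_study.genotypes  # 1% missing injected
        filled = fill_missing_genotypes(observed, mode="dosage")
        miss = observed.missing_mask()
        assert miss.mean() == pytest.approx(0.01, abs=0.005)
        r = np.corrcoef(filled.dosages[miss], truth.dosages[miss])[0, 1]
        assert r > 0 or np.isnan(r)  # frequency fill carries only frequency information
        g_true = genomic_relationship_matrix(truth).G
        g_fill = genomic_relationship_matrix(filled).G
        assert np.max(np.abs(g_true - g_fill)) < 0.05
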