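import numpy as np
import pandas as pd
import pytest

from roegen.kinship import pedigree_relationship_matrix
from roegen.mixedmodel import (
    DesignSpec,
    ModelError,
    build_design,
    default_design_for,
    estimate_parameter_table,
    reml_estimate,
    solve_mme,
)
from roegen.simdata import MatingDesign, simulate_pedigree


def dense_gls_oracle(Y, Xs, A, Vg, Ve):
    """Brute-force multi-trait BLUP: stack observed records, invert V densely."""
    n, t = Y.shape
    obs = [(i, k) for k in range(t) for i in range(n) if not np.isnan(Y[i, k])]
    ps = [X.shape[1] for X in Xs]
    off = np.concatenate([[0], np.cumsum(ps)])
    Xbig = np.zeros((len(obs), off[-1]))
    ybig = np.zeros(len(obs))
    V = np.zeros((len(obs), len(obs)))
    for r, (i, k) in enumerate(obs):
        Xbig[r, off[k]:off[k + 1]] = Xs[k][i]
        ybig[r] = Y[i, k]
        for r2, (i2, k2) in enumerate(obs):
            V[r, r2] = Vg[k, k2] * A[i, i2] + (Ve[k, k2] if i == i2 else 0.0)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(Xbig.T @ Vinv @ Xbig, Xbig.T @ Vinv @ ybig)
    resid = ybig - Xbig @ beta
    U = np.zeros((n, t))
    for j in range(n):
        for k in range(t):
            cov = np.array([Vg[k, k2] * A[j, i2] for (i2, k2) in obs])
            U[j, k] = cov @ Vinv @ resid
    return beta, U


def restricted_m2ll_oracle(y, X, A, vg, ve):
    """-2 restricted log-likelihood, dense formula (constant terms dropped)."""
    V = vg * A + ve * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    r = y - X @ beta
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(C)[1] + r @ Vinv @ r)


@pytest.fixture(scope="module")
def toy_system():
    rng = np.random.default_rng(5)
    n = 8
    df = pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "sire": ["0", "0", "0", "i0", "i0", "i1", "i3", "i3"],
        "dam": ["0", "0", "0", "i1", "i2", "i2", "i4", "i5"],
        "cohort": ["x"] * n,
    })
    from roegen.containers import Pedigree

    A = pedigree_relationship_matrix(Pedigree(df)).A
    return A, [f"i{k}" for k in range(n)], rng


class TestSolveMme:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_trait_matches_dense_gls(self, toy_system, seed):
        A, ids, _ = toy_system
        rng = np.random.default_rng(seed)
        n = len(ids)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        vg, ve = 1.3, 0.8
        fit = solve_mme(y[:, None], [X], ids, (A, ids), [[vg]], [[ve]])
        beta, U = dense_gls_oracle(y[:, None], [X], A, np.array([[vg]]), np.array([[ve]]))
        assert np.allclose(fit.beta[0], beta, atol=1e-8)
        assert np.allclose(fit.u[:, 0], U[:, 0], atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_two_traits_with_missing_match_dense_gls(self, toy_system, seed):
        A, ids, _ = toy_system
        rng = np.random.default_rng(seed)
        n = len(ids)
        Y = rng.normal(size=(n, 2))
        Y[rng.random((n, 2)) < 0.3] = np.nan
        Y[0, 0] = 0.5  # keep at least one record per trait
        Y[1, 1] = -0.2
        Xs = [np.ones((n, 1)), np.column_stack([np.ones(n), rng.normal(size=n)])]
        Vg = np.array([[1.0, 0.3], [0.3, 0.6]])
        Ve = np.array([[0.9, -0.1], [-0.1, 1.1]])
        fit = solve_mme(Y, Xs, ids, (A, ids), Vg, Ve)
        beta, U = dense_gls_oracle(Y, Xs, A, Vg, Ve)
        assert np.allclose(np.concatenate(fit.beta), beta, atol=1e-8)
        assert np.allclose(fit.u, U, atol=1e-8)

    def test_vanishing_genetic_variance_recovers_ols(self, toy_system):
        A, ids, _ = toy_system
        rng = np.random.default_rng(9)
        n = len(ids)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = solve_mme(y[:, None], [X], ids, (A, ids), [[1e-10]], [[1.0]])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta[0], ols, atol=1e-6)
        assert np.abs(fit.u).max() < 1e-6

    def test_exact_fixed_fit_gives_zero_ebv(self, toy_system):
        A, ids, _ = toy_system
        n = len(ids)
        X = np.ones((n, 1))
        y = 3.0 * X[:, 0]
        fit = solve_mme(y[:, None], [X], ids, (A, ids), [[0.5]], [[0.5]])
        assert np.abs(fit.u).max() < 1e-10
        assert fit.beta[0][0] == pytest.approx(3.0)

    def test_shift_invariance_up_to_intercept(self, toy_system):
        A, ids, _ = toy_system
        rng = np.random.default_rng(2)
        n = len(ids)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        f1 = solve_mme(y[:, None], [X], ids, (A, ids), [[1.0]], [[1.0]])
        f2 = solve_mme((y + 10)[:, None], [X], ids, (A, ids), [[1.0]], [[1.0]])
        assert np.allclose(f1.u, f2.u, atol=1e-9)
        assert f2.beta[0][0] - f1.beta[0][0] == pytest.approx(10.0)


class TestBuildDesign:
    def test_nested_covariate_layout(self):
        df = pd.DataFrame({
            "cohort": ["C1", "C1", "C1", "C2", "C2", "C2"],
            "overmature": [0, 1, 0, 0, 1, 1],
            "spawning_week": [1.0, 2.0, 4.0, 3.0, 4.0, 1.0],
        })
        X, names = build_design(df, default_design_for("SW"))
        assert names == ["intercept", "cohort[C2]", "overmature",
                         "spawning_week@cohort[C1]", "spawning_week@cohort[C2]"]
        assert X.shape == (6, 5)

    def test_confounded_effect_named(self):
        df = pd.DataFrame({"cohort": ["C1", "C2"], "dup": ["C1", "C2"]})
        with pytest.raises(ModelError, match="confounded"):
            build_design(df, DesignSpec(factors=["cohort", "dup"]))


class TestReml:
    def test_optimum_matches_likelihood_grid(self):
        # small-pedigree toy: compare against a dense restricted-likelihood grid
        rng = np.random.default_rng(12)
        ped = simulate_pedigree(
            MatingDesign([2], [2], ["C1"], offspring_per_cross=2,
                         n_grandsires=0, n_granddams=0), seed=0)
        A = pedigree_relationship_matrix(ped).A
        n = len(ped)
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        y = 2.0 + L @ rng.normal(size=n) * 0.8 + rng.normal(size=n) * 0.6
        X = np.ones((n, 1))
        vc = reml_estimate(y[:, None], [X], K=A, tol=1e-8, n_em=2)
        grid = np.linspace(0.05, 3.0, 60)
        vals = np.array([[restricted_m2ll_oracle(y, X, A, vg, ve) for ve in grid] for vg in grid])
        gi, gj = np.unravel_index(vals.argmin(), vals.shape)
        step = grid[1] - grid[0]
        assert abs(vc.Vg[0, 0] - grid[gi]) <= step
        assert abs(vc.Ve[0, 0] - grid[gj]) <= step

    def test_null_heritability_estimated_near_zero(self):
        design = MatingDesign.default(total_offspring=800)
        ped = simulate_pedigree(design, seed=3)
        kin = pedigree_relationship_matrix(ped)
        rng = np.random.default_rng(4)
        off = ~ped.is_founder() & ~ped.df["cohort"].eq("P").to_numpy()
        ids = list(ped.df["id"][off])
        rows = kin.index(ids)
        K = kin.A[np.ix_(rows, rows)]
        y = rng.normal(size=len(ids))
        vc = reml_estimate(y[:, None], [np.ones((len(ids), 1))], K=K, tol=1e-6)
        assert vc.h2[0] < 0.05

    def test_likelihood_never_increases_across_iterations(self, complete_study):
        phe = complete_study.phenotypes
        kin = pedigree_relationship_matrix(complete_study.pedigree)
        rows = kin.index(list(phe["id"]))
        K = kin.A[np.ix_(rows, rows)]
        X, _ = build_design(phe, default_design_for("SW"))
        vc = reml_estimate(phe["SW"].to_numpy()[:, None], [X], K=K, tol=1e-6)
        assert vc.converged
        diffs = np.diff(vc.trajectory)
        assert np.all(diffs <= 1e-6)

    def test_single_trait_recovery(self, complete_study):
        # h2(ED) = 0.44 in the generating model; expect recovery within ~3 SE
        phe = complete_study.phenotypes
        kin = pedigree_relationship_matrix(complete_study.pedigree)
        rows = kin.index(list(phe["id"]))
        K = kin.A[np.ix_(rows, rows)]
        X, _ = build_design(phe, default_design_for("ED"))
        vc = reml_estimate(phe["ED"].to_numpy()[:, None], [X], K=K, tol=1e-6)
        assert vc.h2[0] == pytest.approx(0.44, abs=3 * max(vc.h2_se[0], 0.05))

    def test_near_duplicate_traits_have_unit_genetic_correlation(self, complete_study):
        phe = complete_study.phenotypes.copy()
        rng = np.random.default_rng(0)
        kin = pedigree_relationship_matrix(complete_study.pedigree)
        rows = kin.index(list(phe["id"]))
        K = kin.A[np.ix_(rows, rows)]
        y = phe["ED"].to_numpy()
        y2 = y + rng.normal(0, 0.02 * y.std(), len(y))
        X = np.ones((len(y), 1))
        vc = reml_estimate(np.column_stack([y, y2]), [X, X], K=K, tol=1e-6)
        assert vc.rg[0, 1] > 0.98


class TestParameterTable:
    def test_full_table_recovers_generating_values(self, large_study):
        phe = large_study.phenotypes
        kin = pedigree_relationship_matrix(large_study.pedigree)
        params = estimate_parameter_table(
            phe, kin, reml_kwargs={"tol": 1e-5, "max_iter": 60}
        )
        assert set(params.traits) == {"SD", "FW", "PW", "SW", "EN", "EW", "ED"}
        # generating h2 values recovered within ~3 standard errors
        truth = {"SD": 0.27, "FW": 0.30, "PW": 0.33, "SW": 0.32,
                 "EN": 0.24, "EW": 0.27, "ED": 0.44}
        for tr, h in truth.items():
            slack = max(3.0 * params.h2_se[tr], 0.10)
            assert params.h2[tr] == pytest.approx(h, abs=slack), tr
        assert params.rg.loc["SW", "EN"] > 0.6
        assert params.rg.loc["EW", "ED"] > 0.9
        assert all(params.converged.values())
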