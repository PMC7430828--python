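"""Animal-model machinery: fixed-effect designs, Henderson's mixed-model
equations, AI-REML variance components, and the multi-trait parameter table.

The animal model per trait i is y_i = X_i b_i + Z_i u_i + e_i with
cov(u) = K (x) Vg over traits (K = A or G) and trait-structured residuals.
REML maximizes the restricted likelihood with a few EM steps for stability
followed by average-information (AI) updates with step halving, working in
the eigenbasis of K so each iteration costs O(n t^3) instead of a dense
solve of the full coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenomicKinship, PedigreeKinship


class ModelError(ValueError):
    pass


class RemlError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory or []


# ---------------------------------------------------------------------------
# fixed-effect designs


@dataclass
class DesignSpec:
    """Fixed-effect layout for one trait: an intercept, categorical factors
    (first level dropped), 0/1 indicator columns, plain covariates, and
    covariates nested within a factor (one slope per factor level)."""

    factors: list[str] = field(default_factory=list)
    binaries: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    nested_covariates: dict[str, str] = field(default_factory=dict)  # covariate -> factor


def default_design_for(trait: str, adjust_weight: bool = False) -> DesignSpec:
    """The study's per-trait fixed-effect layout.

    Cohort is the main factor for every trait; the overmature-egg flag enters
    for FW, SW, EN and ED; the spawning week is a covariate nested within
    cohort for all traits except SD (week *is* the SD measure). With
    ``adjust_weight`` the female body weight FW enters as a within-cohort
    covariate (the SW*/EN* adjustment).
    """
    spec = DesignSpec(factors=["cohort"])
    if trait in ("FW", "SW", "EN", "ED"):
        spec.binaries.append("overmature")
    if trait != "SD":
        spec.nested_covariates["spawning_week"] = "cohort"
    if adjust_weight and trait in ("SW", "EN"):
        spec.nested_covariates["FW"] = "cohort"
    return spec


def build_design(df: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix; raises naming the confounded column if rank
    deficient."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in spec.factors:
        levels = sorted(df[f].astype(str).unique())
        for lv in levels[1:]:  # drop first level
            cols.append((df[f].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{f}[{lv}]")
    for b in spec.binaries:
        cols.append(df[b].to_numpy(dtype=float))
        names.append(b)
    for c in spec.covariates:
        x = df[c].to_numpy(dtype=float)
        cols.append(x - np.nanmean(x))
        names.append(c)
    for cov, f in spec.nested_covariates.items():
        x = df[cov].to_numpy(dtype=float)
        x = x - np.nanmean(x)
        for lv in sorted(df[f].astype(str).unique()):
            cols.append(np.where(df[f].astype(str) == lv, x, 0.0))
            names.append(f"{cov}@{f}[{lv}]")
    X = np.column_stack(cols)
    # rank check (pivoted QR) with a name for the offending column
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-8 * max(1.0, diag.max())).sum())
    if rank < X.shape[1]:
        raise ModelError(f"confounded fixed effect: {names[int(piv[rank])]}")
    return X, names


@dataclass
class ModelSpec:
    """Which traits are modelled jointly, their designs, and the kinship used."""

    traits: list[str]
    kinship: str = "A"  # "A" | "G"
    adjust_weight: bool = False
    designs: dict[str, DesignSpec] | None = None

    def design_for(self, trait: str) -> DesignSpec:
        if self.designs and trait in self.designs:
            return self.designs[trait]
        return default_design_for(trait, adjust_weight=self.adjust_weight)


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations


@dataclass
class MixedModelFit:
    traits: list[str]
    ids: list[str]  # kinship ids (all animals carrying breeding values)
    beta: list[np.ndarray]
    beta_names: list[list[str]]
    u: np.ndarray  # (N, t) (G)EBVs
    Vg: np.ndarray
    Ve: np.ndarray
    kinship_kind: str = "A"
    pev: np.ndarray | None = None  # (N, N) prediction-error covariance, single trait

    def ebv(self, trait: str) -> pd.Series:
        return pd.Series(self.u[:, self.traits.index(trait)], index=self.ids)


def _kinship_parts(kinship) -> tuple[np.ndarray, list[str], str]:
    if isinstance(kinship, PedigreeKinship):
        return kinship.A, kinship.ids, "A"
    if isinstance(kinship, GenomicKinship):
        return kinship.G, kinship.ids, "G"
    K, ids = kinship
    return np.asarray(K), list(ids), "K"


def solve_mme(
    Y: np.ndarray,
    Xs: list[np.ndarray],
    record_ids: list[str],
    kinship,
    Vg: np.ndarray,
    Ve: np.ndarray,
    traits: list[str] | None = None,
    beta_names: list[list[str]] | None = None,
    compute_pev: bool = False,
) -> MixedModelFit:
    """Solve Henderson's equations for a (multi-trait) animal model.

    Y is (n_records, t) with NaN for trait-wise missing records; Xs holds one
    design matrix per trait (rows aligned with Y). Missing patterns are
    handled through trait-specific residual partitions: each record
    contributes Ve[observed, observed]^-1. ``compute_pev`` (single trait only)
    returns the prediction-error covariance of u from the inverted
    coefficient matrix.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, t = Y.shape
    Vg = np.atleast_2d(np.asarray(Vg, dtype=float))
    Ve = np.atleast_2d(np.asarray(Ve, dtype=float))
    K, kin_ids, kind = _kinship_parts(kinship)
    N = len(kin_ids)
    pos = {s: k for k, s in enumerate(kin_ids)}
    try:
        arow = np.array([pos[i] for i in record_ids])
    except KeyError as e:
        raise ModelError(f"record animal {e} missing from the kinship") from e
    ps = [X.shape[1] for X in Xs]
    off = np.concatenate([[0], np.cumsum(ps)])
    P = int(off[-1])

    obs = ~np.isnan(Y)
    Kinv = np.linalg.inv(K)
    Vginv = np.linalg.inv(Vg)

    XtRX = np.zeros((P, P))
    XtRZ = np.zeros((P, N * t))
    ZtRZ = np.zeros((N * t, N * t))
    rX = np.zeros(P)
    rZ = np.zeros(N * t)

    patterns = {}
    for i in range(n):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    for patt, rows in patterns.items():
        s = [k for k, o in enumerate(patt) if o]
        if not s:
            continue
        W = np.linalg.inv(Ve[np.ix_(s, s)])
        rows = np.array(rows)
        ar = arow[rows]
        for ia, t1 in enumerate(s):
            X1 = Xs[t1][rows]
            y1 = Y[rows, t1]
            for ib, t2 in enumerate(s):
                w = W[ia, ib]
                X2 = Xs[t2][rows]
                XtRX[off[t1]:off[t1 + 1], off[t2]:off[t2 + 1]] += w * X1.T @ X2
                # X' R^-1 Z and Z' R^-1 Z accumulate per animal column
                acc = np.zeros((N, ps[t1]))
                np.add.at(acc, ar, w * X1)
                XtRZ[off[t1]:off[t1 + 1], t2 * N:(t2 + 1) * N] += acc.T
                np.add.at(ZtRZ, (t1 * N + ar, t2 * N + ar), w)
                rX[off[t1]:off[t1 + 1]] += w * X1.T @ Y[rows, t2]
            rZ[t1 * N + ar] += (W[ia] * Y[np.ix_(rows, s)]).sum(axis=1)
    ZtRZ += np.kron(Vginv, Kinv)

    LHS = np.block([[XtRX, XtRZ], [XtRZ.T, ZtRZ]])
    rhs = np.concatenate([rX, rZ])
    try:
        if compute_pev:
            Cinv = np.linalg.inv(LHS)
            sol = Cinv @ rhs
        else:
            sol = np.linalg.solve(LHS, rhs)
    except np.linalg.LinAlgError as e:
        raise ModelError(f"singular mixed-model equations (check fixed effects): {e}") from e
    beta = [sol[off[k]:off[k + 1]] for k in range(t)]
    u = sol[P:].reshape(t, N).T
    pev = None
    if compute_pev:
        if t != 1:
            raise ModelError("PEV extraction supported for single-trait fits only")
        pev = Cinv[P:, P:]
    return MixedModelFit(
        traits=traits or [f"trait{k + 1}" for k in range(t)],
        ids=kin_ids,
        beta=beta,
        beta_names=beta_names or [[f"b{j}" for j in range(p)] for p in ps],
        u=u,
        Vg=Vg,
        Ve=Ve,
        kinship_kind=kind,
        pev=pev,
    )


# ---------------------------------------------------------------------------
# AI-REML


@dataclass
class VarianceComponents:
    traits: list[str]
    Vg: np.ndarray
    Ve: np.ndarray
    h2: np.ndarray
    h2_se: np.ndarray
    rg: np.ndarray  # genetic correlation matrix
    rg_se: np.ndarray
    converged: bool
    boundary: bool
    n_iter: int
    minus2_loglik: float
    cov_params: np.ndarray | None = None
    param_index: list[tuple[str, int, int]] | None = None
    trajectory: list[float] = field(default_factory=list)

    @property
    def rp(self) -> np.ndarray:
        Vp = self.Vg + self.Ve
        s = np.sqrt(np.diag(Vp))
        return Vp / np.outer(s, s)


def _psd_ok(m: np.ndarray) -> bool:
    """Feasibility check keeping Vg and Ve inside the PSD cone (so genetic
    correlations stay within [-1, 1] even when the summed V is well behaved)."""
    w = np.linalg.eigvalsh(0.5 * (m + m.T))
    return bool(w.min() >= -1e-9 * max(np.trace(m), 1.0))


def _param_list(t: int) -> list[tuple[str, int, int]]:
    out = []
    for kind in ("g", "e"):
        for a in range(t):
            for b in range(a, t):
                out.append((kind, a, b))
    return out


def _unpack(theta: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    Vg = np.zeros((t, t))
    Ve = np.zeros((t, t))
    for val, (kind, a, b) in zip(theta, _param_list(t)):
        m = Vg if kind == "g" else Ve
        m[a, b] = m[b, a] = val
    return Vg, Ve


def _pack(Vg: np.ndarray, Ve: np.ndarray) -> np.ndarray:
    t = Vg.shape[0]
    return np.array(
        [(Vg if k == "g" else Ve)[a, b] for (k, a, b) in _param_list(t)]
    )


class _RotatedReml:
    """REML working quantities in the eigenbasis of K (rows independent)."""

    def __init__(self, Y, Xs, w, U):
        self.d = np.clip(w, 0.0, None)
        self.Y = U.T @ Y
        self.Xs = [U.T @ X for X in Xs]
        self.n, self.t = Y.shape
        self.ps = [X.shape[1] for X in self.Xs]
        self.off = np.concatenate([[0], np.cumsum(self.ps)])
        self.P = int(self.off[-1])

    def _blocks(self, Wk):
        """Assemble sum_i B_i' Wk_i B_i where Wk is (n, t, t) and B_i is the
        block-diagonal per-row design."""
        C = np.zeros((self.P, self.P))
        for t1 in range(self.t):
            X1 = self.Xs[t1]
            for t2 in range(self.t):
                C[self.off[t1]:self.off[t1 + 1], self.off[t2]:self.off[t2 + 1]] = (
                    X1.T @ (Wk[:, t1, t2][:, None] * self.Xs[t2])
                )
        return C

    def _xt_v(self, Wk, F):
        """(X' Wk F) stacked over trait blocks, F is (n, t)."""
        out = np.zeros(self.P)
        G = np.einsum("ntk,nk->nt", Wk, F)
        for t1 in range(self.t):
            out[self.off[t1]:self.off[t1 + 1]] = self.Xs[t1].T @ G[:, t1]
        return out

    def loglik_parts(self, Vg, Ve):
        Vi = self.d[:, None, None] * Vg[None] + Ve[None]
        try:
            L = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.einsum("nii->ni", L)))
        Vinv = np.linalg.inv(Vi)
        C = self._blocks(Vinv)
        rhs = self._xt_v(Vinv, self.Y)
        try:
            Lc = np.linalg.cholesky(0.5 * (C + C.T))
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(C, rhs)
        logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
        R = self.Y.copy()
        for t1 in range(self.t):
            R[:, t1] -= self.Xs[t1] @ beta[self.off[t1]:self.off[t1 + 1]]
        PY = np.einsum("ntk,nk->nt", Vinv, R)
        m2ll = logdetV + logdetC + float(np.sum(R * PY))
        return {"Vinv": Vinv, "C": C, "Cinv": np.linalg.inv(C), "beta": beta,
                "R": R, "PY": PY, "m2ll": m2ll}

    def _dV_times(self, kind, a, b, F):
        """(dV_theta F) for derivative matrix c_i * E_ab, F (n, t)."""
        c = self.d if kind == "g" else np.ones(self.n)
        out = np.zeros_like(F)
        out[:, a] += c * F[:, b]
        if a != b:
            out[:, b] += c * F[:, a]
        return out

    def score_and_ai(self, parts):
        Vinv, Cinv, PY = parts["Vinv"], parts["Cinv"], parts["PY"]
        params = _param_list(self.t)
        npar = len(params)
        score = np.zeros(npar)
        fs = []
        for k, (kind, a, b) in enumerate(params):
            c = self.d if kind == "g" else np.ones(self.n)
            mult = 1.0 if a == b else 2.0
            trV = mult * float(np.sum(c * Vinv[:, a, b]))
            # correction: tr(Cinv * X' Vinv dV Vinv X)
            A1 = Vinv[:, :, a] * c[:, None]
            Wk = A1[:, :, None] * Vinv[:, b, :][:, None, :]
            if a != b:
                A2 = Vinv[:, :, b] * c[:, None]
                Wk = Wk + A2[:, :, None] * Vinv[:, a, :][:, None, :]
            Q = self._blocks(Wk)
            tr_corr = float(np.sum(Cinv * Q.T))
            f = self._dV_times(kind, a, b, PY)
            quad = float(np.sum(PY * f))
            score[k] = -0.5 * ((trV - tr_corr) - quad)
            fs.append(f)
        # AI matrix: 0.5 * f_k' P f_l
        Pf = []
        for f in fs:
            g1 = np.einsum("ntk,nk->nt", Vinv, f)
            h = np.zeros(self.P)
            for t1 in range(self.t):
                h[self.off[t1]:self.off[t1 + 1]] = self.Xs[t1].T @ g1[:, t1]
            delta = Cinv @ h
            xd = np.zeros_like(f)
            for t1 in range(self.t):
                xd[:, t1] = self.Xs[t1] @ delta[self.off[t1]:self.off[t1 + 1]]
            Pf.append(g1 - np.einsum("ntk,nk->nt", Vinv, xd))
        AI = np.zeros((npar, npar))
        for k in range(npar):
            for l in range(k, npar):
                AI[k, l] = AI[l, k] = 0.5 * float(np.sum(fs[k] * Pf[l]))
        return score, AI

    def em_update(self, Vg, Ve, parts):
        Vinv, R = parts["Vinv"], parts["R"]
        d = self.d
        VinvR = np.einsum("ntk,nk->nt", Vinv, R)
        # E[u u']/d and E[e e'] averaged over rows (beta treated as known)
        uh = d[:, None] * VinvR  # Vg^-1-free representation: u_hat = d * Vg @ VinvR
        Vg_new = Vg @ (np.einsum("nt,nk->tk", uh, VinvR) / self.n) @ Vg
        Vg_new += Vg - Vg @ (np.einsum("n,ntk->tk", d, Vinv) / self.n) @ Vg
        eh = VinvR
        Ve_new = Ve @ (np.einsum("nt,nk->tk", eh, VinvR) / self.n) @ Ve
        Ve_new += Ve - Ve @ (Vinv.mean(axis=0)) @ Ve
        return 0.5 * (Vg_new + Vg_new.T), 0.5 * (Ve_new + Ve_new.T)


def reml_estimate(
    Y: np.ndarray,
    Xs: list[np.ndarray],
    K: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    traits: list[str] | None = None,
    start: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em: int = 3,
) -> VarianceComponents:
    """AI-REML estimation of (Vg, Ve) for a complete-record animal model.

    Y is (n, t) with one record row per animal carrying records; K is the
    kinship among exactly those animals (or pass its eigendecomposition
    ``eig=(w, U)`` to share it across model fits). Rows with any missing trait
    are dropped (complete-case REML). Traits are standardized internally for
    numerical balance; components are returned on the observed scale.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, t = Y.shape
    keep = ~np.isnan(Y).any(axis=1)
    if not keep.all():
        Y = Y[keep]
        Xs = [X[keep] for X in Xs]
        if eig is not None:
            raise ModelError("cannot drop rows from a precomputed eigendecomposition")
        K = K[np.ix_(keep, keep)]
        n = Y.shape[0]
    if n <= max(X.shape[1] for X in Xs):
        raise ModelError("more fixed effects than records")
    if eig is None:
        w, U = np.linalg.eigh(np.asarray(K, dtype=float))
    else:
        w, U = eig
    sds = Y.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    Ys = (Y - Y.mean(axis=0)) / sds
    core = _RotatedReml(Ys, Xs, w, U)

    if start is None:
        Vg = 0.5 * np.eye(t)
        Ve = 0.5 * np.eye(t)
    else:
        S = np.outer(sds, sds)
        Vg = np.asarray(start[0], dtype=float) / S
        Ve = np.asarray(start[1], dtype=float) / S

    parts = core.loglik_parts(Vg, Ve)
    if parts is None:
        raise RemlError("starting values give a non-positive-definite model")
    traj = [parts["m2ll"]]
    boundary = False
    floor = 1e-6

    for _ in range(n_em):
        Vg_c, Ve_c = core.em_update(Vg, Ve, parts)
        Vg_c[np.diag_indices(t)] = np.maximum(np.diag(Vg_c), floor)
        Ve_c[np.diag_indices(t)] = np.maximum(np.diag(Ve_c), floor)
        if not (_psd_ok(Vg_c) and _psd_ok(Ve_c)):
            continue
        new = core.loglik_parts(Vg_c, Ve_c)
        if new is not None and new["m2ll"] <= parts["m2ll"] + 1e-9:
            Vg, Ve = Vg_c, Ve_c
            parts = new
            traj.append(parts["m2ll"])

    converged = False
    n_iter = n_em
    theta = _pack(Vg, Ve)
    score = AI = None
    n_stationary = 0
    for it in range(max_iter):
        n_iter = n_em + it + 1
        score, AI = core.score_and_ai(parts)
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(len(score)), score)
        except np.linalg.LinAlgError:
            step = score / max(1.0, np.abs(score).max())
        accepted = False
        for _ in range(30):
            cand = theta + step
            Vg_c, Ve_c = _unpack(cand, t)
            Vg_c[np.diag_indices(t)] = np.maximum(np.diag(Vg_c), floor)
            Ve_c[np.diag_indices(t)] = np.maximum(np.diag(Ve_c), floor)
            if _psd_ok(Vg_c) and _psd_ok(Ve_c):
                new = core.loglik_parts(Vg_c, Ve_c)
                if new is not None and new["m2ll"] <= parts["m2ll"] + 1e-9:
                    accepted = True
                    break
            step = 0.5 * step
        if not accepted:
            # at the boundary of the parameter space or numerically stuck
            boundary = boundary or bool(
                (np.diag(Vg) <= floor * 1.01).any() or (np.diag(Ve) <= floor * 1.01).any()
            )
            converged = True
            break
        rel = np.max(np.abs(_pack(Vg_c, Ve_c) - theta) / np.maximum(np.abs(theta), 1e-4))
        dll = parts["m2ll"] - new["m2ll"]
        theta = _pack(Vg_c, Ve_c)
        Vg, Ve = Vg_c, Ve_c
        parts = new
        traj.append(parts["m2ll"])
        if rel < tol:
            converged = True
            break
        # AI can converge only linearly along near-flat ridges of a multi-trait
        # surface; a stationary restricted likelihood is an equivalent optimum
        n_stationary = n_stationary + 1 if dll < 1e-6 else 0
        if n_stationary >= 3:
            converged = True
            break
    if not converged:
        # AI updates can crawl along a near-flat ridge; polish with exact-gradient
        # quasi-Newton from the current point before giving up
        from scipy.optimize import minimize

        def fg(th):
            Vg_t, Ve_t = _unpack(th, t)
            if not (_psd_ok(Vg_t) and _psd_ok(Ve_t)):
                return 1e12, np.zeros_like(th)
            p = core.loglik_parts(Vg_t, Ve_t)
            if p is None:
                return 1e12, np.zeros_like(th)
            s, _ = core.score_and_ai(p)
            return p["m2ll"], -2.0 * s

        res = minimize(fg, theta, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-7})
        new = core.loglik_parts(*_unpack(res.x, t))
        if new is not None and new["m2ll"] <= parts["m2ll"] + 1e-6:
            Vg, Ve = _unpack(res.x, t)
            parts = new
            traj.append(parts["m2ll"])
            converged = True
        else:
            raise RemlError(
                f"REML did not converge in {max_iter} AI iterations", trajectory=traj
            )
    boundary = boundary or bool(
        (np.diag(Vg) <= floor * 1.01).any() or (np.diag(Ve) <= floor * 1.01).any()
    )

    score, AI = core.score_and_ai(parts)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full_like(AI, np.nan)

    # back to the observed scale
    S = np.outer(sds, sds)
    Vg_out, Ve_out = Vg * S, Ve * S
    params = _param_list(t)
    scale_vec = np.array([S[a, b] for (_, a, b) in params])
    cov_out = cov * np.outer(scale_vec, scale_vec)

    h2, h2_se, rg, rg_se = _derived_parameters(Vg_out, Ve_out, cov_out, params)
    return VarianceComponents(
        traits=traits or [f"trait{k + 1}" for k in range(t)],
        Vg=Vg_out,
        Ve=Ve_out,
        h2=h2,
        h2_se=h2_se,
        rg=rg,
        rg_se=rg_se,
        converged=converged,
        boundary=boundary,
        n_iter=n_iter,
        minus2_loglik=float(parts["m2ll"]),
        cov_params=cov_out,
        param_index=params,
        trajectory=traj,
    )


def _derived_parameters(Vg, Ve, cov, params):
    """Delta-method SEs for heritabilities and genetic correlations."""
    t = Vg.shape[0]
    pidx = {pk: k for k, pk in enumerate(params)}
    h2 = np.diag(Vg) / (np.diag(Vg) + np.diag(Ve))
    sg = np.sqrt(np.diag(Vg))
    rg = np.clip(Vg / np.outer(sg, sg), -1.0, 1.0)
    h2_se = np.full(t, np.nan)
    rg_se = np.full((t, t), np.nan)
    ok = np.all(np.isfinite(cov))
    for a in range(t):
        if not ok:
            break
        grad = np.zeros(len(params))
        vg, ve = Vg[a, a], Ve[a, a]
        vp = vg + ve
        grad[pidx[("g", a, a)]] = ve / vp**2
        grad[pidx[("e", a, a)]] = -vg / vp**2
        h2_se[a] = np.sqrt(max(grad @ cov @ grad, 0.0))
    for a in range(t):
        for b in range(a + 1, t):
            if not ok:
                break
            grad = np.zeros(len(params))
            va, vb, vab = Vg[a, a], Vg[b, b], Vg[a, b]
            grad[pidx[("g", a, b)]] = 1.0 / np.sqrt(va * vb)
            grad[pidx[("g", a, a)]] = -0.5 * vab / (va**1.5 * np.sqrt(vb))
            grad[pidx[("g", b, b)]] = -0.5 * vab / (vb**1.5 * np.sqrt(va))
            rg_se[a, b] = rg_se[b, a] = np.sqrt(max(grad @ cov @ grad, 0.0))
    return h2, h2_se, rg, rg_se


# ---------------------------------------------------------------------------
# the multi-trait parameter table


TRAIT_COMBOS = [
    ["BW", "SD", "EW", "SW"],
    ["BW", "SD", "EW", "EN"],
    ["BW", "SD", "ED", "EN"],
    ["BW", "SD", "ED", "SW"],
]
BIVARIATE_PAIRS = [("FW", "PW"), ("SW", "EN"), ("EW", "ED")]


@dataclass
class GeneticParameters:
    traits: list[str]
    h2: pd.Series
    h2_se: pd.Series
    rg: pd.DataFrame
    rp: pd.DataFrame
    provenance: dict
    converged: dict


def estimate_parameter_table(
    pheno: pd.DataFrame,
    kinship,
    body_weight: str = "FW",
    reml_kwargs: dict | None = None,
    include_bivariate: bool = True,
) -> GeneticParameters:
    """Run the four 4-trait models (plus dedicated bivariate models for the
    near-unity pairs) and average every parameter over the models containing it.
    """
    reml_kwargs = dict(reml_kwargs or {})
    K, kin_ids, _ = _kinship_parts(kinship)
    combos = [[body_weight if tr == "BW" else tr for tr in combo] for combo in TRAIT_COMBOS]
    if include_bivariate:
        combos += [list(p) for p in BIVARIATE_PAIRS]
    h2_acc: dict[str, list] = {}
    h2se_acc: dict[str, list] = {}
    rg_acc: dict[tuple, list] = {}
    rp_acc: dict[tuple, list] = {}
    converged = {}
    eig_cache: dict[tuple, tuple] = {}
    for combo in combos:
        cols = set(combo) | {"cohort", "overmature", "spawning_week"}
        sub = pheno.dropna(subset=[c for c in cols if c in pheno.columns])
        sub = sub[sub["id"].isin(set(kin_ids))]
        ids = list(sub["id"])
        key = tuple(ids)
        if key not in eig_cache:
            pos = {s: k for k, s in enumerate(kin_ids)}
            rows = np.array([pos[i] for i in ids])
            eig_cache[key] = tuple(np.linalg.eigh(K[np.ix_(rows, rows)]))
        Y = sub[combo].to_numpy(dtype=float)
        Xs = [build_design(sub, default_design_for(tr))[0] for tr in combo]
        name = "+".join(combo)
        try:
            vc = reml_estimate(Y, Xs, eig=eig_cache[key], traits=combo, **reml_kwargs)
            converged[name] = vc.converged
        except RemlError:
            converged[name] = False
            continue
        rp = vc.rp
        for a, tr in enumerate(combo):
            h2_acc.setdefault(tr, []).append(vc.h2[a])
            h2se_acc.setdefault(tr, []).append(vc.h2_se[a])
            for b in range(a + 1, len(combo)):
                pair = tuple(sorted((tr, combo[b])))
                rg_acc.setdefault(pair, []).append(vc.rg[a, b])
                rp_acc.setdefault(pair, []).append(rp[a, b])
    # near-unity pairs are reported from their dedicated bivariate models only
    for pair in BIVARIATE_PAIRS:
        key = tuple(sorted(pair))
        name = "+".join(pair)
        if include_bivariate and name in converged and converged[name] and key in rg_acc:
            rg_acc[key] = rg_acc[key][-1:]
            rp_acc[key] = rp_acc[key][-1:]
    traits = sorted(h2_acc, key=lambda tr: (TRAIT_ORDER.index(tr) if tr in TRAIT_ORDER else 99))
    h2 = pd.Series({tr: float(np.mean(v)) for tr, v in h2_acc.items()})[traits]
    h2_se = pd.Series({tr: float(np.mean(v)) for tr, v in h2se_acc.items()})[traits]
    # unestimated pairs stay NaN (e.g. PW with egg traits under the FW set)
    shell = np.full((len(traits), len(traits)), np.nan)
    np.fill_diagonal(shell, 1.0)
    rg = pd.DataFrame(shell.copy(), index=traits, columns=traits)
    rp = pd.DataFrame(shell.copy(), index=traits, columns=traits)
    for (a, b), vals in rg_acc.items():
        if a in traits and b in traits:
            rg.loc[a, b] = rg.loc[b, a] = float(np.mean(vals))
    for (a, b), vals in rp_acc.items():
        if a in traits and b in traits:
            rp.loc[a, b] = rp.loc[b, a] = float(np.mean(vals))
    return GeneticParameters(
        traits=traits,
        h2=h2,
        h2_se=h2_se,
        rg=rg,
        rp=rp,
        provenance={"combos": ["+".join(c) for c in combos]},
        converged=converged,
    )


TRAIT_ORDER = ["SD", "FW", "PW", "SW", "EN", "EW", "ED"]
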