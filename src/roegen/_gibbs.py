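"""Numba kernel for the BayesC-pi Gibbs sampler.

One compiled loop samples, per cycle: fixed effects (flat prior), each SNP's
inclusion indicator and effect (spike-and-slab with a common slab variance),
the slab variance and residual variance (scaled inverse chi-square), and pi
from its Beta posterior. The residual vector is updated in place so each SNP
visit costs O(n).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def bayesc_gibbs(
    Xf,  # (n, p) fixed-effect design, float64
    M,  # (n, m) centered dosages, float64, Fortran order preferred
    y,  # (n,)
    cycles,
    burn_in,
    thin,
    pi_a,
    pi_b,
    nu_a,
    s2_a,
    nu_e,
    s2_e,
    seed,
):
    np.random.seed(seed)
    n, p = Xf.shape
    m = M.shape[1]
    xf_ss = np.empty(p)
    for k in range(p):
        xf_ss[k] = np.dot(Xf[:, k], Xf[:, k])
    c = np.empty(m)
    for j in range(m):
        c[j] = np.dot(M[:, j], M[:, j])

    beta = np.zeros(p)
    a = np.zeros(m)
    incl = np.zeros(m, dtype=np.bool_)
    sigma_a2 = s2_a
    sigma_e2 = s2_e
    pi = pi_a / (pi_a + pi_b)

    e = y.copy()
    n_save = (cycles - burn_in) // thin
    s_a = np.zeros((n_save, m), dtype=np.float32)
    s_beta = np.zeros((n_save, p))
    s_sa2 = np.zeros(n_save)
    s_se2 = np.zeros(n_save)
    s_pi = np.zeros(n_save)
    ok = True
    ksave = 0
    for cycle in range(cycles):
        # fixed effects, flat prior
        for k in range(p):
            if xf_ss[k] <= 0.0:
                continue
            rhs = np.dot(Xf[:, k], e) + xf_ss[k] * beta[k]
            mean = rhs / xf_ss[k]
            new = mean + np.random.normal() * np.sqrt(sigma_e2 / xf_ss[k])
            diff = new - beta[k]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= diff * Xf[i, k]
            beta[k] = new
        # SNP indicators and effects
        n_inc = 0
        ssq_a = 0.0
        for j in range(m):
            cj = c[j]
            if cj <= 0.0:
                incl[j] = False
                a[j] = 0.0
                continue
            rhs = np.dot(M[:, j], e)
            if incl[j]:
                rhs += cj * a[j]
            denom = cj * sigma_a2 + sigma_e2
            log_ratio = (
                np.log(pi / (1.0 - pi))
                + 0.5 * np.log(sigma_e2 / denom)
                + 0.5 * rhs * rhs * sigma_a2 / (sigma_e2 * denom)
            )
            if log_ratio > 35.0:
                p_inc = 1.0
            elif log_ratio < -35.0:
                p_inc = 0.0
            else:
                odds = np.exp(log_ratio)
                p_inc = odds / (1.0 + odds)
            old = a[j] if incl[j] else 0.0
            if np.random.random() < p_inc:
                lam = cj + sigma_e2 / sigma_a2
                mean = rhs / lam
                new = mean + np.random.normal() * np.sqrt(sigma_e2 / lam)
                incl[j] = True
                a[j] = new
                n_inc += 1
                ssq_a += new * new
            else:
                incl[j] = False
                a[j] = 0.0
                new = 0.0
            diff = new - old
            if diff != 0.0:
                for i in range(n):
                    e[i] -= diff * M[i, j]
        # slab variance (scaled inverse chi-square)
        sigma_a2 = (ssq_a + nu_a * s2_a) / np.random.chisquare(nu_a + n_inc)
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (sse + nu_e * s2_e) / np.random.chisquare(nu_e + n)
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0.0:
            ok = False
            break
        # pi from its Beta posterior
        pi = np.random.beta(pi_a + n_inc, pi_b + (m - n_inc))
        if pi <= 1e-12:
            pi = 1e-12
        elif pi >= 1.0 - 1e-12:
            pi = 1.0 - 1e-12
        if cycle >= burn_in and (cycle - burn_in) % thin == 0 and ksave < n_save:
            for j in range(m):
                s_a[ksave, j] = a[j]
            for k in range(p):
                s_beta[ksave, k] = beta[k]
            s_sa2[ksave] = sigma_a2
            s_se2[ksave] = sigma_e2
            s_pi[ksave] = pi
            ksave += 1
    return s_a, s_beta, s_sa2, s_se2, s_pi, ksave, ok
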