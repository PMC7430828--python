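"""Pedigree (A) and genomic (G) relationship matrices.

A is built with the tabular method (exact inbreeding through the recursion).
G follows VanRaden's first method, optionally with per-SNP weights d:
W = M - 2p, G = W diag(d) W' / (2 * sum_j d_j p_j (1 - p_j)), with a small
ridge added to the diagonal so G is invertible for mixed-model use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeSet, Pedigree


@dataclass
class PedigreeKinship:
    A: np.ndarray
    ids: list[str]

    def index(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.ids)}
        return np.array([pos[s] for s in ids], dtype=np.int64)

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0


@dataclass
class GenomicKinship:
    G: np.ndarray  # ridged
    ids: list[str]
    freqs: np.ndarray  # centering allele frequencies
    denom: float  # 2 * sum d_j p_j (1 - p_j)
    d: np.ndarray  # SNP weights
    ridge: float

    def index(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.ids)}
        return np.array([pos[s] for s in ids], dtype=np.int64)


def pedigree_relationship_matrix(pedigree: Pedigree) -> PedigreeKinship:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A_j,sire(i) + A_j,dam(i)),
    with unknown parents contributing zero. Requires an acyclic pedigree
    (validated by the Pedigree container).
    """
    df = pedigree.df
    n = len(df)
    order = pedigree.topological_order()
    idx = {iid: k for k, iid in enumerate(df["id"])}
    sire_row = np.array([idx.get(s, -1) for s in df["sire"]])
    dam_row = np.array([idx.get(d, -1) for d in df["dam"]])
    A = np.zeros((n, n))
    # process in topological order; fill full rows so lookups are unconditional
    for r in order:
        s, d = sire_row[r], dam_row[r]
        if s < 0 and d < 0:
            row = np.zeros(n)
        elif s < 0:
            row = 0.5 * A[d]
        elif d < 0:
            row = 0.5 * A[s]
        else:
            row = 0.5 * (A[s] + A[d])
        A[r, :] = row
        A[:, r] = row
        A[r, r] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return PedigreeKinship(A=A, ids=list(df["id"]))


def genomic_relationship_matrix(
    genotypes: GenotypeSet,
    d: np.ndarray | None = None,
    ridge: float = 1e-4,
    freqs: np.ndarray | None = None,
) -> GenomicKinship:
    """VanRaden method-1 genomic relationship matrix from complete dosages.

    Centering uses the observed allele frequencies unless ``freqs`` is given.
    With uniform weights this is the standard G; a weight vector d makes
    Z diag(d) Z' proportional to the weighted G used for SNP back-solving.
    """
    if genotypes.missing_mask().any():
        raise ValueError("G requires complete genotypes; run fill_missing_genotypes first")
    M = genotypes.dosages.astype(np.float64)
    m = genotypes.n_snps
    d = np.ones(m) if d is None else np.asarray(d, dtype=float)
    if d.shape != (m,) or np.any(d < 0):
        raise ValueError("d must be a nonnegative vector with one weight per SNP")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * float(np.sum(d * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic (zero VanRaden denominator)")
    W = M - 2.0 * p[None, :]
    G = (W * d[None, :]) @ W.T / denom
    G[np.diag_indices_from(G)] += ridge
    return GenomicKinship(G=G, ids=list(genotypes.samples), freqs=p, denom=denom, d=d, ridge=ridge)


def centered_dosages(genotypes: GenotypeSet, freqs: np.ndarray | None = None) -> np.ndarray:
    """Z = M - 2p, the centered dosage matrix used in G and in SNP back-solving."""
    M = genotypes.dosages.astype(np.float64)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    return M - 2.0 * p[None, :]
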