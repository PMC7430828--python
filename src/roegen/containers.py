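"""Core in-memory containers: pedigree, genotype matrix with map, QTL regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # missing dosage sentinel in integer genotype matrices

UNKNOWN_PARENT = "0"


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A pedigree as an id/sire/dam/cohort table.

    Parent code "0" marks an unknown parent. Founders are individuals with both
    parents unknown; an individual with exactly one known parent is legal here
    (it occurs in real broodstock data) but is rejected by the gene-dropping
    simulator, which needs both gametes.
    """

    df: pd.DataFrame  # columns: id, sire, dam, cohort (all str)

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "cohort"}
        if not required.issubset(self.df.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(required)}")
        self.df = self.df.astype({c: str for c in ["id", "sire", "dam", "cohort"]})
        if self.df["id"].duplicated().any():
            dup = self.df["id"][self.df["id"].duplicated()].iloc[0]
            raise PedigreeError(f"duplicated individual id: {dup}")
        self._index = {iid: k for k, iid in enumerate(self.df["id"])}
        self._toposort()  # raises on cycles

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=np.int64)

    def parents_of(self, iid: str) -> tuple[str, str]:
        row = self.df.iloc[self._index[iid]]
        return row["sire"], row["dam"]

    def is_founder(self) -> np.ndarray:
        return ((self.df["sire"] == UNKNOWN_PARENT) & (self.df["dam"] == UNKNOWN_PARENT)).to_numpy()

    @property
    def founders(self) -> list[str]:
        return list(self.df["id"][self.is_founder()])

    def _toposort(self) -> None:
        """Kahn's algorithm over parent->offspring edges; cycle -> error naming an id."""
        ids = self.df["id"].to_list()
        sires = self.df["sire"].to_list()
        dams = self.df["dam"].to_list()
        idx = self._index
        n = len(ids)
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for k in range(n):
            for p in (sires[k], dams[k]):
                if p != UNKNOWN_PARENT:
                    if p not in idx:
                        raise PedigreeError(f"parent {p} of {ids[k]} not in pedigree")
                    children[idx[p]].append(k)
                    indeg[k] += 1
        order = [k for k in range(n) if indeg[k] == 0]
        head = 0
        while head < len(order):
            k = order[head]
            head += 1
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != n:
            stuck = ids[int(np.nonzero(indeg > 0)[0][0])]
            raise PedigreeError(f"pedigree cycle detected involving individual {stuck}")
        self._topo = order

    def topological_order(self) -> list[int]:
        """Row indices such that every parent precedes its offspring."""
        return list(self._topo)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str))


@dataclass
class GenotypeSet:
    """Individuals x SNP dosage matrix with a physical map.

    dosages: (n_samples, n_snps); int8 with -1 for missing, or float after
    dosage-mode imputation. snp_map columns: snp, chrom, pos (1-based bp).
    """

    samples: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame
    fill_mode: str | None = None  # set by fill_missing_genotypes

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if self.dosages.shape != (len(self.samples), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_map)} SNPs"
            )
        required = {"snp", "chrom", "pos"}
        if not required.issubset(self.snp_map.columns):
            raise ValueError(f"snp_map needs columns {sorted(required)}")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def missing_mask(self) -> np.ndarray:
        if np.issubdtype(self.dosages.dtype, np.floating):
            return np.isnan(self.dosages)
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (alternate) allele per SNP, missing ignored."""
        miss = self.missing_mask()
        d = np.where(miss, 0, self.dosages).astype(np.float64)
        n_called = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = d.sum(axis=0) / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, samples=None, snp_indices=None) -> "GenotypeSet":
        d = self.dosages
        smp = self.samples
        m = self.snp_map
        if samples is not None:
            pos = {s: k for k, s in enumerate(self.samples)}
            rows = np.array([pos[s] for s in samples], dtype=np.int64)
            d = d[rows]
            smp = list(samples)
        if snp_indices is not None:
            snp_indices = np.asarray(snp_indices)
            d = d[:, snp_indices]
            m = m.iloc[snp_indices].reset_index(drop=True)
        return GenotypeSet(smp, d.copy(), m.copy(), fill_mode=self.fill_mode)

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.samples)}
        return np.array([pos[s] for s in ids], dtype=np.int64)


@dataclass
class QtlRegion:
    """A detected QTL: peak SNP plus a closed bp interval around it."""

    chrom: str
    peak_snp: str
    peak_pos: int
    start: int
    end: int
    peak_stat: float
    method: str  # "gblup" | "bayescpi"
    var_explained_pct: float | None = None
    classification: str | None = None  # "putative" | "strong" (Bayesian scans)
    snp_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("QTL peak position must lie inside its interval")
        if self.var_explained_pct is not None and not (0.0 <= self.var_explained_pct <= 100.0):
            raise ValueError("variance explained must be a percentage in [0, 100]")

    def as_record(self) -> dict:
        return {
            "trait": getattr(self, "trait", ""),
            "chrom": self.chrom,
            "peak_snp": self.peak_snp,
            "peak_pos": self.peak_pos,
            "interval_start": self.start,
            "interval_end": self.end,
            "peak_stat": self.peak_stat,
            "method": self.method,
            "var_explained_pct": self.var_explained_pct,
            "classification": self.classification,
        }
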