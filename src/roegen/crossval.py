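"""Cross-validated comparison of pedigree BLUP vs genomic GBLUP prediction.

Four scenarios: T+ (large random training set), T- (a 672/1077-scaled subset
of T+'s training animals with the same validation fish), and the across-cohort
scenarios T1 (train on cohort 1, validate on cohort 2) and T2 (the reverse).
Accuracy is cor(EBV, corrected phenotype) / sqrt(h2); the inflation
(dispersion) coefficient is the regression of corrected phenotypes on EBVs,
with b < 1 flagging over-dispersed predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenomicKinship, PedigreeKinship
from .mixedmodel import (
    DesignSpec,
    MixedModelFit,
    RemlError,
    build_design,
    default_design_for,
    reml_estimate,
    solve_mme,
)

# training/validation sizes in the reference design, scaled proportionally
# to other population sizes
_REF_TOTAL = 1346
_REF_VALIDATION = 269
_REF_TRAIN_SMALL = 672


class CrossvalError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    name: str  # "T+", "T-", "T1", "T2"
    training: list[list[str]]  # one id list per replicate
    validation: list[list[str]]
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.training)


def build_scenarios(
    ids: list[str],
    cohorts: dict[str, str] | pd.Series,
    seed: int,
    n_replicates: int = 40,
) -> list[ScenarioSpec]:
    """The four scenarios for a phenotyped+genotyped id set.

    T+/T- sizes scale with len(ids) in the 1077/672/269-out-of-1346
    proportions; T- uses the same validation fish as the corresponding T+
    replicate. T1/T2 are the two across-cohort splits (single replicate).
    """
    ids = list(ids)
    n = len(ids)
    if isinstance(cohorts, pd.Series):
        cohorts = cohorts.to_dict()
    labels = sorted({cohorts[i] for i in ids})
    if len(labels) != 2:
        raise CrossvalError(f"need exactly two cohorts, found {labels}")
    n_val = int(round(n * _REF_VALIDATION / _REF_TOTAL))
    n_small = int(round(n * _REF_TRAIN_SMALL / _REF_TOTAL))
    if n_val < 2 or n_small < 2 or n - n_val < 2:
        raise CrossvalError(f"population of {n} too small to build the scenarios")
    rng = np.random.default_rng(seed)
    tplus_tr, tminus_tr, val = [], [], []
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        v = [ids[k] for k in perm[:n_val]]
        big = [ids[k] for k in perm[n_val:]]
        small_rows = rng.choice(len(big), size=n_small, replace=False)
        val.append(v)
        tplus_tr.append(big)
        tminus_tr.append([big[k] for k in sorted(small_rows)])
    c1 = [i for i in ids if cohorts[i] == labels[0]]
    c2 = [i for i in ids if cohorts[i] == labels[1]]
    return [
        ScenarioSpec("T+", tplus_tr, val, seed=seed),
        ScenarioSpec("T-", tminus_tr, val, seed=seed),
        ScenarioSpec("T1", [c1], [c2], seed=seed),
        ScenarioSpec("T2", [c2], [c1], seed=seed),
    ]


def corrected_phenotypes(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """y* = y - X beta_hat: records with fixed effects and covariates removed."""
    return np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)


@dataclass
class PredictionMetrics:
    r: float  # accuracy = cor(EBV, y*) / sqrt(h2)
    b: float  # inflation = cov(y*, EBV) / var(EBV)
    n: int
    flagged: bool = False


def evaluate_predictions(ebv: np.ndarray, ystar: np.ndarray, h2: float) -> PredictionMetrics:
    """Accuracy and dispersion of predictions against corrected phenotypes."""
    if not (0.0 < h2 <= 1.0):
        raise CrossvalError("h2 must be in (0, 1]")
    ebv = np.asarray(ebv, dtype=float)
    ystar = np.asarray(ystar, dtype=float)
    obs = ~(np.isnan(ebv) | np.isnan(ystar))
    ebv, ystar = ebv[obs], ystar[obs]
    v = ebv.var(ddof=1)
    if v <= 0:
        return PredictionMetrics(float("nan"), float("nan"), int(obs.sum()), flagged=True)
    r = float(np.corrcoef(ebv, ystar)[0, 1] / np.sqrt(h2))
    b = float(np.cov(ystar, ebv, ddof=1)[0, 1] / v)
    return PredictionMetrics(r, b, int(obs.sum()))


@dataclass
class CrossvalResult:
    records: pd.DataFrame  # trait, scenario, method, replicate, r, b
    summary: pd.DataFrame  # means/SDs over replicates + relative efficiency
    h2_used: dict  # (trait, method) -> full-data h2 in the accuracy denominator


def _independent_cols(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting).

    Training subsets of a factorial design can zero out or alias factor
    columns (e.g. a single-cohort training set), so fits on subsets prune the
    design instead of failing on a singular system.
    """
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return np.sort(piv[: int((diag > tol).sum())])


def _single_trait_fit(y, X, record_ids, kinship, vg, ve, trait="trait1"):
    return solve_mme(
        y[:, None], [X], record_ids, kinship,
        np.array([[vg]]), np.array([[ve]]), traits=[trait],
    )


def run_crossval(
    pheno: pd.DataFrame,
    kinship_a: PedigreeKinship,
    kinship_g: GenomicKinship,
    traits: list[str],
    scenarios: list[ScenarioSpec],
    designs: dict[str, DesignSpec] | None = None,
    reestimate_components: bool = True,
    reml_kwargs: dict | None = None,
) -> CrossvalResult:
    """Replicate BLUP vs GBLUP cross-validation over traits and scenarios.

    For each replicate the model is refit with validation records masked
    (pedigree links are retained for BLUP; GBLUP's G always covers all
    genotyped animals), validation animals are scored against their corrected
    phenotypes (fixed effects from the full-data fit), and accuracy uses the
    full-data REML heritability of that trait under the method's kinship.
    Components are re-estimated on each training set by default; with
    ``reestimate_components=False`` the full-data components are reused.
    """
    reml_kwargs = dict(reml_kwargs or {"tol": 1e-6, "max_iter": 100})
    kinships = {"BLUP": kinship_a, "GBLUP": kinship_g}
    rows = []
    h2_used = {}
    for trait in traits:
        spec = (designs or {}).get(trait, default_design_for(trait))
        sub = pheno.dropna(subset=[trait]).reset_index(drop=True)
        X, names = build_design(sub, spec)
        y = sub[trait].to_numpy(dtype=float)
        ids = list(sub["id"])
        id_row = {i: k for k, i in enumerate(ids)}
        full_data = {}
        for method, kin in kinships.items():
            K = kin.A if method == "BLUP" else kin.G
            kin_ids = kin.ids
            keep = [i for i in ids if i in set(kin_ids)]
            rows_rec = np.array([id_row[i] for i in keep])
            pos = {s: k for k, s in enumerate(kin_ids)}
            krows = np.array([pos[i] for i in keep])
            Ksub = K[np.ix_(krows, krows)]
            vc = reml_estimate(
                y[rows_rec][:, None], [X[rows_rec]], K=Ksub, traits=[trait], **reml_kwargs
            )
            vg, ve = float(vc.Vg[0, 0]), float(vc.Ve[0, 0])
            h2 = vg / (vg + ve)
            h2_used[(trait, method)] = h2
            fit = _single_trait_fit(y[rows_rec], X[rows_rec], keep, kin, vg, ve, trait)
            beta = fit.beta[0]
            ystar_all = corrected_phenotypes(y, X, beta)
            full_data[method] = {
                "h2": h2, "vg": vg, "ve": ve, "ystar": ystar_all, "keep": set(keep),
            }
        for scen in scenarios:
            for rep in range(scen.n_replicates):
                train = scen.training[rep]
                valid = scen.validation[rep]
                if set(train) & set(valid):
                    raise CrossvalError("training and validation sets overlap")
                for method, kin in kinships.items():
                    fd = full_data[method]
                    tr_ids = [i for i in train if i in fd["keep"]]
                    va_ids = [i for i in valid if i in fd["keep"]]
                    tr_rows = np.array([id_row[i] for i in tr_ids])
                    X_tr = X[tr_rows]
                    X_tr = X_tr[:, _independent_cols(X_tr)]
                    try:
                        if reestimate_components:
                            pos = {s: k for k, s in enumerate(kin.ids)}
                            krows = np.array([pos[i] for i in tr_ids])
                            K = (kin.A if method == "BLUP" else kin.G)[np.ix_(krows, krows)]
                            vc = reml_estimate(
                                y[tr_rows][:, None], [X_tr], K=K,
                                traits=[trait], **reml_kwargs
                            )
                            vg, ve = float(vc.Vg[0, 0]), float(vc.Ve[0, 0])
                        else:
                            vg, ve = fd["vg"], fd["ve"]
                        fit = _single_trait_fit(y[tr_rows], X_tr, tr_ids, kin, vg, ve, trait)
                    except (RemlError, np.linalg.LinAlgError):
                        rows.append(
                            {"trait": trait, "scenario": scen.name, "method": method,
                             "replicate": rep, "r": np.nan, "b": np.nan, "failed": True}
                        )
                        continue
                    ebv = fit.ebv(trait).reindex(va_ids).to_numpy()
                    ystar = fd["ystar"][np.array([id_row[i] for i in va_ids])]
                    m = evaluate_predictions(ebv, ystar, fd["h2"])
                    rows.append(
                        {"trait": trait, "scenario": scen.name, "method": method,
                         "replicate": rep, "r": m.r, "b": m.b, "failed": m.flagged}
                    )
    records = pd.DataFrame(rows)
    summ = (
        records.dropna(subset=["r"])
        .groupby(["trait", "scenario", "method"])
        .agg(
            r_mean=("r", "mean"), r_sd=("r", "std"),
            b_mean=("b", "mean"), b_sd=("b", "std"),
            n_completed=("r", "size"),
        )
        .reset_index()
    )
    # relative efficiency of GBLUP vs BLUP on mean accuracy
    eff = []
    for (trait, scen), grp in summ.groupby(["trait", "scenario"]):
        by = {m: v for m, v in zip(grp["method"], grp["r_mean"])}
        if "BLUP" in by and "GBLUP" in by and by["BLUP"] != 0:
            eff.append({"trait": trait, "scenario": scen,
                        "relative_efficiency": (by["GBLUP"] - by["BLUP"]) / abs(by["BLUP"])})
    summary = summ.merge(pd.DataFrame(eff), on=["trait", "scenario"], how="left")
    return CrossvalResult(records=records, summary=summary, h2_used=h2_used)
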