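"""Logistic apparent-survival models with AICc model averaging.

Apparent survival of a released rabbit is detection in a later survey
(0/1), modelled by logistic regression on release day, sex, release
weight, individual homozygosity (HL) and CB ancestry; juvenile models
additionally carry release year as a categorical term (reference 2014).
Candidate sets are every subset of the five covariates (32 models,
including the null); ranking uses AICc and Akaike weights, and coefficient
averages are "natural": each parameter is averaged over the models that
contain it with weights renormalised within that subset, with
unconditional standard errors and both 85% and 95% normal-theory
confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

COVARIATES = ("release_day", "sex", "release_weight", "HL", "CB")
YEAR_REFERENCE = 2014
Z_85 = 1.4395314709384563  # Phi^-1(0.925)
Z_95 = 1.959963984540054


@dataclass
class ModelFit:
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    flagged: bool = False
    flag_reason: str = ""

    @property
    def aicc(self) -> float:
        if self.n <= self.k + 1:
            return math.inf
        return (
            -2.0 * self.loglik
            + 2.0 * self.k
            + 2.0 * self.k * (self.k + 1) / (self.n - self.k - 1)
        )

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


@dataclass
class ModelAverageResult:
    table: pd.DataFrame  # estimate, se, ci85/ci95 bounds, n_models per row
    weights: pd.Series  # Akaike weight per model (by terms label)
    fits: list[ModelFit] = field(default_factory=list)


def _design(
    data: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix for a term set; rows with missing modelled covariates
    are dropped for that model only."""
    cols: dict[str, pd.Series] = {}
    used: list[str] = []
    for term in terms:
        if term == "year":
            used.append("year")
            levels = sorted(set(data["year"].astype(int)))
            for lv in levels:
                if lv == YEAR_REFERENCE:
                    continue
                cols[f"year_{lv}"] = (
                    data["year"].astype(int) == lv
                ).astype(float)
        elif term == "sex":
            used.append("sex")
            cols["sex_female"] = (
                data["sex"].astype(str).str.upper().isin(["F", "FEMALE"])
            ).astype(float)
        else:
            used.append(term)
            cols[term] = pd.to_numeric(data[term])
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "intercept", 1.0)
    keep = data["detected"].notna()
    for term in used:
        keep &= data[term].notna()
    y = data.loc[keep, "detected"].astype(float)
    return X.loc[keep], y


def fit_logistic(
    data: pd.DataFrame, terms: tuple[str, ...] = ()
) -> ModelFit:
    """Maximum-likelihood logistic fit of detection on a term set.

    Diverging coefficients (complete separation) flag the fit so model
    averaging can exclude it.
    """
    X, y = _design(data, tuple(terms))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix not full rank after exclusions")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    flagged = False
    reason = ""
    if not res.converged or np.abs(res.params.to_numpy()).max() > 15.0:
        flagged = True
        reason = "possible separation: diverging coefficients"
    return ModelFit(
        terms=tuple(terms),
        params=res.params,
        bse=res.bse,
        loglik=float(res.llf),
        k=int(X.shape[1]),
        n=int(len(y)),
        flagged=flagged,
        flag_reason=reason,
    )


def build_candidate_sets(population: str) -> list[tuple[str, ...]]:
    """Candidate term sets per population.

    Adults and release-pen juveniles: every subset of the five covariates,
    null model included (32 sets).  Juveniles: release year in every model
    plus every subset of the remaining covariates (32 sets).
    """
    subsets = [
        tuple(c)
        for r in range(len(COVARIATES) + 1)
        for c in itertools.combinations(COVARIATES, r)
    ]
    if population == "adult" or population == "release_pen":
        return subsets
    if population == "juvenile":
        return [("year",) + s for s in subsets]
    raise ValueError(
        f"unknown population {population!r} "
        "(expected 'adult', 'juvenile' or 'release_pen')"
    )


def akaike_weights(aiccs: list[float]) -> np.ndarray:
    arr = np.asarray(aiccs, dtype=float)
    delta = arr - arr.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def aicc_rank_and_average(fits: list[ModelFit]) -> ModelAverageResult:
    """Rank fits by AICc and model-average every parameter.

    Natural averaging: a parameter's estimate is averaged over the models
    containing it, with those models' Akaike weights renormalised.  The
    unconditional standard error folds in between-model spread:
    se = sqrt(sum w_i (se_i^2 + (b_i - bbar)^2)).
    """
    usable = [f for f in fits if not f.flagged]
    if not usable:
        raise ValueError("no converged fits to average")
    w = akaike_weights([f.aicc for f in usable])
    labels = [" + ".join(f.terms) if f.terms else "(null)" for f in usable]
    weights = pd.Series(w, index=labels, name="akaike_weight")
    params: set[str] = set()
    for f in usable:
        params.update(f.params.index)
    rows = []
    for name in sorted(params):
        idx = [i for i, f in enumerate(usable) if name in f.params.index]
        wi = w[idx] / w[idx].sum()
        est = np.array([usable[i].params[name] for i in idx])
        se = np.array([usable[i].bse[name] for i in idx])
        avg = float(np.sum(wi * est))
        unc_se = float(
            math.sqrt(np.sum(wi * (se**2 + (est - avg) ** 2)))
        )
        rows.append(
            {
                "parameter": name,
                "estimate": avg,
                "unconditional_se": unc_se,
                "ci85_low": avg - Z_85 * unc_se,
                "ci85_high": avg + Z_85 * unc_se,
                "ci95_low": avg - Z_95 * unc_se,
                "ci95_high": avg + Z_95 * unc_se,
                "n_models": len(idx),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return ModelAverageResult(table=table, weights=weights, fits=usable)


def model_table(fits: list[ModelFit]) -> pd.DataFrame:
    """AICc ranking table: terms, k, lnL, AICc, delta, weight."""
    usable = [f for f in fits if not f.flagged]
    w = akaike_weights([f.aicc for f in usable])
    rows = []
    for f, wt in zip(usable, w):
        rows.append(
            {
                "terms": " + ".join(f.terms) if f.terms else "(null)",
                "k": f.k,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "weight": wt,
            }
        )
    df = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    return df


def predicted_survival_curve(
    fit: ModelFit,
    grid: pd.DataFrame,
    data: pd.DataFrame,
) -> np.ndarray:
    """Inverse-logit predictions over a covariate grid, with unspecified
    covariates held at their observed means (reference level for
    categoricals)."""
    X, _ = _design(data, fit.terms)
    means = X.mean(axis=0)
    preds = []
    for _, row in grid.iterrows():
        x = means.copy()
        for col, val in row.items():
            if col == "sex":
                x["sex_female"] = 1.0 if str(val).upper() in ("F", "FEMALE") else 0.0
            elif col == "year":
                for c in x.index:
                    if c.startswith("year_"):
                        x[c] = 1.0 if c == f"year_{int(val)}" else 0.0
            elif col in x.index:
                x[col] = float(val)
        lin = float(np.dot(fit.params.reindex(x.index).fillna(0.0), x))
        preds.append(1.0 / (1.0 + math.exp(-lin)))
    return np.array(preds)


def fit_candidates(
    data: pd.DataFrame, population: str
) -> list[ModelFit]:
    """Fit the whole candidate set for a population, skipping term sets
    whose design collapses (rank deficiency after missing-data
    exclusions)."""
    fits = []
    for terms in build_candidate_sets(population):
        try:
            fits.append(fit_logistic(data, terms))
        except (ValueError, np.linalg.LinAlgError):
            continue
    return fits
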