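"""Multiple imputation by chained equations.

Each of M imputations starts from random draws out of every variable's
observed margin, then cycles through the incomplete variables in order
of increasing missingness, re-imputing each from its conditional model
given all other (current) variables.  Parameter uncertainty is
propagated by the approximate Bayesian bootstrap: the conditional model
is fitted to a with-replacement resample of the observed rows before
drawing imputations.  Continuous variables use predictive-mean matching
(k donors) by default; categorical variables use (multinomial) logistic
draws, falling back to margin draws for rare categories.  The binary
maladjustment outcome is passively re-derived from the imputed scale
totals (a deterministic function of them), with an option to impute it
directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm
from .cohort import Cohort, define_outcome
from .schema import GENDER_COL, LOCAL_COL, OUTCOME_COL, SCHOOL_FLAG_COL

RARE_CATEGORY_MIN = 10


class ImputationModelError(RuntimeError):
    """Conditional model failure, annotated with variable and cycle."""


@dataclass
class ImputationSpec:
    M: int = 15
    n_train: int = 10
    n_validation: int = 5
    n_cycles: int = 10
    seed: int = 0
    pmm_k: int = 5
    #: 'pmm' or 'norm' for continuous variables
    continuous_model: str = "pmm"
    #: passively re-derive the outcome from imputed scales (default) or
    #: impute the binary outcome directly
    direct_outcome: bool = False

    def __post_init__(self):
        if self.n_train + self.n_validation != self.M:
            raise ValueError("n_train + n_validation must equal M")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class ImputationSet:
    completed: list[Cohort]
    partition: list[str]  # 'train' / 'validation' per copy
    diagnostics: dict[str, np.ndarray]  # var -> (n_cycles, M) chain means
    spec: ImputationSpec

    @property
    def M(self) -> int:
        return len(self.completed)

    def training(self) -> list[Cohort]:
        return [c for c, p in zip(self.completed, self.partition) if p == "train"]

    def validation(self) -> list[Cohort]:
        return [c for c, p in zip(self.completed, self.partition) if p == "validation"]


def _margin_draw(rng, observed: pd.Series, size: int):
    vals = observed.dropna().to_numpy()
    return rng.choice(vals, size=size, replace=True)


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X, _, _ = glm.build_design(df, predictors)
    return X


def _pmm_draw(rng, X, y_obs_mask, y, k: int) -> np.ndarray:
    """Predictive-mean matching with Bayesian-bootstrap slopes."""
    X_obs, y_obs = X[y_obs_mask], y[y_obs_mask]
    X_mis = X[~y_obs_mask]
    ridge = 1e-6 * np.eye(X.shape[1])
    beta_hat = np.linalg.solve(X_obs.T @ X_obs + ridge, X_obs.T @ y_obs)
    idx = rng.integers(0, len(y_obs), size=len(y_obs))
    Xb, yb = X_obs[idx], y_obs[idx]
    beta_star = np.linalg.solve(Xb.T @ Xb + ridge, Xb.T @ yb)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    order = np.argsort(yhat_obs)
    sorted_hat = yhat_obs[order]
    sorted_y = y_obs[order]
    out = np.empty(len(yhat_mis))
    pos = np.searchsorted(sorted_hat, yhat_mis)
    m = len(sorted_hat)
    kk = min(k, m)
    for i, (p, v) in enumerate(zip(pos, yhat_mis)):
        lo = max(0, p - kk)
        hi = min(m, p + kk)
        window = np.arange(lo, hi)
        d = np.abs(sorted_hat[window] - v)
        donors = window[np.argsort(d, kind="stable")[:kk]]
        out[i] = sorted_y[rng.choice(donors)]
    return out


def _norm_draw(rng, X, y_obs_mask, y) -> np.ndarray:
    """Parametric normal draw with bootstrap parameter uncertainty."""
    X_obs, y_obs = X[y_obs_mask], y[y_obs_mask]
    X_mis = X[~y_obs_mask]
    ridge = 1e-6 * np.eye(X.shape[1])
    idx = rng.integers(0, len(y_obs), size=len(y_obs))
    Xb, yb = X_obs[idx], y_obs[idx]
    beta_star = np.linalg.solve(Xb.T @ Xb + ridge, Xb.T @ yb)
    resid = yb - Xb @ beta_star
    dfree = max(len(yb) - X.shape[1], 1)
    sigma = np.sqrt(np.sum(resid**2) / dfree)
    return X_mis @ beta_star + rng.standard_normal(len(X_mis)) * sigma


def _categorical_draw(rng, df, var, miss_mask, predictors):
    """Logistic (2 levels, own IRLS) or multinomial-logistic (>2,
    scikit-learn) draws on an approximate-Bayesian-bootstrap refit."""
    obs_mask = ~miss_mask
    cat = df[var]
    levels = list(cat.cat.categories)
    codes = cat.cat.codes.to_numpy().copy()
    counts = cat[obs_mask].value_counts()
    present = [lv for lv in levels if counts.get(lv, 0) > 0]
    if len(present) < 2 or counts[counts > 0].min() < RARE_CATEGORY_MIN:
        return _margin_draw(rng, cat[obs_mask], int(miss_mask.sum()))
    X = _design(df, predictors)
    X_obs, X_mis = X[obs_mask.to_numpy()], X[miss_mask.to_numpy()]
    y_obs = codes[obs_mask.to_numpy()]
    idx = rng.integers(0, len(y_obs), size=len(y_obs))
    Xb, yb = X_obs[idx], y_obs[idx]
    if len(np.unique(yb)) < 2:
        return _margin_draw(rng, cat[obs_mask], int(miss_mask.sum()))
    if len(present) == 2:
        hi = max(np.unique(yb))
        beta, _, _, _ = glm.fit_logistic_arrays(Xb, (yb == hi).astype(float), ridge=1e-3)
        p = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ beta, -35, 35)))
        drawn = np.where(rng.random(len(p)) < p, hi, np.unique(yb).min())
        return np.asarray(levels)[drawn]
    from sklearn.linear_model import LogisticRegression

    # standardize (sans intercept column) so lbfgs converges quickly
    mu = Xb[:, 1:].mean(axis=0)
    sd = Xb[:, 1:].std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(C=100.0, max_iter=200)
    model.fit((Xb[:, 1:] - mu) / sd, yb)  # sklearn adds its own intercept
    probs = model.predict_proba((X_mis[:, 1:] - mu) / sd)
    cum = np.cumsum(probs, axis=1)
    drawn = (rng.random(len(X_mis))[:, None] > cum).sum(axis=1)
    return np.asarray(levels)[model.classes_[drawn]]


def impute(cohort: Cohort, spec: ImputationSpec) -> ImputationSet:
    """Run chained equations, returning M completed cohorts with the
    train/validation partition and per-variable chain-mean diagnostics.
    Deterministic given (cohort, spec)."""
    df = cohort.df
    demographics = [c for c in (GENDER_COL, LOCAL_COL, SCHOOL_FLAG_COL) if c in df]
    variables = list(cohort.item_names) + list(cohort.scale_names)
    if spec.direct_outcome:
        variables.append(OUTCOME_COL)
    incomplete = [v for v in variables if df[v].isna().any()]
    for v in incomplete:
        if df[v].notna().sum() == 0:
            raise ImputationModelError(f"variable {v!r} has no observed values")
    if not any(df[v].notna().all() for v in variables + demographics):
        raise ImputationModelError("need at least one fully observed variable")
    # visit order: increasing missingness
    incomplete.sort(key=lambda v: (int(df[v].isna().sum()), v))
    miss_masks = {v: df[v].isna() for v in incomplete}

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.M)
    completed: list[Cohort] = []
    diagnostics: dict[str, list[list[float]]] = {v: [] for v in incomplete}
    for m in range(spec.M):
        rng = np.random.default_rng(seeds[m])
        work = cohort.copy()
        wdf = work.df
        for v in incomplete:
            mask = miss_masks[v]
            draws = _margin_draw(rng, df[v], int(mask.sum()))
            wdf.loc[mask, v] = draws
        chain = {v: [] for v in incomplete}
        for cycle in range(spec.n_cycles):
            for v in incomplete:
                mask = miss_masks[v]
                predictors = [
                    p
                    for p in demographics + variables
                    if p != v and (spec.direct_outcome or p != OUTCOME_COL)
                ]
                try:
                    if v in cohort.scale_names:
                        X = _design(wdf, predictors)
                        y = wdf[v].to_numpy(dtype=float)
                        obs = ~mask.to_numpy()
                        if spec.continuous_model == "pmm":
                            vals = _pmm_draw(rng, X, obs, y, spec.pmm_k)
                        else:
                            vals = _norm_draw(rng, X, obs, y)
                        wdf.loc[mask, v] = vals
                        chain[v].append(float(np.mean(vals)))
                    elif v == OUTCOME_COL:
                        X = _design(wdf, predictors)
                        y = wdf[v].to_numpy(dtype=float)
                        obs = ~mask.to_numpy()
                        idx = rng.integers(0, obs.sum(), size=obs.sum())
                        beta, _, _, _ = glm.fit_logistic_arrays(
                            X[obs][idx], y[obs][idx], ridge=1e-3
                        )
                        p = 1.0 / (1.0 + np.exp(-np.clip(X[~obs] @ beta, -35, 35)))
                        vals = (rng.random(len(p)) < p).astype(float)
                        wdf.loc[mask, v] = vals
                        chain[v].append(float(np.mean(vals)))
                    else:
                        vals = _categorical_draw(rng, wdf, v, mask, predictors)
                        wdf.loc[mask, v] = vals
                        ref = work.schema.item(v).reference_level
                        chain[v].append(float(np.mean(np.asarray(vals) != ref)))
                except Exception as exc:  # annotate with variable and cycle
                    raise ImputationModelError(
                        f"conditional model for {v!r} failed in cycle {cycle + 1}: {exc}"
                    ) from exc
        if not spec.direct_outcome and work.schema.thresholds:
            work = define_outcome(
                work,
                percentile=work.schema.outcome_percentile or 95.0,
                thresholds=work.schema.thresholds,
            )
        completed.append(work)
        for v in incomplete:
            diagnostics[v].append(chain[v])
    partition = ["train"] * spec.n_train + ["validation"] * spec.n_validation
    diag = {v: np.asarray(diagnostics[v]).T for v in incomplete}  # (cycles, M)
    return ImputationSet(completed=completed, partition=partition,
                         diagnostics=diag, spec=spec)


def split_train_validation(
    iset: ImputationSet, n_train: int, n_validation: int
) -> ImputationSet:
    """Deterministic partition by copy index: first ``n_train`` copies
    are the training samples, the remainder validate."""
    if n_train + n_validation != iset.M:
        raise ValueError(
            f"n_train + n_validation = {n_train + n_validation} != M = {iset.M}"
        )
    partition = ["train"] * n_train + ["validation"] * n_validation
    return replace(iset, partition=partition)
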