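"""Binary logistic regression and stepwise selection, from scratch.

Maximum likelihood by iteratively reweighted least squares, with
categorical terms expanded to indicators against their reference level.
Stepwise selection is forward entry with backward elimination driven by
likelihood-ratio tests; a multi-level item enters or leaves as a whole
block (k-1 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

INTERCEPT = "(Intercept)"
#: any coefficient drifting past this during IRLS flags separation
SEPARATION_BOUND = 15.0
MAX_ITER = 100
TOL = 1e-8


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation (diverging coefficients)."""


class RankDeficiencyError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n: int
    #: term -> list of design-column names it contributed
    term_blocks: dict[str, list[str]] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def se(self) -> dict[str, float]:
        d = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return dict(zip(self.coefficients, d))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        beta = np.array(list(self.coefficients.values()))
        return X @ beta

    def to_json_dict(self) -> dict:
        return {
            "terms": list(self.term_blocks),
            "coefficients": self.coefficients,
            "se": self.se(),
            "log_likelihood": self.log_likelihood,
            "n": self.n,
        }


def build_design(
    df: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Design matrix with intercept; categorical columns expand to
    indicators of every level after the first (the reference)."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [INTERCEPT]
    blocks: dict[str, list[str]] = {}
    for t in terms:
        x = df[t]
        if isinstance(x.dtype, pd.CategoricalDtype) or x.dtype == object:
            cat = x.astype("category") if x.dtype == object else x
            if cat.isna().any():
                raise ValueError(f"term {t!r} has missing values")
            levels = list(cat.cat.categories)
            block = []
            for lv in levels[1:]:
                cols.append((cat == lv).to_numpy(dtype=float))
                name = f"{t}[{lv}]"
                names.append(name)
                block.append(name)
            blocks[t] = block
        else:
            v = x.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"term {t!r} has missing values")
            cols.append(v)
            names.append(t)
            blocks[t] = [t]
    return np.column_stack(cols), names, blocks


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_arrays(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    on_separation: str = "raise",
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """IRLS core on raw arrays.  Returns (beta, covariance, loglik,
    converged).  ``on_separation``: 'raise' or 'ridge' (refit with a
    fixed small penalty on everything but the intercept)."""
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # never penalize the intercept
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + np.diag(penalty)
        g = XtW @ z
        try:
            new = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                raise RankDeficiencyError("singular information matrix") from None
            raise
        step = np.max(np.abs(new - beta))
        beta = new
        if ridge == 0.0 and np.any(np.abs(beta) > SEPARATION_BOUND):
            if on_separation == "ridge":
                return fit_logistic_arrays(X, y, ridge=0.1, on_separation="raise")
            raise SeparationError(
                "coefficients diverging: complete or quasi-complete separation"
            )
        if step < TOL:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X.T * w) @ X + np.diag(penalty)
    cov = np.linalg.pinv(H)
    return beta, cov, _loglik(y, eta), converged


def fit_logistic(
    data,
    outcome: str,
    terms: list[str],
    ridge: float = 0.0,
    on_separation: str = "raise",
) -> LogisticFit:
    """Fit outcome ~ intercept + terms on a DataFrame (or Cohort)."""
    df = getattr(data, "df", data)
    y = df[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome has missing values")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    X, names, blocks = build_design(df, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    beta, cov, ll, converged = fit_logistic_arrays(
        X, y, ridge=ridge, on_separation=on_separation
    )
    return LogisticFit(
        coefficients=dict(zip(names, beta)),
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n=len(y),
        term_blocks=blocks,
    )


@dataclass
class StepwiseResult:
    selected_items: set[str]
    final_fit: LogisticFit
    trace: list[tuple[int, str, str, float]]  # (step, item, enter/remove, p)


def _lr_pvalue(ll_full: float, ll_reduced: float, df_diff: int) -> float:
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(chi2.sf(stat, df_diff))


def _block_df(df: pd.DataFrame, item: str) -> int:
    x = df[item]
    if isinstance(x.dtype, pd.CategoricalDtype):
        return len(x.cat.categories) - 1
    if x.dtype == object:
        return x.nunique() - 1
    return 1


def stepwise_select(
    data,
    outcome: str,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    on_separation: str = "ridge",
    max_steps: int = 200,
) -> StepwiseResult:
    """Forward selection with backward elimination on LR-test p-values.

    At each step the candidate with the smallest likelihood-ratio p
    below ``p_enter`` enters (ties broken lexicographically by item
    name); after each entry any included item whose LR p exceeds
    ``p_remove`` is removed, largest p first.  Deterministic.
    """
    if not (0.0 < p_enter < 1.0 and 0.0 < p_remove < 1.0):
        raise ValueError("p thresholds must be in (0, 1)")
    df = getattr(data, "df", data)
    current: list[str] = []
    trace: list[tuple[int, str, str, float]] = []
    step = 0

    def fit(terms):
        return fit_logistic(df, outcome, terms, on_separation=on_separation)

    base_fit = fit(current)
    while step < max_steps:
        changed = False
        # forward
        best: tuple[float, str] | None = None
        for cand in sorted(set(candidates) - set(current)):
            try:
                full = fit(current + [cand])
            except (SeparationError, RankDeficiencyError):
                continue
            p = _lr_pvalue(full.log_likelihood, base_fit.log_likelihood,
                           _block_df(df, cand))
            if best is None or (p, cand) < best:
                best = (p, cand)
        if best is not None and best[0] < p_enter:
            step += 1
            current.append(best[1])
            current.sort()
            trace.append((step, best[1], "enter", best[0]))
            base_fit = fit(current)
            changed = True
        # backward
        while current:
            full = base_fit
            worst: tuple[float, str] | None = None
            for item in sorted(current):
                reduced = fit([t for t in current if t != item])
                p = _lr_pvalue(full.log_likelihood, reduced.log_likelihood,
                               _block_df(df, item))
                # largest p first; lexicographic tie-break
                if worst is None or (-p, item) < (-worst[0], worst[1]):
                    worst = (p, item)
            if worst is not None and worst[0] > p_remove:
                step += 1
                current.remove(worst[1])
                trace.append((step, worst[1], "remove", worst[0]))
                base_fit = fit(current)
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseResult(selected_items=set(current), final_fit=base_fit, trace=trace)
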