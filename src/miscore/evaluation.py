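"""Internal validation of the instrument.

Discrimination (Mann-Whitney AUC with DeLong standard errors),
calibration slope (logistic regression of the outcome on the
risk-oriented linear predictor, ideal value +1), Rubin's-rules pooling
across imputations, dichotomized diagnostic-test metrics under the
protective orientation (high score = test NEGATIVE), Youden-index
cutoff optimization, score-band likelihood ratios, and Bayes post-test
updating.  Also the listwise-deletion comparison arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from . import glm
from .instrument import ScoreTable, build_score_table, score_individuals
from .schema import OUTCOME_COL


# ---------------------------------------------------------------- AUC

def auc(scores, outcomes) -> tuple[float, float]:
    """Mann-Whitney AUC of a risk-oriented score (ties count 1/2) with
    the DeLong placement-value standard error."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    cases = s[y == 1]
    controls = s[y == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # placement values via rank trick
    order = np.sort(controls)
    v10 = (np.searchsorted(order, cases, side="left")
           + np.searchsorted(order, cases, side="right")) / (2.0 * n)
    order_c = np.sort(cases)
    v01 = 1.0 - (np.searchsorted(order_c, controls, side="left")
                 + np.searchsorted(order_c, controls, side="right")) / (2.0 * m)
    estimate = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    return estimate, se


# -------------------------------------------------- calibration slope

def calibration_slope(linear_predictor, outcomes) -> tuple[float, float]:
    """Coefficient of the risk-oriented linear predictor in a logistic
    regression of the outcome on it; 1 is ideal, <1 over-optimistic."""
    eta = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(eta) == 0:
        raise ValueError("constant linear predictor")
    df = pd.DataFrame({"eta": eta, "y": y})
    fit = glm.fit_logistic(df, "y", ["eta"])
    slope = fit.coefficients["eta"]
    se = fit.se()["eta"]
    return float(slope), float(se)


# ------------------------------------------------------ Rubin pooling

@dataclass
class PooledEstimate:
    Q_bar: float
    W: float
    B: float
    T: float
    df: float
    ci_low: float
    ci_high: float
    M: int

    @property
    def se(self) -> float:
        return math.sqrt(self.T)


def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Rubin's rules: T = W + (1 + 1/M) B, Barnard-Rubin-style df
    (M-1)(1 + W/((1+1/M)B))^2, t-based confidence interval."""
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape:
        raise ValueError("estimates and variances must have equal length")
    if np.any(v < 0):
        raise ValueError("negative variance")
    M = len(q)
    if M == 0:
        raise ValueError("empty input")
    Q_bar = float(q.mean())
    W = float(v.mean())
    if M == 1:
        B = 0.0
    else:
        B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if M > 1 and B > 0:
        df = (M - 1) * (1.0 + W / ((1.0 + 1.0 / M) * B)) ** 2
        crit = t_dist.ppf(1.0 - alpha / 2.0, df)
    else:
        df = math.inf
        crit = norm.ppf(1.0 - alpha / 2.0)
    half = crit * math.sqrt(T)
    return PooledEstimate(Q_bar=Q_bar, W=W, B=B, T=T, df=df,
                         ci_low=Q_bar - half, ci_high=Q_bar + half, M=M)


# ---------------------------------------------------- diagnostic test

@dataclass
class DiagnosticReport:
    cutoff: float
    negative_rule: str
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    dor: float
    prevalence: float
    fraction_negative: float
    counts: dict[str, int]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("cutoff", "negative_rule", "sensitivity", "specificity", "ppv",
              "npv", "lr_pos", "lr_neg", "dor", "prevalence", "fraction_negative")}
        d["counts"] = self.counts
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _logit_ci(p: float, n: int, z: float) -> tuple[float, float]:
    if p <= 0.0 or p >= 1.0 or n == 0:
        return (p, p)
    se = math.sqrt(1.0 / (n * p * (1.0 - p)))
    lo = math.log(p / (1 - p)) - z * se
    hi = math.log(p / (1 - p)) + z * se
    return (1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi)))


def diagnostic_metrics(
    scores, outcomes, cutoff: float, prevalence: float | None = None
) -> DiagnosticReport:
    """Dichotomize a protective-positive score: test NEGATIVE iff
    score > cutoff.  PPV/NPV come from the 2x2 table, or from supplied
    prevalence via Bayes.  CIs: logit-scale Wald for proportions,
    log-scale Wald for ratios."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    positive = s <= cutoff  # low protective score = test positive
    tp = int(np.sum(positive & (y == 1)))
    fp = int(np.sum(positive & (y == 0)))
    fn = int(np.sum(~positive & (y == 1)))
    tn = int(np.sum(~positive & (y == 0)))
    if (tp + fn) == 0 or (tn + fp) == 0:
        raise ValueError("cutoff leaves an outcome class empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prev = prevalence if prevalence is not None else (tp + fn) / len(y)
    if prevalence is not None:
        ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev)) \
            if (sens * prev + (1 - spec) * (1 - prev)) > 0 else float("nan")
        npv = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev) \
            if (spec * (1 - prev) + (1 - sens) * prev) > 0 else float("nan")
    else:
        ppv = tp / (tp + fp) if (tp + fp) else float("nan")
        npv = tn / (tn + fn) if (tn + fn) else float("nan")
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    dor = lr_pos / lr_neg if lr_neg > 0 else float("inf")
    z = norm.ppf(0.975)
    ci = {
        "sensitivity": _logit_ci(sens, tp + fn, z),
        "specificity": _logit_ci(spec, tn + fp, z),
        "ppv": _logit_ci(ppv, tp + fp, z) if not math.isnan(ppv) else (ppv, ppv),
        "npv": _logit_ci(npv, tn + fn, z) if not math.isnan(npv) else (npv, npv),
    }
    if 0 < sens < 1 and 0 < spec < 1:
        se_lrp = math.sqrt((1 - sens) / tp + spec / fp)
        se_lrn = math.sqrt(sens / fn + (1 - spec) / tn)
        se_dor = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        ci["lr_pos"] = (lr_pos * math.exp(-z * se_lrp), lr_pos * math.exp(z * se_lrp))
        ci["lr_neg"] = (lr_neg * math.exp(-z * se_lrn), lr_neg * math.exp(z * se_lrn))
        ci["dor"] = (dor * math.exp(-z * se_dor), dor * math.exp(z * se_dor))
    return DiagnosticReport(
        cutoff=float(cutoff),
        negative_rule=f"score > {cutoff:g} => test negative",
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, dor=dor,
        prevalence=float(prev),
        fraction_negative=float(np.mean(~positive)),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        ci=ci,
    )


def youden_optimal_cutoff(scores, outcomes) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 over all
    midpoints between adjacent distinct scores (protective orientation:
    test positive iff score <= cutoff).  Ties go to the smaller cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("constant scores")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_case = float(np.sum(y == 1))
    n_ctrl = float(np.sum(y == 0))
    best = None
    for c in mids:
        sens = np.sum((s <= c) & (y == 1)) / n_case
        spec = np.sum((s > c) & (y == 0)) / n_ctrl
        J = sens + spec - 1.0
        if best is None or J > best[1] + 1e-12:
            best = (float(c), float(J))
    return best


# --------------------------------------------------- likelihood ratios

@dataclass
class LikelihoodRatioBands:
    edges: tuple[float, ...]
    labels: list[str]
    lr_by_band: dict[str, float]
    lr_by_band_cc: dict[str, float]  # +0.5 continuity-corrected
    counts: dict[str, tuple[int, int]]  # band -> (cases, non-cases)


def band_likelihood_ratios(scores, outcomes, edges) -> LikelihoodRatioBands:
    """LR(band) = P(band | case) / P(band | non-case) over the bands
    (-inf, e1], (e1, e2], ..., (ek, inf).  Empty-denominator bands
    report +inf; a continuity-corrected (+0.5 per cell) version is also
    emitted."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    edges = tuple(float(e) for e in edges)
    bounds = (-math.inf,) + edges + (math.inf,)
    n_case = float(np.sum(y == 1))
    n_ctrl = float(np.sum(y == 0))
    labels, lrs, lrs_cc, counts = [], {}, {}, {}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if math.isinf(lo):
            label = f"<= {hi:g}"
        elif math.isinf(hi):
            label = f"> {lo:g}"
        else:
            label = f"({lo:g}, {hi:g}]"
        in_band = (s > lo) & (s <= hi)
        a = float(np.sum(in_band & (y == 1)))
        b = float(np.sum(in_band & (y == 0)))
        if a + b == 0:
            raise ValueError(f"band {label} contains no observations")
        labels.append(label)
        counts[label] = (int(a), int(b))
        p_case = a / n_case
        p_ctrl = b / n_ctrl
        lrs[label] = p_case / p_ctrl if p_ctrl > 0 else math.inf
        lrs_cc[label] = ((a + 0.5) / (n_case + 0.5)) / ((b + 0.5) / (n_ctrl + 0.5))
    return LikelihoodRatioBands(edges=edges, labels=labels, lr_by_band=lrs,
                                lr_by_band_cc=lrs_cc, counts=counts)


def posterior_probability(prior: float, lr: float) -> float:
    """Bayes updating: posterior odds = prior odds x likelihood ratio."""
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    odds = prior / (1.0 - prior) * lr
    return odds / (1.0 + odds)


def pooled_prevalence(validation_sets: list) -> PooledEstimate:
    """Per-imputation outcome proportion with binomial variance, pooled
    by Rubin's rules."""
    props, variances = [], []
    for c in validation_sets:
        df = getattr(c, "df", c)
        y = df[OUTCOME_COL].to_numpy(dtype=float)
        if len(y) == 0:
            raise ValueError("empty validation set")
        p = float(np.mean(y))
        props.append(p)
        variances.append(p * (1 - p) / len(y))
    return rubin_pool(props, variances)


# ----------------------------------------------- complete-case arm

def complete_case_pipeline(
    cohort_with_missing,
    outcome: str = OUTCOME_COL,
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    cutoff: float = 1.0,
    min_rows: int = 50,
) -> dict:
    """Listwise deletion, then the standard development path on the
    retained rows: stepwise selection, a single-fit score table, and
    in-sample evaluation."""
    df = getattr(cohort_with_missing, "df", cohort_with_missing)
    schema = getattr(cohort_with_missing, "schema", None)
    if candidates is None:
        if schema is None:
            raise ValueError("candidates required without a schema")
        candidates = list(schema.item_names)
    analysis_cols = list(candidates) + ([outcome] if outcome in df else [])
    if schema is not None:
        analysis_cols += list(schema.scale_names)
    complete = df.dropna(subset=[c for c in analysis_cols if c in df])
    n_complete = len(complete)
    if n_complete < min_rows:
        raise ValueError(
            f"only {n_complete} complete rows (< {min_rows}); refusing to fit"
        )
    step = glm.stepwise_select(complete, outcome, candidates,
                               p_enter=p_enter, p_remove=p_remove)
    from .instrument import SelectionSummary

    summary = SelectionSummary(
        frequency={i: 1.0 for i in step.selected_items},
        threshold=0.0,
        included_items=set(step.selected_items),
    )
    table = build_score_table([complete], summary, outcome)
    scored = score_individuals(table, complete)
    y = complete[outcome].to_numpy(dtype=float)
    risk = -scored["score"].to_numpy()
    auc_est, auc_se = auc(risk, y)
    slope, slope_se = calibration_slope(risk, y)
    report = diagnostic_metrics(scored["score"].to_numpy(), y, cutoff=cutoff)
    return {
        "n_complete": n_complete,
        "stepwise": step,
        "score_table": table,
        "auc": (auc_est, auc_se),
        "calibration_slope": (slope, slope_se),
        "diagnostics": report,
    }
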