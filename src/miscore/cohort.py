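"""Synthetic cohort generation, outcome definition, and missingness.

The generator produces complete cohorts with the dependence structure
the downstream analysis assumes: a single standard-normal latent risk
factor per student drives both the informative questionnaire items
(multinomial logits shifted by the latent factor) and the three
continuous scale totals (linear loadings plus skewed independent
noise).  Maladjustment is defined by exceeding a gender-specific
percentile on any scale.  Missingness is imposed per variable under
MCAR, MAR (logistic in fully observed covariates) or MNAR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .schema import (
    DEMOGRAPHIC_COLS,
    GENDER_COL,
    ID_COL,
    LOCAL_COL,
    OUTCOME_COL,
    SCHOOL_COL,
    SCHOOL_FLAG_COL,
    CohortConfig,
    CohortSchema,
    MissingnessConfig,
)


@dataclass
class Cohort:
    """A cohort table plus its schema (item levels, outcome thresholds)."""

    df: pd.DataFrame
    schema: CohortSchema

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), replace(self.schema, thresholds=dict(self.schema.thresholds)))

    @property
    def item_names(self) -> tuple[str, ...]:
        return self.schema.item_names

    @property
    def scale_names(self) -> tuple[str, ...]:
        return self.schema.scale_names


def _standardized_lognormal(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Zero-mean unit-variance right-skewed noise (or N(0,1) at sigma=0)."""
    if sigma <= 0:
        return rng.standard_normal(n)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mu = np.exp(sigma**2 / 2)
    sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2))
    return (raw - mu) / sd


def _marginal_calibrated_logits(
    target_probs, effects, shift: float = 0.0, mix: float = 0.0,
    n_quad: int = 40, n_iter: int = 200,
) -> np.ndarray:
    """Level logits a such that E_u[softmax(a + effects*u)] equals the
    configured marginal level probabilities (the latent tilting
    otherwise shifts the marginals), where u is the mixture
    (1-mix) N(0,1) + mix N(shift,1).  Fixed-point iteration on
    Gauss-Hermite quadrature nodes."""
    target = np.asarray(target_probs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    all_nodes = np.concatenate([nodes, nodes + shift])
    all_weights = np.concatenate([(1.0 - mix) * weights, mix * weights])
    a = np.log(target)
    for _ in range(n_iter):
        logits = a[None, :] + np.outer(all_nodes, effects)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        marginal = all_weights @ p
        err = np.log(target) - np.log(marginal)
        a = a + err
        if np.max(np.abs(err)) < 1e-12:
            break
    return a - a.max()


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort (no missing cells) with outcomes.

    Deterministic given ``config.seed``.  The empirical outcome
    prevalence matches ``config.target_prevalence`` (threshold
    calibration on the complete data) or, if that is None, follows from
    ``config.outcome_percentile``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_students

    df = pd.DataFrame({ID_COL: np.arange(1, n + 1)})
    gender = np.where(rng.random(n) < config.male_prob, "male", "female")
    df[GENDER_COL] = pd.Categorical(gender, categories=["female", "male"])
    local = np.where(rng.random(n) < config.nonlocal_prob, "non_local", "local")
    df[LOCAL_COL] = pd.Categorical(local, categories=["local", "non_local"])

    # latent risk: standard normal, shifted for non-local students
    u = rng.standard_normal(n) + config.nonlocal_risk_shift * (local == "non_local")

    school_probs = np.full(config.n_schools, np.nan)
    flagged = set(config.nonparticipating_schools)
    for s in flagged:
        school_probs[s] = config.nonparticipating_school_prob
    rest = (1.0 - config.nonparticipating_school_prob * len(flagged)) / (
        config.n_schools - len(flagged)
    )
    school_probs[np.isnan(school_probs)] = rest
    school = rng.choice(config.n_schools, size=n, p=school_probs)
    df[SCHOOL_COL] = school
    df[SCHOOL_FLAG_COL] = pd.Categorical(
        np.where(np.isin(school, list(flagged)), "yes", "no"), categories=["no", "yes"]
    )

    for item in config.item_schemas:
        effects = np.array([item.effect(lv) for lv in item.levels])
        base = _marginal_calibrated_logits(
            item.probs(), effects,
            shift=config.nonlocal_risk_shift, mix=config.nonlocal_prob)
        logits = base[None, :] + np.outer(u, effects)  # (n, k)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        draws = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        df[item.name] = pd.Categorical(
            np.asarray(item.levels)[draws], categories=list(item.levels)
        )

    is_male = (df[GENDER_COL] == "male").to_numpy()
    for j, scale in enumerate(config.scale_names):
        rho = config.scale_loading[j]
        eps = _standardized_lognormal(rng, n, config.scale_skew)
        z = rho * u + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
        z = z + config.gender_shift[j] * is_male
        df[scale] = config.scale_mean[j] + config.scale_sd[j] * z

    schema = CohortSchema(
        item_schemas=tuple(config.item_schemas),
        scale_names=tuple(config.scale_names),
    )
    cohort = Cohort(df, schema)

    if config.target_prevalence is not None:
        pct = _calibrate_percentile(cohort, config.target_prevalence)
    else:
        pct = config.outcome_percentile
    return define_outcome(cohort, percentile=pct, by_gender=True)


def _prevalence_at(cohort: Cohort, percentile: float) -> float:
    trial = define_outcome(cohort, percentile=percentile, by_gender=True)
    return float(trial.df[OUTCOME_COL].mean())


def _calibrate_percentile(cohort: Cohort, target: float) -> float:
    """Find the common per-scale percentile whose any-scale exceedance
    rate equals the target prevalence (monotone decreasing in the
    percentile; bisection on the complete data)."""

    def f(p):
        return _prevalence_at(cohort, p) - target

    lo, hi = 50.0, 99.9
    if f(lo) < 0:  # even generous thresholds cannot reach the target
        return lo
    if f(hi) > 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-3))


def compute_thresholds(
    cohort: Cohort, percentile: float, by_gender: bool = True
) -> dict:
    """Empirical gender-specific percentile thresholds per scale,
    computed from the non-missing scale values."""
    df = cohort.df
    thresholds = {}
    for scale in cohort.scale_names:
        if by_gender:
            for g in df[GENDER_COL].cat.categories:
                vals = df.loc[df[GENDER_COL] == g, scale].dropna()
                thresholds[(scale, str(g))] = float(np.percentile(vals, percentile))
        else:
            vals = df[scale].dropna()
            thr = float(np.percentile(vals, percentile))
            for g in df[GENDER_COL].cat.categories:
                thresholds[(scale, str(g))] = thr
    return thresholds


def define_outcome(
    cohort: Cohort,
    percentile: float = 95.0,
    by_gender: bool = True,
    thresholds: dict | None = None,
) -> Cohort:
    """Classify maladjustment: above the gender-specific percentile on
    any one of the scales.

    A row with one observed scale above its threshold is a definite
    case even if the other scales are missing; a row is a definite
    non-case only when all scales are observed and none exceeds; any
    other row has a missing outcome.  Idempotent given thresholds.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    out = cohort.copy()
    df = out.df
    if thresholds is None:
        thresholds = compute_thresholds(out, percentile, by_gender)
    n = len(df)
    any_above = np.zeros(n, dtype=bool)
    all_observed_below = np.ones(n, dtype=bool)
    for scale in out.scale_names:
        vals = df[scale].to_numpy(dtype=float)
        thr = np.empty(n)
        for g in df[GENDER_COL].cat.categories:
            thr[(df[GENDER_COL] == g).to_numpy()] = thresholds[(scale, str(g))]
        observed = ~np.isnan(vals)
        above = observed & (vals > thr)
        any_above |= above
        all_observed_below &= observed & ~above
    outcome = np.full(n, np.nan)
    outcome[any_above] = 1.0
    outcome[~any_above & all_observed_below] = 0.0
    df[OUTCOME_COL] = outcome
    out.schema.thresholds = dict(thresholds)
    out.schema.outcome_percentile = float(percentile)
    return out


def _dependence_design(df: pd.DataFrame, terms) -> np.ndarray:
    """Numeric columns for the missingness logit: level indicators for
    (col, level) terms, standardized values for numeric terms."""
    cols = []
    for col, level, _w in terms:
        x = df[col]
        if level is not None:
            cols.append((x.astype(str) == level).to_numpy(dtype=float))
        else:
            v = x.to_numpy(dtype=float)
            v = np.where(np.isnan(v), np.nanmean(v), v)
            sd = v.std()
            cols.append((v - v.mean()) / (sd if sd > 0 else 1.0))
    return np.column_stack(cols)


def _calibrated_probs(eta: np.ndarray, rate: float) -> np.ndarray:
    """Per-row missingness probabilities sigmoid(a + eta) with the
    intercept a solved so the mean probability equals ``rate``."""
    if rate <= 0.0:
        return np.zeros_like(eta)
    if rate >= 1.0:
        return np.ones_like(eta)

    def f(a):
        return expit(a + eta).mean() - rate

    lo, hi = -30.0, 30.0
    a = brentq(f, lo, hi, xtol=1e-10)
    return expit(a + eta)


def apply_missingness(cohort: Cohort, mcfg: MissingnessConfig) -> Cohort:
    """Degrade a complete cohort per the missingness configuration and
    re-derive the outcome under the missing-aware case rule."""
    out = cohort.copy()
    df = out.df
    rng = np.random.default_rng(mcfg.seed)
    maskable = set(mcfg.per_variable_rate)
    if mcfg.mechanism == "MAR":
        for var, terms in mcfg.dependence.items():
            for col, _level, _w in terms:
                if col in maskable and mcfg.per_variable_rate.get(col, 0.0) > 0:
                    raise ValueError(
                        f"MAR missingness of {var!r} may not depend on "
                        f"{col!r}, which can itself be missing"
                    )
    # mask using pre-degradation values (MNAR depends on the value itself)
    complete = cohort.df
    for var in sorted(maskable):
        rate = float(mcfg.per_variable_rate[var])
        if rate == 0.0:
            continue
        n = len(df)
        terms = mcfg.dependence.get(var, ()) if mcfg.mechanism != "MCAR" else ()
        if terms:
            X = _dependence_design(complete, terms)
            w = np.array([t[2] for t in terms], dtype=float)
            eta = X @ w
        else:
            eta = np.zeros(n)
        p = _calibrated_probs(eta, rate)
        mask = rng.random(n) < p
        if isinstance(df[var].dtype, pd.CategoricalDtype):
            df.loc[mask, var] = np.nan
        else:
            col = df[var].to_numpy(dtype=float)
            col[mask] = np.nan
            df[var] = col
    if out.schema.thresholds:
        out = define_outcome(
            out,
            percentile=out.schema.outcome_percentile or 95.0,
            thresholds=out.schema.thresholds,
        )
    return out


def write_cohort(cohort: Cohort, csv_path, schema_path=None) -> None:
    """CSV with empty cells for missing values, plus a JSON sidecar
    holding the item schemas and thresholds."""
    cohort.df.to_csv(csv_path, index=False, na_rep="")
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            fh.write(cohort.schema.to_json())


def read_cohort(csv_path, schema_path) -> Cohort:
    with open(schema_path) as fh:
        schema = CohortSchema.from_json(fh.read())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for item in schema.item_schemas:
        df[item.name] = pd.Categorical(df[item.name], categories=list(item.levels))
    for col, cats in ((GENDER_COL, ["female", "male"]),
                      (LOCAL_COL, ["local", "non_local"]),
                      (SCHOOL_FLAG_COL, ["no", "yes"])):
        if col in df:
            df[col] = pd.Categorical(df[col], categories=cats)
    return Cohort(df, schema)
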