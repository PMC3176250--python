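"""Validation metrics: AUC against the pairwise oracle, calibration
slope identities, Rubin's rules hand calculations, diagnostic-test
identities on the published operating characteristics, Youden search
against exhaustive enumeration, band likelihood ratios, and Bayes
post-test updating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miscore import (auc, band_likelihood_ratios, calibration_slope,
                     diagnostic_metrics, fit_logistic, pooled_prevalence,
                     posterior_probability, rubin_pool,
                     youden_optimal_cutoff)


# ------------------------------------------------------------- AUC

def brute_force_auc(scores, outcomes):
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    cases, controls = s[y == 1], s[y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def test_auc_perfect_separation():
    est, _ = auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
    assert est == 1.0


def test_auc_all_ties():
    est, _ = auc([1.0] * 8, [1, 1, 0, 0, 1, 0, 0, 1])
    assert est == 0.5


def test_auc_worked_example():
    # 3 cases {0.9, 0.8, 0.4} vs 3 non-cases {0.7, 0.3, 0.2}: 8 of the 9
    # pairs are concordant
    est, _ = auc([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
    assert est == pytest.approx(8 / 9)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([1, 2, 3], [1, 1, 1])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_equals_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 200))
    scores = np.round(rng.standard_normal(n), 1)  # induce ties
    y = rng.integers(0, 2, n)
    if y.sum() in (0, n):
        y[0], y[1] = 0, 1
    est, se = auc(scores, y)
    assert est == pytest.approx(brute_force_auc(scores, y), abs=1e-12)
    assert se >= 0


def test_auc_delong_se_matches_direct_placement_computation():
    rng = np.random.default_rng(3)
    s = rng.standard_normal(100)
    y = (rng.random(100) < 0.4).astype(int)
    est, se = auc(s, y)
    cases, controls = s[y == 1], s[y == 0]
    v10 = np.array([np.mean((c > controls) + 0.5 * (c == controls))
                    for c in cases])
    v01 = np.array([np.mean((cases > k) + 0.5 * (cases == k))
                    for k in controls])
    direct = math.sqrt(v10.var(ddof=1) / len(cases)
                       + v01.var(ddof=1) / len(controls))
    assert se == pytest.approx(direct, abs=1e-12)


# --------------------------------------------- calibration slope

def test_calibration_slope_self_consistency():
    # regressing outcomes on a model's own in-sample linear predictor
    # returns slope 1, intercept 0 (MLE score equations)
    rng = np.random.default_rng(8)
    n = 500
    df = pd.DataFrame({"x": rng.standard_normal(n)})
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-(0.4 + 1.2 * df["x"])))).astype(float)
    fit = fit_logistic(df, "y", ["x"])
    eta = (fit.coefficients["(Intercept)"]
           + fit.coefficients["x"] * df["x"].to_numpy())
    slope, _ = calibration_slope(eta, df["y"])
    assert slope == pytest.approx(1.0, abs=1e-6)


def test_calibration_slope_under_true_model():
    rng = np.random.default_rng(9)
    n = 20_000
    eta = -1.0 + 1.5 * rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    slope, se = calibration_slope(eta, y)
    assert abs(slope - 1.0) < 3 * se


def test_calibration_slope_rescaling_identity():
    rng = np.random.default_rng(10)
    n = 20_000
    eta = -1.0 + 1.5 * rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    slope, se = calibration_slope(eta / 2.0, y)
    assert abs(slope - 2.0) < 3 * se


def test_calibration_slope_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        calibration_slope([1.0, 2.0], [1, 1])
    with pytest.raises(ValueError):
        calibration_slope([1.0] * 10, [0, 1] * 5)


# ------------------------------------------------- Rubin's rules

def test_rubin_pool_no_between_variance():
    p = rubin_pool([0.8, 0.8, 0.8], [0.01, 0.01, 0.01])
    assert p.Q_bar == pytest.approx(0.8)
    assert p.B == pytest.approx(0.0, abs=1e-15)
    assert p.T == pytest.approx(0.01)


def test_rubin_pool_hand_calculation():
    p = rubin_pool([1.0, 1.2, 1.4], [0.01, 0.01, 0.01])
    assert p.Q_bar == pytest.approx(1.2)
    assert p.W == pytest.approx(0.01)
    assert p.B == pytest.approx(0.04)
    assert p.T == pytest.approx(0.01 + (4 / 3) * 0.04)
    assert p.ci_low <= p.Q_bar <= p.ci_high


def test_rubin_pool_zero_within_variance():
    p = rubin_pool([0.0, 1.0], [0.0, 0.0])
    assert p.Q_bar == 0.5
    assert p.T == pytest.approx((1 + 1 / 2) * 0.5)  # (1+1/M)*B exactly


def test_rubin_pool_input_validation():
    with pytest.raises(ValueError):
        rubin_pool([1.0, 2.0], [0.1])
    with pytest.raises(ValueError):
        rubin_pool([1.0], [-0.1])


# --------------------------------------------- diagnostic metrics

def _protective_sample(rng, n=400, prev=0.25):
    y = (rng.random(n) < prev).astype(float)
    score = 2.0 - 1.5 * y + rng.standard_normal(n)
    return score, y


def test_everyone_positive_below_min_cutoff(rng):
    score, y = _protective_sample(rng)
    rep = diagnostic_metrics(score, y, cutoff=score.max() + 1)
    assert rep.sensitivity == 1.0
    assert rep.fraction_negative == 0.0


def test_lr_neg_from_printed_sens_spec():
    # (1 - 0.480) / 0.860 = 0.605 to 3 decimals
    assert round((1 - 0.480) / 0.860, 3) == 0.605


def test_dor_identity_from_printed_lrs():
    # LR+ / LR- = 3.414 / 0.605 = 5.64 to 2 decimals
    assert round(3.414 / 0.605, 2) == 5.64


def test_diagnostic_identities_exact(rng):
    score, y = _protective_sample(rng)
    rep = diagnostic_metrics(score, y, cutoff=1.0)
    assert rep.lr_pos == pytest.approx(
        rep.sensitivity / (1 - rep.specificity), abs=1e-12)
    assert rep.lr_neg == pytest.approx(
        (1 - rep.sensitivity) / rep.specificity, abs=1e-12)
    assert rep.dor == pytest.approx(rep.lr_pos / rep.lr_neg, abs=1e-9)
    assert rep.lr_pos * (1 - rep.specificity) == pytest.approx(
        rep.sensitivity, abs=1e-12)


def test_ppv_npv_bayes_agrees_with_table(rng):
    score, y = _protective_sample(rng)
    direct = diagnostic_metrics(score, y, cutoff=1.0)
    bayes = diagnostic_metrics(score, y, cutoff=1.0,
                               prevalence=float(np.mean(y)))
    assert bayes.ppv == pytest.approx(direct.ppv, abs=1e-12)
    assert bayes.npv == pytest.approx(direct.npv, abs=1e-12)


def test_negative_rule_orientation(rng):
    # high protective score => test negative
    score = np.array([3.0, 3.0, -2.0, -2.0])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    rep = diagnostic_metrics(score, y, cutoff=1.0)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.fraction_negative == 0.5


# --------------------------------------------------- Youden index

def brute_force_youden(scores, outcomes):
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    distinct = np.unique(s)
    best = None
    for c in (distinct[:-1] + distinct[1:]) / 2:
        sens = np.mean(s[y == 1] <= c)
        spec = np.mean(s[y == 0] > c)
        J = sens + spec - 1
        if best is None or J > best[1] + 1e-12:
            best = (c, J)
    return best


def test_youden_perfectly_separated():
    cutoff, J = youden_optimal_cutoff([0, 1, 5, 6], [1, 1, 0, 0])
    assert J == pytest.approx(1.0)
    # the (smallest) midpoint between the separated groups
    assert cutoff == pytest.approx(3.0)


def test_youden_toy_overlap_matches_exhaustive():
    scores = [0.1, 0.4, 0.6, 0.9, 1.1, 1.4, 1.6, 2.0]
    y = [1, 1, 1, 0, 1, 0, 0, 0]
    assert youden_optimal_cutoff(scores, y) == pytest.approx(
        brute_force_youden(scores, y))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_youden_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 500))
    s = np.round(rng.standard_normal(n) - rng.integers(0, 2, n), 1)
    y = rng.integers(0, 2, n)
    if y.sum() in (0, n):
        y[:2] = [0, 1]
    c, J = youden_optimal_cutoff(s, y)
    bc, bJ = brute_force_youden(s, y)
    assert J == pytest.approx(bJ, abs=1e-12)
    assert c == pytest.approx(bc, abs=1e-12)


def test_youden_invariant_under_monotone_transform(rng):
    s, y = _protective_sample(rng)
    _, J1 = youden_optimal_cutoff(s, y)
    _, J2 = youden_optimal_cutoff(np.exp(0.5 * s), y)
    assert J1 == pytest.approx(J2, abs=1e-12)


# --------------------------------------- band likelihood ratios

def test_single_band_lr_is_one(rng):
    s, y = _protective_sample(rng)
    bands = band_likelihood_ratios(s, y, edges=[])
    assert list(bands.lr_by_band.values()) == [1.0]


def test_band_lr_direct_ratio():
    # 20/100 cases vs 10/400 non-cases in the low band: LR = 8
    s = np.r_[np.zeros(20), np.ones(80), np.zeros(10), np.ones(390)]
    y = np.r_[np.ones(100), np.zeros(400)]
    bands = band_likelihood_ratios(s, y, edges=[0.5])
    assert bands.lr_by_band["<= 0.5"] == pytest.approx(8.0)


def test_band_lrs_decrease_in_protective_score(ci_cohort):
    # under the generative model, LRs fall monotonically across
    # increasing protective-score bands
    from miscore import build_score_table, score_individuals, \
        selection_frequency, stepwise_select

    res = stepwise_select(ci_cohort, "outcome", list(ci_cohort.item_names))
    table = build_score_table([ci_cohort],
                              selection_frequency([res], 0.5), "outcome")
    s = score_individuals(table, ci_cohort)["score"].to_numpy()
    y = ci_cohort.df["outcome"].to_numpy()
    qs = np.unique(np.quantile(s, [1 / 3, 2 / 3]))
    bands = band_likelihood_ratios(s, y, edges=qs[qs < s.max()])
    lrs = list(bands.lr_by_band.values())
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


def test_empty_band_reported():
    with pytest.raises(ValueError, match="contains no observations"):
        band_likelihood_ratios([1.0, 2.0], [0, 1], edges=[5.0])


# ------------------------------------------------ Bayes updating

def test_posterior_probability_uninformative():
    assert posterior_probability(0.5, 1.0) == 0.5


def test_posterior_probability_printed_examples():
    lrs = (6.85, 2.46, 1.16, 0.83, 0.48, 0.22, 0.11)
    expected = (0.87, 0.71, 0.54, 0.45, 0.32, 0.18, 0.10)
    for lr, want in zip(lrs, expected):
        assert round(posterior_probability(0.5, lr), 2) == want


def test_posterior_probability_validation():
    with pytest.raises(ValueError):
        posterior_probability(0.0, 2.0)
    with pytest.raises(ValueError):
        posterior_probability(0.5, -1.0)


# --------------------------------------------- pooled prevalence

def test_pooled_prevalence_identical_sets(small_cohort):
    pooled = pooled_prevalence([small_cohort] * 3)
    assert pooled.B == pytest.approx(0.0, abs=1e-15)
    assert pooled.Q_bar == pytest.approx(small_cohort.df["outcome"].mean())


def test_pooled_prevalence_hand_mean():
    df1 = pd.DataFrame({"outcome": [1.0] * 18 + [0.0] * 82})
    df2 = pd.DataFrame({"outcome": [1.0] * 20 + [0.0] * 80})
    pooled = pooled_prevalence([df1, df2])
    assert pooled.Q_bar == pytest.approx(0.19)
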