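"""Synthetic cohort generator: determinism, marginal structure, the
any-scale outcome rule, and configurable missingness."""

import numpy as np
import pandas as pd
import pytest

from miscore import (CohortConfig, ItemSchema, MissingnessConfig,
                     apply_missingness, define_outcome, generate_cohort)
from miscore.cohort import compute_thresholds, read_cohort, write_cohort
from miscore.schema import (GENDER_COL, LOCAL_COL, OUTCOME_COL,
                            core_item_schemas, default_missingness)

from conftest import make_scale_cohort


def test_seed_determinism(small_schemas):
    cfg = CohortConfig(n_students=300, item_schemas=small_schemas, seed=7)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.df, b.df)
    cfg2 = CohortConfig(n_students=300, item_schemas=small_schemas, seed=8)
    c = generate_cohort(cfg2)
    assert not a.df.equals(c.df)


def test_invalid_configs(small_schemas):
    with pytest.raises(ValueError):
        CohortConfig(n_students=0, item_schemas=small_schemas)
    with pytest.raises(ValueError):
        CohortConfig(n_students=10, item_schemas=small_schemas,
                     outcome_percentile=100.0)
    with pytest.raises(ValueError):
        ItemSchema("bad", ("only",), "only")


def test_item_marginals_match_level_probabilities():
    # a family-attitude summary item with an unfavorable level configured
    # at 4.8%: at n=2919 the observed proportion sits within 3 binomial
    # SEs despite the latent-risk tilting
    family = ItemSchema(
        "family_summary", ("favorable", "neutral", "unfavorable"), "favorable",
        informative=True,
        effect_by_level={"favorable": 0.0, "neutral": 0.5, "unfavorable": 1.0},
        base_probs=(0.851, 0.101, 0.048),
    )
    items = core_item_schemas() + [family]
    cfg = CohortConfig(n_students=2919, item_schemas=items, seed=123)
    cohort = generate_cohort(cfg)
    for level, p in zip(family.levels, family.probs()):
        obs = float((cohort.df["family_summary"] == level).mean())
        se = np.sqrt(p * (1 - p) / cfg.n_students)
        assert abs(obs - p) < 3 * se, level


def test_prevalence_calibrated_to_target(small_schemas):
    cfg = CohortConfig(n_students=50_000, item_schemas=small_schemas,
                       target_prevalence=0.184, seed=5)
    cohort = generate_cohort(cfg)
    prev = float(cohort.df[OUTCOME_COL].mean())
    assert 0.174 <= prev <= 0.194


def test_prevalence_monotone_in_percentile(small_cohort):
    prevs = [
        define_outcome(small_cohort, percentile=p).df[OUTCOME_COL].mean()
        for p in (80.0, 90.0, 95.0, 99.0)
    ]
    assert all(a >= b for a, b in zip(prevs, prevs[1:]))


def test_outcome_rule_exact_counts():
    # thresholds fixed so exactly 2 of 20 rows exceed on one scale
    vals = np.zeros(20)
    vals[[3, 11]] = 100.0
    cohort = make_scale_cohort({"A": vals, "B": np.zeros(20), "C": np.zeros(20)})
    thr = {("A", "female"): 50.0, ("A", "male"): 50.0,
           ("B", "female"): 50.0, ("B", "male"): 50.0,
           ("C", "female"): 50.0, ("C", "male"): 50.0}
    out = define_outcome(cohort, thresholds=thr)
    y = out.df[OUTCOME_COL]
    assert int(y.sum()) == 2 and int((y == 0).sum()) == 18


def test_outcome_rule_truth_table_with_missing_scales():
    a = np.array([100.0, 10.0, np.nan])
    b = np.array([np.nan, np.nan, 10.0])
    c = np.array([np.nan, np.nan, 10.0])
    cohort = make_scale_cohort({"A": a, "B": b, "C": c})
    thr = {(s, g): 50.0 for s in "ABC" for g in ("female", "male")}
    out = define_outcome(cohort, thresholds=thr)
    y = out.df[OUTCOME_COL]
    # one observed scale above threshold => definite case
    assert y.iloc[0] == 1.0
    # only one scale observed and below => undetermined
    assert np.isnan(y.iloc[1])
    # two observed below, one missing => still undetermined
    assert np.isnan(y.iloc[2])


def test_outcome_all_below_is_all_zero():
    cohort = make_scale_cohort({"A": np.zeros(5), "B": np.zeros(5),
                                "C": np.zeros(5)})
    thr = {(s, g): 50.0 for s in "ABC" for g in ("female", "male")}
    out = define_outcome(cohort, thresholds=thr)
    assert (out.df[OUTCOME_COL] == 0.0).all()


def test_outcome_idempotent(small_cohort):
    once = define_outcome(small_cohort, percentile=95.0)
    twice = define_outcome(once, percentile=95.0,
                           thresholds=once.schema.thresholds)
    pd.testing.assert_series_equal(once.df[OUTCOME_COL], twice.df[OUTCOME_COL])


def test_gender_specific_thresholds(small_cohort):
    thr = compute_thresholds(small_cohort, 95.0, by_gender=True)
    for scale in small_cohort.scale_names:
        assert thr[(scale, "female")] != thr[(scale, "male")]


def test_missingness_zero_rates_is_identity(small_cohort):
    mcfg = MissingnessConfig(per_variable_rate={"strong": 0.0}, mechanism="MCAR")
    out = apply_missingness(small_cohort, mcfg)
    pd.testing.assert_frame_equal(out.df, small_cohort.df)


def test_missingness_rates_and_outcome_missing_fraction():
    cfg = CohortConfig(n_students=2919, seed=31)  # full ~80-item schema
    cohort = generate_cohort(cfg)
    mcfg = default_missingness(cfg, seed=32)
    out = apply_missingness(cohort, mcfg)
    n = len(out.df)
    for scale, rate in zip(cohort.scale_names, (0.593, 0.271, 0.277)):
        obs = out.df[scale].isna().mean()
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(obs - rate) < 3 * se, scale
    item_rates = np.array([out.df[v].isna().mean() for v in cohort.item_names])
    assert 0.01 < np.median(item_rates) < 0.03
    assert item_rates.max() < 0.15
    # ~70% of rows lack a case definition once the scales are degraded
    assert 0.63 < out.df[OUTCOME_COL].isna().mean() < 0.77


def test_mar_missingness_depends_on_covariate(small_cohort):
    mcfg = MissingnessConfig(
        per_variable_rate={"strong": 0.3},
        mechanism="MAR",
        dependence={"strong": [(LOCAL_COL, "non_local", 1.5)]},
        seed=3,
    )
    out = apply_missingness(small_cohort, mcfg)
    miss = out.df["strong"].isna()
    nonlocal_rate = miss[out.df[LOCAL_COL] == "non_local"].mean()
    local_rate = miss[out.df[LOCAL_COL] == "local"].mean()
    assert nonlocal_rate > local_rate
    # overall rate still calibrated
    assert abs(miss.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(out.df))


def test_mar_rejects_missingness_dependent_covariate(small_cohort):
    mcfg = MissingnessConfig(
        per_variable_rate={"strong": 0.3, "weakcat": 0.2},
        mechanism="MAR",
        dependence={"strong": [("weakcat", "y", 1.0)]},
    )
    with pytest.raises(ValueError, match="can itself be missing"):
        apply_missingness(small_cohort, mcfg)


def test_mcar_observed_means_unbiased(small_schemas):
    # repeated simulation: observed-data scale means track complete means
    diffs = []
    for seed in range(30):
        cfg = CohortConfig(n_students=10_000, item_schemas=small_schemas,
                           seed=seed)
        cohort = generate_cohort(cfg)
        mcfg = MissingnessConfig(per_variable_rate={"CBCL": 0.4},
                                 mechanism="MCAR", seed=seed + 100)
        out = apply_missingness(cohort, mcfg)
        diffs.append(out.df["CBCL"].mean() - cohort.df["CBCL"].mean())
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 0.05


def test_csv_roundtrip(tmp_path, small_cohort):
    mcfg = MissingnessConfig(per_variable_rate={"strong": 0.2, "CBCL": 0.3},
                             mechanism="MCAR", seed=9)
    degraded = apply_missingness(small_cohort, mcfg)
    csv, sidecar = tmp_path / "c.csv", tmp_path / "c.json"
    write_cohort(degraded, csv, sidecar)
    back = read_cohort(csv, sidecar)
    assert back.df["strong"].isna().sum() == degraded.df["strong"].isna().sum()
    np.testing.assert_allclose(
        back.df["CBCL"].to_numpy(), degraded.df["CBCL"].to_numpy(),
        equal_nan=True)
    # re-serialization is byte-identical
    csv2 = tmp_path / "c2.csv"
    write_cohort(back, csv2)
    assert csv.read_bytes() == csv2.read_bytes()
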