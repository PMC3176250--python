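"""End-to-end orchestration: simulate -> degrade -> impute -> select ->
build score table -> validate, plus the listwise-deletion comparison.

A single master seed deterministically derives the per-stage seeds
(fixed counter scheme, recorded in the manifest), so identical
configurations produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .cohort import Cohort, apply_missingness, generate_cohort, write_cohort
from .glm import stepwise_select
from .instrument import (ScoreTable, build_score_table, score_individuals,
                         selection_frequency)
from .mice import ImputationSpec, impute
from .reference import PUBLISHED_BAND_EDGES
from .schema import (OUTCOME_COL, CohortConfig, MissingnessConfig,
                     ci_item_schemas, default_missingness)

log = logging.getLogger("miscore")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    missingness: MissingnessConfig | None = None  # None -> study-rate default
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    p_enter: float = 0.05
    p_remove: float = 0.05
    frequency_threshold: float = 0.70
    cutoffs: tuple[float, ...] = (1.0, 1.6, 2.0)
    band_edges: tuple[float, ...] = PUBLISHED_BAND_EDGES
    prior_grid: tuple[float, ...] = (0.1, 0.184, 0.3, 0.5)
    seed: int = 0


def profile_config(name: str, seed: int = 0) -> RunConfig:
    """Shipped profiles: 'paper' (n=2919, ~80 items, M=15 split 10/5,
    10 cycles) and 'ci' (n=1000, 8 items, M=6 split 4/2, 4 cycles)."""
    if name == "paper":
        cohort = CohortConfig(seed=seed)
        imputation = ImputationSpec(M=15, n_train=10, n_validation=5, n_cycles=10)
    elif name == "ci":
        cohort = CohortConfig(n_students=1000, item_schemas=ci_item_schemas(),
                              seed=seed)
        imputation = ImputationSpec(M=6, n_train=4, n_validation=2, n_cycles=4)
    elif name == "contrast":
        return contrast_config(seed)
    else:
        raise ValueError(f"unknown profile {name!r}")
    return RunConfig(cohort=cohort, imputation=imputation, seed=seed)


def contrast_config(seed: int = 0) -> RunConfig:
    """MI-versus-listwise-deletion demonstration conditions: many noise
    candidates and heavy MAR missingness tied to an outcome-related
    covariate (residence status), leaving a small biased complete-case
    sample on which stepwise selection overfits."""
    from .schema import GENDER_COL, LOCAL_COL, noise_item_schemas

    items = ci_item_schemas() + noise_item_schemas(10)
    cohort = CohortConfig(n_students=2000, item_schemas=items, seed=seed)
    names = [s.name for s in items]
    rates = {n: 0.08 for n in names}
    rates.update(dict(zip(cohort.scale_names, (0.55, 0.30, 0.30))))
    dep = {
        n: [(LOCAL_COL, "non_local", 1.5), (GENDER_COL, "male", 0.5)]
        for n in names + list(cohort.scale_names)
    }
    return RunConfig(
        cohort=cohort,
        missingness=MissingnessConfig(per_variable_rate=rates, mechanism="MAR",
                                      dependence=dep),
        imputation=ImputationSpec(M=6, n_train=4, n_validation=2, n_cycles=4),
        seed=seed,
    )


def stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(4)
    names = ("cohort", "missingness", "imputation", "spare")
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


def config_hash(config: RunConfig) -> str:
    text = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def develop_instrument(iset, config: RunConfig):
    """Stepwise per training imputation, selection-frequency rule, then
    the coefficient-averaged score table."""
    results = []
    candidates = list(iset.completed[0].item_names)
    for i, cohort in enumerate(iset.training()):
        t0 = time.perf_counter()
        res = stepwise_select(cohort, OUTCOME_COL, candidates,
                              p_enter=config.p_enter, p_remove=config.p_remove)
        log.info("stepwise train=%d selected=%s (%.2fs)", i,
                 sorted(res.selected_items), time.perf_counter() - t0)
        results.append(res)
    summary = selection_frequency(results, threshold=config.frequency_threshold)
    table = build_score_table(iset.training(), summary, OUTCOME_COL)
    return results, summary, table


def evaluate_instrument(
    table: ScoreTable,
    validation_sets: list[Cohort],
    cutoffs=(1.0,),
    band_edges=PUBLISHED_BAND_EDGES,
    prior_grid=(0.5,),
) -> dict:
    """Pooled validation: AUC and calibration slope Rubin-pooled across
    the validation imputations (full-precision weights); dichotomized
    diagnostics and score-band likelihood ratios on the rounded
    published-style scores."""
    per_imp = []
    all_scores, all_outcomes = [], []
    for i, cohort in enumerate(validation_sets):
        y = cohort.df[OUTCOME_COL].to_numpy(dtype=float)
        precise = score_individuals(table, cohort, precise=True)["score"].to_numpy()
        rounded = score_individuals(table, cohort, precise=False)["score"].to_numpy()
        risk = -precise
        a, a_se = ev.auc(risk, y)
        s, s_se = ev.calibration_slope(risk, y)
        per_imp.append({"imputation": i, "auc": a, "auc_se": a_se,
                        "slope": s, "slope_se": s_se,
                        "prevalence": float(np.mean(y))})
        all_scores.append(rounded)
        all_outcomes.append(y)
    pooled_auc = ev.rubin_pool([r["auc"] for r in per_imp],
                               [r["auc_se"] ** 2 for r in per_imp])
    pooled_slope = ev.rubin_pool([r["slope"] for r in per_imp],
                                 [r["slope_se"] ** 2 for r in per_imp])
    pooled_prev = ev.pooled_prevalence(validation_sets)
    scores = np.concatenate(all_scores)
    outcomes = np.concatenate(all_outcomes)
    youden_cut, youden_j = ev.youden_optimal_cutoff(scores, outcomes)
    diagnostics = {}
    for label, c in [(f"{c:g}", c) for c in cutoffs] + [("youden", youden_cut)]:
        try:
            diagnostics[label] = ev.diagnostic_metrics(scores, outcomes, c).to_json_dict()
        except ValueError as exc:
            diagnostics[label] = {"error": str(exc)}
    # keep only edges that actually split the observed score range;
    # fall back to score quartiles when none do (short instruments)
    usable = [e for e in band_edges if scores.min() <= e < scores.max()]
    if not usable:
        qs = np.unique(np.quantile(scores, (0.25, 0.5, 0.75)))
        usable = [q for q in qs if q < scores.max()]
    bands = ev.band_likelihood_ratios(scores, outcomes, usable)
    posterior_table = {
        f"{p:g}": {label: ev.posterior_probability(p, lr) if np.isfinite(lr) else 1.0
                   for label, lr in bands.lr_by_band.items()}
        for p in prior_grid
    }
    return {
        "per_imputation": per_imp,
        "pooled": {
            "auc": dataclasses.asdict(pooled_auc),
            "calibration_slope": dataclasses.asdict(pooled_slope),
            "prevalence": dataclasses.asdict(pooled_prev),
        },
        "diagnostics_by_cutoff": diagnostics,
        "youden": {"cutoff": youden_cut, "J": youden_j},
        "band_likelihood_ratios": {
            "edges": list(bands.edges),
            "lr": bands.lr_by_band,
            "lr_continuity_corrected": bands.lr_by_band_cc,
            "counts": {k: list(v) for k, v in bands.counts.items()},
        },
        "posterior_probability": posterior_table,
    }


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute every stage and write all artifacts plus a manifest of
    {config hash, stage seeds, file checksums}."""
    seeds = stage_seeds(config.seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    log.info("simulate n=%d seed=%d", cohort_cfg.n_students, seeds["cohort"])
    complete = generate_cohort(cohort_cfg)
    mcfg = config.missingness
    if mcfg is None:
        mcfg = default_missingness(cohort_cfg)
    mcfg = dataclasses.replace(mcfg, seed=seeds["missingness"])
    degraded = apply_missingness(complete, mcfg)
    spec = dataclasses.replace(config.imputation, seed=seeds["imputation"])
    log.info("impute M=%d cycles=%d", spec.M, spec.n_cycles)
    iset = impute(degraded, spec)
    results, summary, table = develop_instrument(iset, config)
    report = evaluate_instrument(
        table, iset.validation(), cutoffs=config.cutoffs,
        band_edges=config.band_edges, prior_grid=config.prior_grid,
    )
    manifest = {
        "config_hash": config_hash(config),
        "stage_seeds": seeds,
        "selection_frequency": summary.frequency,
        "included_items": sorted(summary.included_items),
        "n_students": cohort_cfg.n_students,
        "M": spec.M,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(complete, out / "cohort_complete.csv", out / "schema.json")
        write_cohort(degraded, out / "cohort_degraded.csv")
        for i, c in enumerate(iset.completed):
            c.df.to_csv(out / f"imputed_{i:02d}.csv", index=False, na_rep="")
        (out / "score_table.json").write_text(table.to_json())
        (out / "score_table.md").write_text(table.to_markdown() + "\n")
        (out / "evaluation.json").write_text(json.dumps(report, indent=1, default=float))
        pd.DataFrame(report["per_imputation"]).to_csv(
            out / "per_imputation_estimates.csv", index=False)
        files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
        manifest["checksums"] = {p.name: _checksum(p) for p in files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["score_table"] = table
    manifest["evaluation"] = report
    manifest["stepwise_results"] = results
    return manifest


def compare_mi_vs_complete_case(config: RunConfig, output_dir=None) -> dict:
    """Both arms on the same degraded cohort.  The listwise-deletion
    arm's score is also evaluated on the MI validation imputations so
    the two calibration slopes are comparable."""
    seeds = stage_seeds(config.seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    complete = generate_cohort(cohort_cfg)
    mcfg = config.missingness
    if mcfg is None:
        mcfg = default_missingness(cohort_cfg)
    mcfg = dataclasses.replace(mcfg, seed=seeds["missingness"])
    degraded = apply_missingness(complete, mcfg)
    spec = dataclasses.replace(config.imputation, seed=seeds["imputation"])
    iset = impute(degraded, spec)
    _, summary, mi_table = develop_instrument(iset, config)
    mi_report = evaluate_instrument(mi_table, iset.validation(),
                                    cutoffs=config.cutoffs,
                                    band_edges=config.band_edges)
    cc = ev.complete_case_pipeline(degraded, candidates=list(degraded.item_names),
                                   p_enter=config.p_enter, p_remove=config.p_remove)
    # CC-arm score applied to the MI validation sets
    cc_auc, cc_slope = [], []
    for cohort in iset.validation():
        y = cohort.df[OUTCOME_COL].to_numpy(dtype=float)
        risk = -score_individuals(cc["score_table"], cohort)["score"].to_numpy()
        a, a_se = ev.auc(risk, y)
        s, s_se = ev.calibration_slope(risk, y)
        cc_auc.append((a, a_se**2))
        cc_slope.append((s, s_se**2))
    cc_auc_pooled = ev.rubin_pool([x[0] for x in cc_auc], [x[1] for x in cc_auc])
    cc_slope_pooled = ev.rubin_pool([x[0] for x in cc_slope], [x[1] for x in cc_slope])
    mi_items = set(summary.included_items)
    cc_items = set(cc["stepwise"].selected_items)
    report = {
        "n_total": cohort_cfg.n_students,
        "n_complete_case": cc["n_complete"],
        "mi_items": sorted(mi_items),
        "cc_items": sorted(cc_items),
        "overlap_count": len(mi_items & cc_items),
        "mi": {
            "auc": mi_report["pooled"]["auc"]["Q_bar"],
            "calibration_slope": mi_report["pooled"]["calibration_slope"]["Q_bar"],
            "slope_ci": (mi_report["pooled"]["calibration_slope"]["ci_low"],
                         mi_report["pooled"]["calibration_slope"]["ci_high"]),
        },
        "complete_case": {
            "auc": cc_auc_pooled.Q_bar,
            "calibration_slope": cc_slope_pooled.Q_bar,
            "slope_ci": (cc_slope_pooled.ci_low, cc_slope_pooled.ci_high),
        },
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison.json").write_text(json.dumps(report, indent=1, default=float))
    return report
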