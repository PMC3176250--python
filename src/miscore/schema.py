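"""Cohort schemas and configuration objects.

A cohort is a rectangular table, one row per student: categorical
questionnaire items, three continuous psychometric scale totals
(CBCL/YSR/MHI analogues), demographics, and a binary maladjustment
outcome derived from the scales.  The schema objects here describe the
item level structures, how items load on a single latent risk factor,
and how missingness is to be imposed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

ID_COL = "student_id"
GENDER_COL = "gender"
SCHOOL_COL = "school"
LOCAL_COL = "local"
SCHOOL_FLAG_COL = "school_nonparticipating"
OUTCOME_COL = "outcome"

#: demographic columns that are always fully observed
DEMOGRAPHIC_COLS = (GENDER_COL, SCHOOL_COL, LOCAL_COL, SCHOOL_FLAG_COL)


@dataclass(frozen=True)
class ItemSchema:
    """One categorical questionnaire item.

    ``levels`` are ordered with the reference level explicit;
    ``effect_by_level`` gives each level's log-odds contribution to the
    latent-risk loading (risk-oriented: positive = more likely among
    high-risk students).  The reference level's effect is 0 by
    construction.  ``base_probs`` are the marginal level probabilities
    for a student at average risk.
    """

    name: str
    levels: tuple[str, ...]
    reference_level: str
    informative: bool = False
    effect_by_level: Mapping[str, float] = field(default_factory=dict)
    base_probs: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError(f"item {self.name!r} needs >=2 levels")
        if self.reference_level not in self.levels:
            raise ValueError(
                f"item {self.name!r}: reference {self.reference_level!r} not in levels"
            )
        if self.effect_by_level.get(self.reference_level, 0.0) != 0.0:
            raise ValueError(
                f"item {self.name!r}: reference level must have zero effect"
            )
        if self.base_probs is not None and len(self.base_probs) != len(self.levels):
            raise ValueError(f"item {self.name!r}: base_probs length mismatch")

    def effect(self, level: str) -> float:
        return float(self.effect_by_level.get(level, 0.0))

    def probs(self) -> tuple[float, ...]:
        if self.base_probs is None:
            k = len(self.levels)
            return tuple(1.0 / k for _ in self.levels)
        total = float(sum(self.base_probs))
        return tuple(p / total for p in self.base_probs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["effect_by_level"] = dict(self.effect_by_level)
        if self.base_probs is not None:
            d["base_probs"] = list(self.base_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ItemSchema":
        return cls(
            name=d["name"],
            levels=tuple(d["levels"]),
            reference_level=d["reference_level"],
            informative=bool(d.get("informative", False)),
            effect_by_level=dict(d.get("effect_by_level", {})),
            base_probs=tuple(d["base_probs"]) if d.get("base_probs") else None,
        )


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``scale_loading`` is each scale total's correlation with the single
    standard-normal latent risk factor.  The outcome is defined as
    exceeding a gender-specific percentile on any of the three scales;
    when ``target_prevalence`` is set, the percentile is calibrated on
    the generated complete data so the overall outcome rate matches it
    (mirroring scale thresholds that come from external norms rather
    than the sample itself); otherwise ``outcome_percentile`` is used
    directly.
    """

    n_students: int = 2919
    item_schemas: Sequence[ItemSchema] = field(default_factory=lambda: default_item_schemas())
    scale_names: tuple[str, ...] = ("CBCL", "YSR", "MHI")
    scale_loading: tuple[float, ...] = (0.7, 0.7, 0.7)
    scale_mean: tuple[float, ...] = (13.6, 24.4, 173.5)
    scale_sd: tuple[float, ...] = (14.1, 19.7, 29.9)
    #: additive mean shift (in SD units) for boys on each scale
    gender_shift: tuple[float, ...] = (0.2, 0.2, 0.0)
    #: lognormal shape of the scale noise (0 = gaussian noise)
    scale_skew: float = 0.6
    outcome_percentile: float = 95.0
    target_prevalence: float | None = 0.184
    male_prob: float = 0.533
    nonlocal_prob: float = 0.20
    #: mean latent-risk shift for non-local (migrant) students; makes the
    #: default MAR mechanism (missingness higher among non-locals)
    #: outcome-relevant, so listwise deletion is a biased analysis
    nonlocal_risk_shift: float = 0.4
    n_schools: int = 21
    #: schools whose parents were never given the CBCL (structural missingness)
    nonparticipating_schools: tuple[int, ...] = (0, 1)
    #: sampling probability of each non-participating school
    nonparticipating_school_prob: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.n_students <= 0:
            raise ValueError("n_students must be positive")
        if not 0.0 < self.outcome_percentile < 100.0:
            raise ValueError("outcome_percentile must be in (0, 100)")
        if self.target_prevalence is not None and not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if len(self.scale_names) != len(self.scale_loading):
            raise ValueError("scale_loading length must match scale_names")
        self.item_schemas = tuple(self.item_schemas)

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.item_schemas)


@dataclass
class MissingnessConfig:
    """How to degrade a complete cohort.

    ``dependence`` maps a variable to the covariates driving its
    missingness logit: triples ``(covariate, level, weight)`` where
    ``level`` names a category (the indicator of that category is used)
    or is None for a standardized numeric covariate.  Under MAR every
    dependence covariate must itself be fully observed.
    """

    per_variable_rate: Mapping[str, float] = field(default_factory=dict)
    mechanism: str = "MAR"
    dependence: Mapping[str, Sequence[tuple[str, str | None, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for var, rate in self.per_variable_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {var!r} outside [0, 1]")


@dataclass
class CohortSchema:
    """Metadata travelling with a cohort table: item schemas, scale
    names, and the gender-specific outcome thresholds once defined."""

    item_schemas: tuple[ItemSchema, ...]
    scale_names: tuple[str, ...]
    #: {(scale, gender_level): threshold}; populated by define_outcome
    thresholds: dict = field(default_factory=dict)
    outcome_percentile: float | None = None

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.item_schemas)

    def item(self, name: str) -> ItemSchema:
        for s in self.item_schemas:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "item_schemas": [s.to_dict() for s in self.item_schemas],
                "scale_names": list(self.scale_names),
                "thresholds": {f"{k[0]}|{k[1]}": v for k, v in self.thresholds.items()},
                "outcome_percentile": self.outcome_percentile,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSchema":
        d = json.loads(text)
        return cls(
            item_schemas=tuple(ItemSchema.from_dict(s) for s in d["item_schemas"]),
            scale_names=tuple(d["scale_names"]),
            thresholds={
                (k.split("|")[0], k.split("|")[1]): v
                for k, v in d.get("thresholds", {}).items()
            },
            outcome_percentile=d.get("outcome_percentile"),
        )


def _risk_effects(levels: Sequence[str], protective_weights: Sequence[float]) -> dict:
    """Convert protective-positive per-level weights into risk-oriented
    generator effects (sign flip; reference stays 0)."""
    return {lv: -w for lv, w in zip(levels, protective_weights)}


def core_item_schemas() -> list[ItemSchema]:
    """The ten informative items of the published screening instrument,
    with its printed level structures (reference level last as printed)
    and risk effects proportional to the published protective weights."""
    specs = [
        ("gender_item", ("female", "male"), "female", (0.0, 0.60), (0.467, 0.533)),
        ("family_feeling", ("4_to_7", "1", "2", "3"), "4_to_7",
         (0.0, 0.96, 0.94, 0.76), (0.15, 0.40, 0.28, 0.17)),
        ("ridiculed", ("never", "rarely", "sometimes", "regularly"), "never",
         (0.0, -0.13, -0.26, -1.00), (0.45, 0.30, 0.20, 0.05)),
        ("ignored", ("never", "rarely", "sometimes", "regularly"), "never",
         (0.0, -0.25, -0.47, -0.92), (0.50, 0.28, 0.17, 0.05)),
        ("weekend_homework", ("five_plus_h", "none_lt1h", "1_to_2h", "3_to_4h"),
         "five_plus_h", (0.0, 0.41, 0.52, 0.36), (0.21, 0.15, 0.34, 0.30)),
        ("math_difficulty", ("never", "rarely", "sometimes", "regularly"), "never",
         (0.0, -0.43, -0.64, -1.03), (0.35, 0.30, 0.27, 0.08)),
        ("appetite", ("not_good", "somewhat_good", "always_good"), "not_good",
         (0.0, 0.73, 0.78), (0.10, 0.35, 0.55)),
        ("sleep_hours", ("gt_8h", "7_to_8h", "lt_7h"), "gt_8h",
         (0.0, -0.16, -0.80), (0.25, 0.55, 0.20)),
        ("same_sex_friends", ("no", "yes"), "no", (0.0, 0.41), (0.30, 0.70)),
        ("karaoke_bars", ("two_plus", "none", "one"), "two_plus",
         (0.0, 0.47, 0.70), (0.20, 0.45, 0.35)),
    ]
    out = []
    for name, levels, ref, weights, probs in specs:
        # gender_item duplicates the demographic gender column as a scored
        # item in the published instrument; modeled as its own item here
        out.append(
            ItemSchema(
                name=name,
                levels=levels,
                reference_level=ref,
                informative=True,
                effect_by_level=_risk_effects(levels, weights),
                base_probs=probs,
            )
        )
    return out


def noise_item_schemas(n: int, n_levels: int = 3) -> list[ItemSchema]:
    """Uninformative filler items emulating the remaining questionnaire
    questions (the form has ~80; only ten load on risk)."""
    levels = tuple(f"l{i}" for i in range(n_levels))
    return [
        ItemSchema(
            name=f"noise_{i:02d}",
            levels=levels,
            reference_level=levels[0],
            informative=False,
            base_probs=tuple([0.6] + [0.4 / (n_levels - 1)] * (n_levels - 1)),
        )
        for i in range(n)
    ]


def ci_item_schemas() -> list[ItemSchema]:
    """Reduced-profile items: three clearly informative predictors plus
    five noise items.  Effects are larger than the full-scale items'
    (~1 on common levels) so that detection power at n=1000 matches the
    full-scale design at n~3000 (signal scaled with 1/sqrt(n))."""
    informative = [
        ItemSchema("risk_a", ("low", "high"), "low", True,
                   {"low": 0.0, "high": 1.5}, (0.6, 0.4)),
        ItemSchema("risk_b", ("none", "mild", "severe"), "none", True,
                   {"none": 0.0, "mild": 0.8, "severe": 1.7}, (0.5, 0.3, 0.2)),
        ItemSchema("risk_c", ("no", "yes"), "no", True,
                   {"no": 0.0, "yes": 1.5}, (0.7, 0.3)),
    ]
    return informative + noise_item_schemas(5)


def default_item_schemas(n_noise: int = 70) -> list[ItemSchema]:
    """Ten informative items plus filler, ~80 items total by default."""
    return core_item_schemas() + noise_item_schemas(n_noise)


def default_missingness(
    config: CohortConfig,
    item_rate_range: tuple[float, float] = (0.013, 0.119),
    scale_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> MissingnessConfig:
    """MAR missingness at the observed study's rates.

    Item rates are spread so most sit near the 1.8% median with a tail
    up to ~12%; scale totals default to 59.3/27.1/27.7% with the first
    scale structurally missing in the non-participating schools.
    Missingness of every variable depends on fully observed demographics
    (gender, residence status, school participation flag).
    """
    if scale_rates is None:
        scale_rates = dict(zip(config.scale_names, (0.593, 0.271, 0.277)))
    names = list(config.item_names)
    lo, hi = item_rate_range
    rates: dict[str, float] = {}
    for i, name in enumerate(names):
        # geometric spread: median near lo*(hi/lo)^0.25 ~= 0.022
        frac = (i / max(len(names) - 1, 1)) ** 3
        rates[name] = lo * (hi / lo) ** frac
    rates.update({k: float(v) for k, v in scale_rates.items()})
    dependence = {}
    for name in names:
        dependence[name] = [(LOCAL_COL, "non_local", 0.5), (GENDER_COL, "male", 0.3)]
    scale_names = list(scale_rates)
    # first scale (CBCL analogue) structurally missing at flagged schools
    dependence[scale_names[0]] = [
        (SCHOOL_FLAG_COL, "yes", 50.0),
        (LOCAL_COL, "non_local", 0.6),
    ]
    for s in scale_names[1:]:
        dependence[s] = [(LOCAL_COL, "non_local", 0.6), (GENDER_COL, "male", 0.2)]
    return MissingnessConfig(
        per_variable_rate=rates, mechanism="MAR", dependence=dependence, seed=seed
    )
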