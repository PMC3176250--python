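"""Build the additive screening instrument from per-imputation stepwise
results and score individual students.

Items selected in at least a threshold fraction (default 70%) of the
training imputations are retained; one logistic model containing
exactly the retained items is refitted on every training imputation and
each level's weight is the across-refit mean coefficient, sign-flipped
to the protective-positive orientation (higher score = lower modeled
risk).  Reference levels carry weight 0.  The published-table artifact
rounds to 2 decimals; full-precision weights are retained for
evaluation so rounding loss cannot contaminate AUC or calibration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import StepwiseResult, fit_logistic


@dataclass
class SelectionSummary:
    frequency: dict[str, float]
    threshold: float = 0.70
    included_items: set[str] = field(default_factory=set)


def selection_frequency(
    results: list[StepwiseResult], threshold: float = 0.70
) -> SelectionSummary:
    """Fraction of stepwise runs selecting each item; inclusion iff the
    fraction is at least the threshold."""
    if not results:
        raise ValueError("empty results list")
    counts: dict[str, int] = {}
    for r in results:
        for item in r.selected_items:
            counts[item] = counts.get(item, 0) + 1
    freq = {item: c / len(results) for item, c in sorted(counts.items())}
    included = {item for item, f in freq.items() if f >= threshold}
    return SelectionSummary(frequency=freq, threshold=threshold,
                           included_items=included)


@dataclass
class ScoreTable:
    """The additive instrument: item -> level -> weight, protective-
    positive, reference levels at 0.  ``entries`` holds full-precision
    weights; serialization and ``rounded_entries`` apply ``rounding``."""

    entries: dict[str, dict[str, float]]
    rounding: int = 2

    @property
    def items(self) -> list[str]:
        return list(self.entries)

    def rounded_entries(self) -> dict[str, dict[str, float]]:
        return {
            item: {lv: round(w, self.rounding) for lv, w in levels.items()}
            for item, levels in self.entries.items()
        }

    def min_score(self) -> float:
        return sum(min(levels.values()) for levels in self.entries.values())

    def max_score(self) -> float:
        return sum(max(levels.values()) for levels in self.entries.values())

    def to_json(self) -> str:
        return json.dumps(
            {"rounding": self.rounding, "entries": self.rounded_entries(),
             "orientation": "protective-positive"},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreTable":
        d = json.loads(text)
        return cls(entries=d["entries"], rounding=d.get("rounding", 2))

    def to_markdown(self) -> str:
        lines = ["| Item | Level | Score |", "|---|---|---|"]
        for item, levels in self.entries.items():
            for lv, w in levels.items():
                lines.append(f"| {item} | {lv} | {w:+.{self.rounding}f} |")
        return "\n".join(lines)


def _level_coefficients(fit, item: str) -> dict[str, float]:
    out = {}
    for name in fit.term_blocks.get(item, []):
        m = re.match(rf"^{re.escape(item)}\[(.+)\]$", name)
        level = m.group(1) if m else name
        out[level] = fit.coefficients[name]
    return out


def build_score_table(
    training_data: list,
    summary: SelectionSummary,
    outcome: str,
    rounding: int = 2,
) -> ScoreTable:
    """Refit the included-item model on every training imputation and
    average (then sign-flip) the per-level coefficients."""
    items = sorted(summary.included_items)
    if not items:
        raise ValueError("no items reached the selection threshold")
    per_fit: list[dict[str, dict[str, float]]] = []
    for i, data in enumerate(training_data):
        try:
            fit = fit_logistic(data, outcome, items, on_separation="ridge")
        except Exception as exc:
            raise RuntimeError(f"refit failed on training imputation {i}: {exc}") from exc
        per_fit.append({item: _level_coefficients(fit, item) for item in items})
    entries: dict[str, dict[str, float]] = {}
    for item in items:
        df0 = getattr(training_data[0], "df", training_data[0])
        col = df0[item]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        else:
            levels = sorted(col.unique())
        weights = {str(levels[0]): 0.0}  # reference
        for lv in levels[1:]:
            coefs = [pf[item].get(str(lv), 0.0) for pf in per_fit]
            weights[str(lv)] = -float(np.mean(coefs))
        entries[item] = weights
    return ScoreTable(entries=entries, rounding=rounding)


def score_individuals(
    table: ScoreTable, data, precise: bool = True, id_col: str = "student_id"
) -> pd.DataFrame:
    """Additive score per student: sum of per-item level weights."""
    df = getattr(data, "df", data)
    entries = table.entries if precise else table.rounded_entries()
    total = np.zeros(len(df))
    for item, weights in entries.items():
        vals = df[item].astype(str)
        unknown = set(vals.unique()) - set(weights)
        if unknown:
            raise KeyError(f"level(s) {sorted(unknown)} of {item!r} absent from score table")
        total += vals.map(weights).to_numpy(dtype=float)
    out = pd.DataFrame({id_col: df[id_col] if id_col in df else np.arange(len(df)),
                        "score": total})
    return out
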