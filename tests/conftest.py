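import warnings

import numpy as np
import pandas as pd
import pytest

from miscore import (Cohort, CohortConfig, CohortSchema, ItemSchema,
                     define_outcome, generate_cohort)
from miscore.schema import ci_item_schemas

# imputation models at reduced n can trip benign sklearn warnings
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_schemas():
    """Two binary items and one 3-level item, one of each informative."""
    return [
        ItemSchema("strong", ("a", "b"), "a", True, {"a": 0.0, "b": 1.5},
                   (0.5, 0.5)),
        ItemSchema("weakcat", ("x", "y", "z"), "x", True,
                   {"x": 0.0, "y": 0.4, "z": 0.9}, (0.5, 0.3, 0.2)),
        ItemSchema("noise", ("p", "q"), "p", False, base_probs=(0.7, 0.3)),
    ]


@pytest.fixture
def small_cohort(small_schemas):
    cfg = CohortConfig(n_students=800, item_schemas=small_schemas,
                       target_prevalence=0.18, seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def ci_cohort():
    cfg = CohortConfig(n_students=1000, item_schemas=ci_item_schemas(), seed=7)
    return generate_cohort(cfg)


def make_scale_cohort(scale_values: dict, genders=None) -> Cohort:
    """Hand-built cohort with explicit scale totals for outcome-rule
    truth-table tests; one dummy binary item."""
    n = len(next(iter(scale_values.values())))
    item = ItemSchema("dummy", ("a", "b"), "a", base_probs=(0.5, 0.5))
    df = pd.DataFrame({"student_id": np.arange(1, n + 1)})
    g = genders if genders is not None else ["female"] * n
    df["gender"] = pd.Categorical(g, categories=["female", "male"])
    df["dummy"] = pd.Categorical(["a"] * n, categories=["a", "b"])
    for k, v in scale_values.items():
        df[k] = np.asarray(v, dtype=float)
    schema = CohortSchema(item_schemas=(item,),
                          scale_names=tuple(scale_values))
    return Cohort(df, schema)
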