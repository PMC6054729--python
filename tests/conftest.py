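"""Shared fixtures and cohort-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from npcperm.dataset_io import CohortTable, VariableSpec
from npcperm.synthetic_data import BinaryVariable, CohortModel, NumericVariable


def build_cohort(groups, columns, specs, missing=None) -> CohortTable:
    """Assemble a CohortTable directly from python lists.

    ``columns`` maps variable name -> list of values (None marks missing for
    categorical, NaN for numeric); ``missing`` may override the mask.
    """
    groups = np.asarray(groups, dtype=int)
    values = {}
    miss = {}
    for spec in specs:
        col = columns[spec.name]
        if spec.is_numeric:
            arr = np.array([np.nan if v is None else float(v) for v in col])
            m = np.isnan(arr)
        else:
            arr = np.array(col, dtype=object)
            m = np.array([v is None for v in col])
        if missing and spec.name in missing:
            m = np.asarray(missing[spec.name], dtype=bool)
        values[spec.name] = arr
        miss[spec.name] = m
    return CohortTable(
        groups=groups,
        values=pd.DataFrame(values),
        missing=pd.DataFrame(miss),
        specs=list(specs),
        group_labels={"A": 1, "B": 2},
    )


@pytest.fixture
def numeric_spec():
    return VariableSpec("x", "numeric")


@pytest.fixture
def binary_spec():
    return VariableSpec("status", "categorical", ("yes", "no"))


@pytest.fixture
def tiny_numeric_cohort(numeric_spec):
    """n1 = 2, n2 = 2, one numeric variable, well separated groups."""
    return build_cohort(
        [1, 1, 2, 2], {"x": [1.0, 2.0, 10.0, 11.0]}, [numeric_spec]
    )


def small_null_model(k_numeric=5, k_binary=5, n1=60, n2=100) -> CohortModel:
    """Global-null mixed model for size studies: standard-normal numerics and
    0.3-proportion binaries, identical in both groups."""
    variables = tuple(
        [NumericVariable(f"num{i}", 0.0, 1.0, 0.0, 1.0) for i in range(k_numeric)]
        + [BinaryVariable(f"bin{i}", 0.3, 0.3) for i in range(k_binary)]
    )
    return CohortModel(variables=variables, n1=n1, n2=n2)
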