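"""Two-group mixed-type cohort tables: reading, validation, summaries.

A cohort is a rectangular table with one grouping column (exactly two observed
levels) and K outcome columns of declared type, numeric or categorical.  Cells
equal to a configurable NA token (empty string or ``"NA"`` by default) are
treated as missing completely at random and are dropped per variable, not
listwise: a unit missing one variable still contributes to every other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, DegenerateVariableError

DEFAULT_NA_TOKENS = ("", "NA")


@dataclass(frozen=True)
class VariableSpec:
    """Declared identity and type of one outcome variable.

    Parameters
    ----------
    name : str
        Column label; must be unique within a spec set.
    kind : {"numeric", "categorical"}
    levels : tuple of str, optional
        Ordered category labels; required (>= 2 entries) iff categorical.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("variable name must be non-empty")
        if self.kind not in ("numeric", "categorical"):
            raise ConfigurationError(
                f"{self.name!r}: kind must be 'numeric' or 'categorical', got {self.kind!r}"
            )
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ConfigurationError(
                    f"{self.name!r}: categorical variables need >= 2 levels"
                )
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        elif self.levels is not None:
            raise ConfigurationError(f"{self.name!r}: numeric variables take no levels")

    @property
    def is_numeric(self) -> bool:
        return self.kind == "numeric"


def _check_unique_names(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate variable names: {dupes}")


@dataclass
class CohortTable:
    """Two-group observation matrix with a missingness mask.

    Attributes
    ----------
    groups : (n,) int array with entries in {1, 2}.
    values : DataFrame, one column per variable (float for numeric variables,
        object/str for categorical; missing cells hold NaN / None).
    missing : boolean DataFrame aligned with ``values``.
    specs : the VariableSpec list the table was validated against.
    group_labels : mapping from original group labels to {1, 2}.
    """

    groups: np.ndarray
    values: pd.DataFrame
    missing: pd.DataFrame
    specs: list[VariableSpec]
    group_labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        if not set(np.unique(self.groups)) == {1, 2}:
            raise DataError("both groups must be non-empty and labelled 1/2")
        if len(self.values) != len(self.groups):
            raise DataError("values and groups length mismatch")

    @property
    def n1(self) -> int:
        return int(np.sum(self.groups == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.groups == 2))

    @property
    def n_units(self) -> int:
        return len(self.groups)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec_for(self, variable: str) -> VariableSpec:
        for s in self.specs:
            if s.name == variable:
                return s
        raise ConfigurationError(f"unknown variable {variable!r}")


def read_cohort_csv(
    path,
    group_column: str,
    specs: Sequence[VariableSpec],
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
    group_mapping: dict[str, int] | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV (RFC-4180, header row required).

    Group labels are mapped to {1, 2} lexicographically unless ``group_mapping``
    is given.  Cells equal to one of ``na_tokens`` are flagged missing.
    """
    _check_unique_names(specs)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if group_column not in raw.columns:
        raise ConfigurationError(f"group column {group_column!r} not in file")
    for s in specs:
        if s.name not in raw.columns:
            raise ConfigurationError(f"variable column {s.name!r} not in file")

    glabels = raw[group_column].astype(str)
    observed = sorted(glabels.unique())
    if len(observed) != 2:
        raise DataError(
            f"group column {group_column!r} must have exactly 2 levels, found {observed}"
        )
    if group_mapping is None:
        group_mapping = {observed[0]: 1, observed[1]: 2}
    elif sorted(group_mapping.values()) != [1, 2] or set(group_mapping) != set(observed):
        raise ConfigurationError(f"group mapping must map {observed} onto {{1, 2}}")
    groups = glabels.map(group_mapping).to_numpy(dtype=int)

    na_set = set(na_tokens)
    values: dict[str, object] = {}
    missing: dict[str, np.ndarray] = {}
    for s in specs:
        col = raw[s.name].astype(str)
        miss = col.isin(na_set).to_numpy()
        if s.is_numeric:
            out = np.full(len(col), np.nan)
            for idx in np.flatnonzero(~miss):
                try:
                    out[idx] = float(col.iloc[idx])
                except ValueError:
                    raise DataError(
                        f"row {idx}, column {s.name!r}: {col.iloc[idx]!r} is not numeric"
                    ) from None
            values[s.name] = out
        else:
            lev = set(s.levels)
            for idx in np.flatnonzero(~miss):
                if col.iloc[idx] not in lev:
                    raise DataError(
                        f"row {idx}, column {s.name!r}: value {col.iloc[idx]!r} "
                        f"not among declared levels {list(s.levels)}"
                    )
            values[s.name] = np.where(miss, None, col.to_numpy(dtype=object))
        missing[s.name] = miss

    return CohortTable(
        groups=groups,
        values=pd.DataFrame(values),
        missing=pd.DataFrame(missing),
        specs=list(specs),
        group_labels=dict(group_mapping),
    )


def write_cohort_csv(table: CohortTable, path, na_token: str = "") -> None:
    """Write a cohort in the same dialect ``read_cohort_csv`` accepts.

    Floats are written with ``repr`` precision so a round trip is exact.
    """
    inv = {v: k for k, v in table.group_labels.items()} or {1: "1", 2: "2"}
    out = {"group": [inv[g] for g in table.groups]}
    for s in table.specs:
        col = table.values[s.name]
        miss = table.missing[s.name].to_numpy()
        if s.is_numeric:
            out[s.name] = [na_token if m else repr(float(v)) for v, m in zip(col, miss)]
        else:
            out[s.name] = [na_token if m else str(v) for v, m in zip(col, miss)]
    pd.DataFrame(out).to_csv(path, index=False)


def extract_complete(table: CohortTable, variable: str):
    """Split the non-missing values of one variable by group.

    Per-variable casewise deletion: only units missing *this* variable are
    dropped, which is unbiased under MCAR.  Raises
    :class:`DegenerateVariableError` if either group ends up empty.
    """
    spec = table.spec_for(variable)
    keep = ~table.missing[variable].to_numpy()
    col = table.values[variable].to_numpy()
    g = table.groups
    x1 = col[keep & (g == 1)]
    x2 = col[keep & (g == 2)]
    if len(x1) == 0 or len(x2) == 0:
        raise DegenerateVariableError(
            f"variable {variable!r}: no observed values in group "
            f"{'1' if len(x1) == 0 else '2'}"
        )
    if spec.is_numeric:
        return x1.astype(float), x2.astype(float)
    return list(x1), list(x2)


def complete_case_index(table: CohortTable, variable: str) -> np.ndarray:
    """Unit indices (in table order) with this variable observed."""
    return np.flatnonzero(~table.missing[variable].to_numpy())


def summarize_variable(x1, x2, spec: VariableSpec) -> dict:
    """Per-group descriptive summary.

    Numeric: mean and n-1 sample SD per group (SD is None for a single
    observation, never reported as zero).  Categorical: per-level percentages
    summing to 100 within each group; full precision, rounding is left to
    rendering.
    """
    if len(x1) == 0 or len(x2) == 0:
        raise DataError("summary requires both groups non-empty")
    if spec.is_numeric:
        a1, a2 = np.asarray(x1, float), np.asarray(x2, float)

        def sd(a):
            return float(np.std(a, ddof=1)) if len(a) > 1 else None

        return {
            "kind": "numeric",
            "n": (len(a1), len(a2)),
            "mean": (float(a1.mean()), float(a2.mean())),
            "sd": (sd(a1), sd(a2)),
        }
    pct = {}
    for level in spec.levels:
        pct[level] = (
            100.0 * sum(1 for v in x1 if v == level) / len(x1),
            100.0 * sum(1 for v in x2 if v == level) / len(x2),
        )
    return {"kind": "categorical", "n": (len(x1), len(x2)), "percent": pct}


def read_variable_specs(path) -> list[VariableSpec]:
    """Load a variable-spec config (YAML list of {name, kind, levels})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["variables"] if isinstance(doc, dict) and "variables" in doc else doc
    if not isinstance(entries, list):
        raise ConfigurationError("spec config must be a list of variable entries")
    specs = [
        VariableSpec(
            name=str(e["name"]),
            kind=str(e["kind"]),
            levels=tuple(map(str, e["levels"])) if e.get("levels") else None,
        )
        for e in entries
    ]
    _check_unique_names(specs)
    return specs


def write_variable_specs(specs: Sequence[VariableSpec], path) -> None:
    entries = []
    for s in specs:
        e: dict = {"name": s.name, "kind": s.kind}
        if s.levels:
            e["levels"] = list(s.levels)
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump({"variables": entries}, fh, sort_keys=False)
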