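"""Synthetic two-group cohort generator.

Emulates the statistical structure the analysis assumes: two independently
sampled groups, numeric variables Gaussian with per-group mean/SD, binary
variables Bernoulli with per-group proportions, variables independent of one
another, and an optional MCAR missingness mask.  The default model carries
the published descriptive parameters of the motivating inflammatory bowel
disease cohort — 631 Crohn's disease vs 1091 ulcerative colitis patients and
22 mixed-type clinical variables — so the full pipeline can run end to end
without any external data.

A global-null variant (group-2 parameters overwritten by group-1's) supports
type-I-error studies, and an optional Gaussian-copula correlation matrix
supports dependence-robustness checks of the combining step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset_io import CohortTable, VariableSpec
from .errors import ConfigurationError


@dataclass(frozen=True)
class NumericVariable:
    """Gaussian numeric variable with per-group (mean, sd).

    ``truncate_at_zero`` resamples negative draws' sign region by clipping at
    0; ``integer_support`` additionally rounds to the nearest non-negative
    integer (an ordinal-score emulation).  Both default off so the generated
    first two moments match the declared parameters.
    """

    name: str
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    truncate_at_zero: bool = False
    integer_support: bool = False

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ConfigurationError(f"{self.name!r}: sd must be >= 0")

    @property
    def spec(self) -> VariableSpec:
        return VariableSpec(self.name, "numeric")

    def params(self, group: int) -> tuple[float, float]:
        return (self.mean1, self.sd1) if group == 1 else (self.mean2, self.sd2)


@dataclass(frozen=True)
class BinaryVariable:
    """Bernoulli variable over two labels; p is the probability of levels[0]."""

    name: str
    p1: float
    p2: float
    levels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ConfigurationError(f"{self.name!r}: proportions must lie in [0, 1]")

    @property
    def spec(self) -> VariableSpec:
        return VariableSpec(self.name, "categorical", tuple(self.levels))

    def params(self, group: int) -> float:
        return self.p1 if group == 1 else self.p2


ModelVariable = NumericVariable | BinaryVariable


@dataclass(frozen=True)
class CohortModel:
    """Full sampling model: variables, group sizes, MCAR rate, optional copula.

    ``correlation`` (K×K, positive semi-definite, unit diagonal) induces
    dependence through a Gaussian copula: one latent multivariate normal draw
    per unit is mapped through each variable's marginal.  ``None`` means
    independent variables.
    """

    variables: tuple[ModelVariable, ...]
    n1: int
    n2: int
    missing_rate: float = 0.0
    correlation: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigurationError("variable names must be unique")
        if self.correlation is not None:
            r = np.asarray(self.correlation, float)
            k = len(self.variables)
            if r.shape != (k, k):
                raise ConfigurationError("correlation must be K x K")

    @property
    def specs(self) -> list[VariableSpec]:
        return [v.spec for v in self.variables]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]


def default_model(charlson_ordinal: bool = False) -> CohortModel:
    """The 22-variable CD-vs-UC cohort model at its published parameters.

    Group 1 is Crohn's disease (n = 631), group 2 ulcerative colitis
    (n = 1091).  Numeric variables carry the published group means ± SDs;
    binary variables the published "yes" (or first-label) percentages as
    fractions.  ``charlson_ordinal=True`` switches the Charlson comorbidity
    score to a zero-truncated, integer-rounded Gaussian; the default keeps it
    continuous so its generated moments match the declared ones.
    """
    v: list[ModelVariable] = [
        NumericVariable("Diagnosis age", 43.80, 21.59, 45.87, 20.83),
        BinaryVariable("Gender", 0.493, 0.577, levels=("M", "F")),
        BinaryVariable("Smoking habit", 0.439, 0.352),
        BinaryVariable("Immunosuppressive therapy", 0.384, 0.264),
        NumericVariable("Duration of immunosuppr. therapy", 12.27, 8.67, 14.92, 9.84),
        BinaryVariable("Biological drugs", 0.184, 0.087),
        NumericVariable("Duration of biological treatment", 12.23, 7.33, 16.03, 9.41),
        BinaryVariable("Re-hospitalization", 0.456, 0.278),
        BinaryVariable("Adverse events", 0.179, 0.092),
        BinaryVariable("Infections", 0.070, 0.076),
        BinaryVariable("Cancers", 0.036, 0.025),
        BinaryVariable("Diabetes", 0.056, 0.106),
        BinaryVariable("Hypertension", 0.203, 0.196),
        BinaryVariable("Heart failure", 0.057, 0.057),
        BinaryVariable("Kidney failure", 0.021, 0.026),
        BinaryVariable("Pulmonary failure", 0.036, 0.051),
        BinaryVariable("Neuropathy", 0.017, 0.016),
        BinaryVariable("Liver disease", 0.016, 0.013),
        NumericVariable(
            "Charlson score", 1.47, 1.81, 1.20, 1.39,
            truncate_at_zero=charlson_ordinal, integer_support=charlson_ordinal,
        ),
        BinaryVariable("Surgery", 0.197, 0.053),
        BinaryVariable("Final exitus", 0.979, 0.976, levels=("survivor", "died")),
        NumericVariable("Follow-up time", 34.57, 4.54, 34.92, 4.16),
    ]
    return CohortModel(variables=tuple(v), n1=631, n2=1091)


def null_model(base: CohortModel) -> CohortModel:
    """Copy of ``base`` with group-2 parameters overwritten by group-1's.

    Every variable then has identical distributions in the two groups, so the
    global null of joint distributional equality holds exactly — the setting
    for size (type-I error) studies.
    """
    out = []
    for v in base.variables:
        if isinstance(v, NumericVariable):
            out.append(replace(v, mean2=v.mean1, sd2=v.sd1))
        else:
            out.append(replace(v, p2=v.p1))
    return replace(base, variables=tuple(out))


def _marginal_from_normal(v: ModelVariable, z: np.ndarray, group: int) -> np.ndarray:
    if isinstance(v, NumericVariable):
        mean, sd = v.params(group)
        x = mean + sd * z
        if v.truncate_at_zero:
            x = np.maximum(x, 0.0)
        if v.integer_support:
            x = np.rint(np.maximum(x, 0.0))
        return x
    p = v.params(group)
    # levels[0] with probability p: uniform grade of z below p
    u = norm.cdf(z)
    return np.where(u < p, v.levels[0], v.levels[1]).astype(object)


def generate_cohort(model: CohortModel, seed: int) -> CohortTable:
    """Draw one cohort from the model; fully reproducible given ``seed``."""
    rng = np.random.default_rng(seed)
    n = model.n1 + model.n2
    groups = np.concatenate([np.ones(model.n1, int), np.full(model.n2, 2)])
    k = len(model.variables)

    if model.correlation is not None:
        r = np.asarray(model.correlation, float)
        chol = np.linalg.cholesky(r + 1e-12 * np.eye(k))
        z = rng.standard_normal((n, k)) @ chol.T
    else:
        z = rng.standard_normal((n, k))

    cols: dict[str, np.ndarray] = {}
    for j, v in enumerate(model.variables):
        col = np.empty(n, dtype=object if isinstance(v, BinaryVariable) else float)
        for group, sl in ((1, groups == 1), (2, groups == 2)):
            col[sl] = _marginal_from_normal(v, z[sl, j], group)
        cols[v.name] = col

    if model.missing_rate > 0:
        miss = rng.random((n, k)) < model.missing_rate
    else:
        miss = np.zeros((n, k), dtype=bool)

    values = {}
    missing = {}
    for j, v in enumerate(model.variables):
        m = miss[:, j]
        if isinstance(v, NumericVariable):
            col = cols[v.name].astype(float)
            col[m] = np.nan
            values[v.name] = col
        else:
            col = cols[v.name].copy()
            col[m] = None
            values[v.name] = col
        missing[v.name] = m

    return CohortTable(
        groups=groups,
        values=pd.DataFrame(values),
        missing=pd.DataFrame(missing),
        specs=model.specs,
        group_labels={"group1": 1, "group2": 2},
    )


def model_to_config(model: CohortModel) -> dict:
    """Serializable description: variable specs plus a parameters block."""
    params: dict[str, object] = {}
    variables = []
    for v in model.variables:
        e: dict[str, object] = {"name": v.name, "kind": v.spec.kind}
        if isinstance(v, BinaryVariable):
            e["levels"] = list(v.levels)
            params[v.name] = {"p1": v.p1, "p2": v.p2}
        else:
            params[v.name] = {
                "mean1": v.mean1, "sd1": v.sd1, "mean2": v.mean2, "sd2": v.sd2,
            }
        variables.append(e)
    return {
        "variables": variables,
        "parameters": params,
        "n1": model.n1,
        "n2": model.n2,
        "missing_rate": model.missing_rate,
    }
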