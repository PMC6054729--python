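"""Per-variable (partial) two-sample permutation tests.

Each of the K outcome variables gets a one-dimensional permutation test of
the sub-null that its distribution is the same in both groups, against the
two-sided alternative of distributional inequality:

* numeric variables — absolute difference of group means, |x̄1 − x̄2|, the
  unstandardized "difference of two means" statistic (an optionally
  studentized Welch-type variant is available);
* categorical variables — the likelihood-ratio statistic
  G = 2 Σ O log(O/E) of the 2×L group-by-level contingency table.

Both are significant for large values, so the shared upper-tail p-value
machinery of :mod:`npcperm.permutation_engine` applies.  When several
variables are tested jointly the statistics must be recomputed on the *same*
assignment sequence so their joint permutation distribution retains the
inter-variable dependence the nonparametric combination relies on; the
``assignments`` argument lets a caller pass one shared unit-level matrix,
restricted per variable to its complete cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import CohortTable, complete_case_index
from .errors import ConfigurationError, DegenerateVariableError
from .permutation_engine import (
    DEFAULT_TIE_TOL,
    PermutationScheme,
    generate_assignments,
    pvalue_from_distribution,
)


def mean_diff_statistic(x1, x2, studentize: bool = False) -> float:
    """Two-sided mean-difference statistic |mean(x1) - mean(x2)|.

    With ``studentize=True`` the difference is divided by the Welch standard
    error sqrt(s1^2/n1 + s2^2/n2), which is robust to unequal variances but
    requires at least two observations per group.
    """
    a1, a2 = np.asarray(x1, float), np.asarray(x2, float)
    if a1.size == 0 or a2.size == 0:
        raise DegenerateVariableError("mean difference needs both groups non-empty")
    diff = abs(a1.mean() - a2.mean())
    if not studentize:
        return float(diff)
    if a1.size < 2 or a2.size < 2:
        raise DegenerateVariableError("studentized statistic needs n >= 2 per group")
    se = np.sqrt(a1.var(ddof=1) / a1.size + a2.var(ddof=1) / a2.size)
    return float(diff / se) if se > 0 else 0.0


def lr_statistic(counts) -> float:
    """Likelihood-ratio (G) statistic of a 2×L contingency table.

    G = 2 Σ O log(O/E) with expectations E = row_total × col_total / grand
    under independence; empty cells contribute zero (the 0·log 0 convention)
    and all-zero columns drop out.
    """
    o = np.asarray(counts, dtype=float)
    if o.ndim != 2 or o.shape[0] != 2:
        raise ConfigurationError("counts must be a 2 x L table")
    if np.any(o < 0):
        raise ConfigurationError("counts must be non-negative")
    row = o.sum(axis=1, keepdims=True)
    col = o.sum(axis=0, keepdims=True)
    grand = o.sum()
    if grand == 0 or np.any(row == 0):
        raise DegenerateVariableError("each group needs at least one observation")
    e = row * col / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / np.where(e > 0, e, 1.0)), 0.0)
    return float(2.0 * terms.sum())


@dataclass
class PartialTestResult:
    """Observed statistic, permutation distribution and raw p for one variable."""

    variable: str
    t_obs: float
    t_perm: np.ndarray
    raw_p: float
    n1: int
    n2: int
    exact: bool
    degenerate: bool = False
    message: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_assignments(self) -> int:
        return len(self.t_perm)


def _numeric_perm_stats(x: np.ndarray, labels: np.ndarray, studentize: bool) -> np.ndarray:
    """Vectorized |Δmean| (optionally studentized) over assignment rows.

    ``labels`` is (R, m) boolean; rows where a group is empty yield 0.
    """
    m = x.size
    lab = labels.astype(np.float64)
    k1 = lab.sum(axis=1)
    k2 = m - k1
    ok = (k1 > 0) & (k2 > 0)
    s1 = lab @ x
    total = x.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / k1
        mean2 = (total - s1) / k2
        t = np.abs(mean1 - mean2)
    if studentize:
        sq1 = lab @ (x * x)
        sq2 = (x * x).sum() - sq1
        with np.errstate(divide="ignore", invalid="ignore"):
            v1 = (sq1 - k1 * mean1**2) / (k1 - 1)
            v2 = (sq2 - k2 * mean2**2) / (k2 - 1)
            se = np.sqrt(v1 / k1 + v2 / k2)
            t = np.where(se > 0, t / se, 0.0)
        ok &= (k1 > 1) & (k2 > 1)
    return np.where(ok, np.nan_to_num(t), 0.0)


def _categorical_perm_stats(codes: np.ndarray, n_levels: int, labels: np.ndarray) -> np.ndarray:
    """Vectorized G statistic over assignment rows for integer-coded values."""
    m = codes.size
    onehot = np.zeros((m, n_levels), dtype=np.float64)
    onehot[np.arange(m), codes] = 1.0
    col = onehot.sum(axis=0)  # level totals, fixed across assignments
    c1 = labels.astype(np.float64) @ onehot  # (R, L) group-1 counts
    c2 = col[None, :] - c1
    k1 = c1.sum(axis=1)
    k2 = m - k1
    e1 = k1[:, None] * col[None, :] / m
    e2 = k2[:, None] * col[None, :] / m
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(c1 > 0, c1 * np.log(c1 / np.where(e1 > 0, e1, 1.0)), 0.0).sum(axis=1)
        g += np.where(c2 > 0, c2 * np.log(c2 / np.where(e2 > 0, e2, 1.0)), 0.0).sum(axis=1)
    return np.where((k1 > 0) & (k2 > 0), 2.0 * g, 0.0)


def _degenerate_result(variable: str, n1: int, n2: int, n_rows: int, msg: str) -> PartialTestResult:
    warnings.warn(f"variable {variable!r}: {msg}; raw p set to 1", stacklevel=3)
    return PartialTestResult(
        variable=variable,
        t_obs=0.0,
        t_perm=np.zeros(max(n_rows, 1)),
        raw_p=1.0,
        n1=n1,
        n2=n2,
        exact=False,
        degenerate=True,
        message=msg,
    )


def partial_test(
    table: CohortTable,
    variable: str,
    scheme: PermutationScheme,
    assignments: np.ndarray | None = None,
    studentize: bool = False,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> PartialTestResult:
    """Run the partial permutation test for one variable.

    ``assignments`` may be a unit-level (R, n_units) boolean matrix shared
    across variables (row 0 = observed labeling); it is restricted to this
    variable's complete cases, so units missing the variable are removed from
    the permutation sample space for this variable only.  When omitted, a
    fresh assignment sequence is generated for the complete cases.

    Degenerate variables (a single observed level, or an empty group) yield a
    flagged result with raw p = 1 and a warning instead of an error.
    """
    spec = table.spec_for(variable)
    idx = complete_case_index(table, variable)
    g = table.groups[idx]
    n1 = int(np.sum(g == 1))
    n2 = int(np.sum(g == 2))
    n_rows = assignments.shape[0] if assignments is not None else scheme.n_permutations
    if n1 == 0 or n2 == 0:
        return _degenerate_result(variable, n1, n2, n_rows, "one group has no observed values")

    col = table.values[variable].to_numpy()[idx]
    if spec.is_numeric:
        x = col.astype(float)
        if np.all(x == x[0]):
            return _degenerate_result(variable, n1, n2, n_rows, "no variation in observed values")
    else:
        level_index = {lev: i for i, lev in enumerate(spec.levels)}
        codes = np.array([level_index[v] for v in col], dtype=np.intp)
        if np.unique(codes).size < 2:
            return _degenerate_result(variable, n1, n2, n_rows, "single observed level")

    if assignments is not None:
        # restrict the shared unit-level assignment to this variable's cases,
        # reordering so the observed group-1 cases come first (row 0 stays the
        # observed labeling of the complete cases)
        order = np.concatenate([np.flatnonzero(g == 1), np.flatnonzero(g == 2)])
        labels = assignments[:, idx[order]]
        exact = False
        sorted_vals = col[order]
    else:
        order = np.concatenate([np.flatnonzero(g == 1), np.flatnonzero(g == 2)])
        labels = generate_assignments(n1, n2, scheme)
        exact = scheme.is_exact(n1, n2)
        sorted_vals = col[order]

    if spec.is_numeric:
        x = sorted_vals.astype(float)
        t_perm = _numeric_perm_stats(x, labels, studentize)
    else:
        codes = np.array([level_index[v] for v in sorted_vals], dtype=np.intp)
        t_perm = _categorical_perm_stats(codes, len(spec.levels), labels)

    t_obs = float(t_perm[0])
    raw_p = pvalue_from_distribution(t_obs, t_perm, tie_tol=tie_tol)
    return PartialTestResult(
        variable=variable,
        t_obs=t_obs,
        t_perm=t_perm,
        raw_p=raw_p,
        n1=n1,
        n2=n2,
        exact=exact,
        meta={"kind": spec.kind, "studentize": studentize},
    )
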