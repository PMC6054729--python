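"""Nonparametric combination (NPC) of dependent partial permutation tests.

The global null — joint distributional equality of all K variables — is the
intersection of the K sub-nulls; the global alternative is their union.  NPC
tests it without modelling the dependence among variables: every partial
statistic is recomputed on one shared assignment sequence, each B-long
statistic column is converted to within-column significance levels
λ[b] = #{b' : T[b'] >= T[b]} / B (the permutation survival level, the
conditional analogue of a p-value), each assignment's K levels are collapsed
by a combining function

* Fisher:  ψ = −2 Σ log λ_i
* Liptak:  ψ = Σ Φ⁻¹(1 − λ_i)
* Tippett: ψ = max_i (1 − λ_i)

and the combined statistic is referred to its own permutation distribution.
Because the λ-rows inherit the joint dependence of the partial statistics,
no correlation structure ever needs to be specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError
from .partial_tests import PartialTestResult
from .permutation_engine import DEFAULT_TIE_TOL, pvalue_from_distribution

COMBINING_METHODS = ("fisher", "liptak", "tippett")


def significance_transform(t_column: np.ndarray, tie_tol: float = DEFAULT_TIE_TOL) -> np.ndarray:
    """Within-column permutation survival levels.

    λ[b] = #{b' : t[b'] >= t[b] - tol} / B, with the same relative tie
    tolerance used for p-values; λ ranges over [1/B, 1] and λ of the observed
    row (b = 0) is exactly the partial raw p-value.
    """
    t = np.asarray(t_column, dtype=float)
    b = t.size
    if b < 2:
        raise ConfigurationError("need at least 2 assignments")
    tol = tie_tol * np.maximum(1.0, np.abs(t))
    order = np.sort(t)
    # count of values >= t_b - tol_b via position in the sorted column
    lam = (b - np.searchsorted(order, t - tol, side="left")) / b
    return lam


def combine(lambdas, method: str, clamp: float | None = None) -> float:
    """Collapse K significance levels into one combined statistic.

    ``clamp`` bounds λ into [clamp, 1 - clamp] before the Fisher log or
    Liptak normal-quantile transform so the statistic stays finite at the
    λ = 1/B and λ = 1 boundaries; ranks are unaffected.  Tippett needs no
    clamping.
    """
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ConfigurationError("significance levels must lie in (0, 1]")
    if method == "tippett":
        return float(np.max(1.0 - lam))
    if clamp:
        lam = np.clip(lam, clamp, 1.0 - clamp)
    if method == "fisher":
        return float(-2.0 * np.sum(np.log(lam)))
    if method == "liptak":
        return float(np.sum(norm.ppf(1.0 - lam)))
    raise ConfigurationError(f"unknown combining method {method!r}")


def _combine_rows(lam: np.ndarray, method: str, clamp: float) -> np.ndarray:
    """Row-wise combining of a (B, K) significance-level matrix."""
    if method == "tippett":
        return np.max(1.0 - lam, axis=1)
    lam = np.clip(lam, clamp, 1.0 - clamp)
    if method == "fisher":
        return -2.0 * np.sum(np.log(lam), axis=1)
    if method == "liptak":
        return np.sum(norm.ppf(1.0 - lam), axis=1)
    raise ConfigurationError(f"unknown combining method {method!r}")


@dataclass
class NPCResult:
    """Combined global test over K dependent partial tests."""

    method: str
    variables: list[str]
    partial_raw_p: np.ndarray
    lambda_obs: np.ndarray
    psi_obs: float
    psi_perm: np.ndarray
    combined_p: float

    @property
    def n_assignments(self) -> int:
        return len(self.psi_perm)

    @property
    def at_floor(self) -> bool:
        """Whether the combined p-value sits at its 1/B resolution floor."""
        return self.combined_p <= 1.0 / self.n_assignments + 1e-15


def npc_global_test(
    partials: list[PartialTestResult],
    method: str = "fisher",
    tie_tol: float = DEFAULT_TIE_TOL,
) -> NPCResult:
    """Combine K partial tests computed on one shared assignment sequence.

    The (B, K) matrix of permuted statistics (row 0 = observed) is converted
    column-wise to significance levels, combined row-wise into ψ, and the
    observed ψ is referred to the ψ column itself.  Rejecting when the
    combined p <= α tests the global null of joint distributional equality.
    """
    if method not in COMBINING_METHODS:
        raise ConfigurationError(
            f"method must be one of {COMBINING_METHODS}, got {method!r}"
        )
    if not partials:
        raise ConfigurationError("need at least one partial test")
    b = partials[0].n_assignments
    for p in partials:
        if p.n_assignments != b:
            raise ConfigurationError(
                "all partial tests must share one assignment sequence "
                f"({p.variable!r} has {p.n_assignments} rows, expected {b})"
            )
    lam = np.column_stack(
        [significance_transform(p.t_perm, tie_tol=tie_tol) for p in partials]
    )
    clamp = 1.0 / (2.0 * b)
    psi_perm = _combine_rows(lam, method, clamp)
    psi_obs = float(psi_perm[0])
    combined_p = pvalue_from_distribution(psi_obs, psi_perm, tie_tol=tie_tol)
    return NPCResult(
        method=method,
        variables=[p.variable for p in partials],
        partial_raw_p=np.array([p.raw_p for p in partials]),
        lambda_obs=lam[0].copy(),
        psi_obs=psi_obs,
        psi_perm=psi_perm,
        combined_p=combined_p,
    )
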