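"""Bonferroni-Holm sequentially rejective step-down multiplicity control.

The K partial raw p-values are sorted ascending; hypotheses are rejected in
order while p_(i) < α/(K − i + 1) and the procedure stops at the first i with
p_(i) >= α/(K − i + 1) (that hypothesis and all later ones are retained).
This controls the familywise error rate at α for arbitrary dependence among
the tests and is uniformly more powerful than the single-step Bonferroni
correction.

Adjusted p-values use the monotone step-down form
q_(i) = max_{j<=i} min(cap, (K − j + 1) · p_(j)), so that thresholding q at
any α reproduces the sequential decisions exactly.  The cap defaults to 1; a
compatibility cap of 0.9999 — the largest raw p a 10,000-permutation test
that counts the identity assignment can produce below 1 — mimics software
that saturates non-significant entries at that value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


def _validate(raw_ps) -> np.ndarray:
    p = np.asarray(raw_ps, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigurationError("need a non-empty 1-D vector of p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return p


def holm_decisions(raw_ps, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejection vector of the sequential Holm rule, in input order.

    Ties among raw p-values keep their input order (stable sort); the
    decisions are unaffected because tied values face the stricter threshold
    first.
    """
    p = _validate(raw_ps)
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    k = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(k, dtype=bool)
    for i, idx in enumerate(order, start=1):
        if p[idx] < alpha / (k - i + 1):
            reject[idx] = True
        else:
            break
    return reject


def holm_adjust(raw_ps, cap: float = 1.0) -> np.ndarray:
    """Step-down adjusted p-values, in input order.

    q_(i) = max_{j<=i} min(cap, (K − j + 1) p_(j)); rejecting where q <= α
    agrees with :func:`holm_decisions` for every α < cap.
    """
    p = _validate(raw_ps)
    if not 0 < cap <= 1:
        raise ConfigurationError("cap must lie in (0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    factors = k - np.arange(k)  # K, K-1, ..., 1
    stepped = np.minimum(cap, factors * p[order])
    adj_sorted = np.maximum.accumulate(stepped)
    adj = np.empty(k)
    adj[order] = adj_sorted
    return adj


@dataclass
class HolmResult:
    """Holm outcome for one variable."""

    variable: str
    raw_p: float
    rank_i: int
    adj_p: float
    significant: bool


def holm_report(
    variables: list[str], raw_ps, alpha: float = 0.05, cap: float = 1.0
) -> list[HolmResult]:
    """Per-variable Holm results (rank, adjusted p, decision), in input order."""
    p = _validate(raw_ps)
    if len(variables) != p.size:
        raise ConfigurationError("variables and p-values must align")
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=int)
    ranks[order] = np.arange(1, p.size + 1)
    adj = holm_adjust(p, cap=cap)
    rej = holm_decisions(p, alpha=alpha)
    return [
        HolmResult(
            variable=v,
            raw_p=float(p[i]),
            rank_i=int(ranks[i]),
            adj_p=float(adj[i]),
            significant=bool(rej[i]),
        )
        for i, v in enumerate(variables)
    ]


def bonferroni_adjust(raw_ps, cap: float = 1.0) -> np.ndarray:
    """Single-step Bonferroni adjustment min(cap, K·p), for comparison."""
    p = _validate(raw_ps)
    return np.minimum(cap, p.size * p)
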