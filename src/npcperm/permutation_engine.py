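"""Group-label reassignment generation and permutation p-values.

Permutation inference conditions on the pooled observed data: under the null
of distributional equality the group labels are exchangeable, so the null
distribution of any statistic is obtained by recomputing it over label
reassignments.  Two modes are supported:

* exact enumeration of all C(n1+n2, n1) distinct assignments, used when that
  count is small enough (oracle-grade, no Monte Carlo error);
* Conditional Monte Carlo (CMC): the identity assignment plus B-1 uniformly
  random label shuffles.  Duplicated splits are retained — deduplication would
  bias the p-value estimator.

The identity (observed) assignment always comes first and is counted in both
numerator and denominator of the p-value, so the smallest attainable p is 1/B
(0.0001 at B = 10,000) and p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import ConfigurationError

DEFAULT_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PermutationScheme:
    """Sampling plan for the permutation distribution.

    Parameters
    ----------
    n_permutations : int
        B, the number of assignments in CMC mode (identity included); >= 2.
    seed : int
        Seed for the random label shuffles.
    exact_threshold : int
        Exhaustive enumeration replaces random sampling whenever
        C(n1+n2, n1) <= exact_threshold.
    include_identity : bool
        Whether the observed labeling is prepended in CMC mode (it always is
        in exact mode, where it arises naturally).  Default True.
    """

    n_permutations: int = 10_000
    seed: int = 0
    exact_threshold: int = 20_000
    include_identity: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 2:
            raise ConfigurationError("n_permutations must be >= 2")
        if self.exact_threshold < 0:
            raise ConfigurationError("exact_threshold must be >= 0")

    def is_exact(self, n1: int, n2: int) -> bool:
        return comb(n1 + n2, n1) <= self.exact_threshold


def generate_assignments(n1: int, n2: int, scheme: PermutationScheme) -> np.ndarray:
    """Return a (R, n1+n2) boolean matrix; True marks membership in group 1.

    Row 0 is always the observed labeling (first n1 units in group 1).  In
    exact mode all C(n1+n2, n1) distinct assignments are returned; in CMC mode
    exactly ``scheme.n_permutations`` rows, the identity plus B-1 uniform
    random reassignments.
    """
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("both group sizes must be >= 1")
    n = n1 + n2
    identity = np.zeros(n, dtype=bool)
    identity[:n1] = True

    if scheme.is_exact(n1, n2):
        m = comb(n, n1)
        out = np.zeros((m, n), dtype=bool)
        out[0] = identity
        row = 1
        for picks in combinations(range(n), n1):
            if picks == tuple(range(n1)):
                continue  # identity already first
            out[row, list(picks)] = True
            row += 1
        return out

    b = scheme.n_permutations
    rng = np.random.default_rng(scheme.seed)
    n_random = b - 1 if scheme.include_identity else b
    out = np.empty((n_random, n), dtype=bool)
    base = identity.copy()
    for r in range(n_random):
        out[r] = rng.permutation(base)
    if scheme.include_identity:
        out = np.vstack([identity[None, :], out])
    return out


def pvalue_from_distribution(
    t_obs: float, t_perm: np.ndarray, tie_tol: float = DEFAULT_TIE_TOL
) -> float:
    """Upper-tail permutation p-value of a statistic significant for large values.

    ``p = #{b : t_perm[b] >= t_obs - tol} / B`` with a relative tie tolerance
    ``tol = tie_tol * max(1, |t_obs|)`` absorbing floating-point jitter among
    permutations of the same sums.  The observed assignment's statistic is
    expected to be included in ``t_perm``, so p >= 1/B > 0.
    """
    t_perm = np.asarray(t_perm, dtype=float)
    if t_perm.size == 0:
        raise ConfigurationError("empty permutation distribution")
    tol = tie_tol * max(1.0, abs(t_obs))
    return float(np.count_nonzero(t_perm >= t_obs - tol) / t_perm.size)
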