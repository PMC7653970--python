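"""Likelihood of the observed discovery matrix for a candidate total m.

The observed matrix ``d`` has unlabeled columns: many complete matrices
``x`` with ``m`` columns truncate to the same ``d``.  Their number is the
anagram coefficient

    H(d, m) = m! / ((m - j)! j_1! ... j_r!)

where ``j_h`` are the repetition counts of the ``r`` distinct column
patterns (the m - j missing problems play the role of a null letter
repeated m - j times).  Because columns are exchangeable, every one of
those complete matrices has the same probability, so

    P(d | theta, m) = H(d, m) * P(one padded matrix | theta, m).

Both the homogeneous (single p) and heterogeneous (logit-normal) column
models are provided.  Everything is computed in log space — H overflows
for quite modest m — and the multinomial constant 1/(j_1!...j_r!) is
retained so that exhaustive-enumeration normalization checks are exact.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from .discovery_matrix import DiscoveryMatrix
from .lnbzt import HeterogeneityParams, q_vector

__all__ = [
    "log_permutation_count",
    "homogeneous_loglik",
    "column_pattern_lik",
    "heterogeneous_loglik",
]


def _pattern_log_factorials(d: DiscoveryMatrix) -> float:
    cached = d.__dict__.get("_plf_cache")
    if cached is None:
        cached = float(sum(gammaln(c + 1) for _, c in d.pattern_counts()))
        object.__setattr__(d, "_plf_cache", cached)
    return cached


def log_permutation_count(d: DiscoveryMatrix, m: int) -> float:
    """log H(d, m), the log count of complete matrices truncating to d.

    Exact (via log-gamma) for small arguments: ``exp`` of the result
    reproduces the integer count while it is representable.
    """
    if m < d.j:
        raise ValueError(f"m = {m} is below the observed problem count j = {d.j}")
    return float(
        gammaln(m + 1) - gammaln(m - d.j + 1) - _pattern_log_factorials(d)
    )


def homogeneous_loglik(d: DiscoveryMatrix, p: float, m: int) -> float:
    """log P(d | p, m) under a single shared detection probability:

        H(d, m) * p^x.. * (1-p)^(n m - x..)

    Boundary p values incompatible with the data give -inf, not an error.
    """
    if m < d.j:
        raise ValueError(f"m = {m} is below the observed problem count j = {d.j}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    x_tot = d.total_detections
    zeros = d.n * m - x_tot
    if (p == 0.0 and x_tot > 0) or (p == 1.0 and zeros > 0):
        return -math.inf
    log_bern = 0.0
    if x_tot:
        log_bern += x_tot * math.log(p)
    if zeros:
        log_bern += zeros * math.log1p(-p)
    return log_permutation_count(d, m) + log_bern


def column_pattern_lik(k: int, n: int, params: HeterogeneityParams) -> float:
    """Q(k) = E_p[p^k (1-p)^(n-k)]: probability of one specific column
    pattern with sum k, under the logit-normal detection model."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in 0..n, got {k}")
    return float(q_vector(n, params)[k])


def heterogeneous_loglik(
    d: DiscoveryMatrix, params: HeterogeneityParams, m: int
) -> float:
    """log P(d | mu, sigma, m) under the logit-normal column model.

    Columns are independent given (mu, sigma), so the padded-matrix
    probability factorizes into Q(k_l) over observed columns times
    Q(0)^(m-j) for the undiscovered ones:

        log H(d,m) + sum_l log Q(k_l) + (m - j) log Q(0)

    The (m-j) log Q(0) term penalizes large m while log H grows with m —
    the trade-off that makes m estimable from the matrix alone.
    """
    if m < d.j:
        raise ValueError(f"m = {m} is below the observed problem count j = {d.j}")
    q = q_vector(d.n, params)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    obs = float(logq[d.column_sums].sum()) if d.j else 0.0
    tail = (m - d.j) * float(logq[0]) if m > d.j else 0.0
    return log_permutation_count(d, m) + obs + tail
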