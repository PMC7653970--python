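"""Margin-based estimators of the total number of usability problems.

These classical methods work in two steps: estimate a single detection
probability ``p`` from the problem margin (the column sums of the
discovery matrix), then deduce the total problem count from

    j = (1 - (1 - p)^n) * m,

i.e. the expected fraction of problems seen at least once by ``n``
participants.  Four plug-in estimates of ``p`` are provided (naive,
normalized, Good-Turing, double-deflation) together with the
maximum-likelihood fit of the zero-truncated binomial to the margin.
All assume a homogeneous ``p``; heterogeneity-aware models live in
:mod:`discoverym.lnbzt` and :mod:`discoverym.bayes_engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .discovery_matrix import DiscoveryMatrix

__all__ = [
    "HomogeneousParams",
    "EstimateResult",
    "UndefinedEstimateError",
    "naive_p",
    "normalized_p",
    "good_turing_p",
    "double_deflation_p",
    "discovery_proportion",
    "deduce_m",
    "zt_binomial_pmf",
    "fit_zt_binomial",
    "estimate_m_margin",
    "MARGIN_METHODS",
]


class UndefinedEstimateError(ValueError):
    """The estimator is undefined for this input (e.g. j = 0 or n = 1)."""


@dataclass(frozen=True)
class HomogeneousParams:
    """Single shared detection probability."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")


@dataclass
class EstimateResult:
    """Outcome of one estimation method on one discovery matrix.

    ``m_hat`` is kept continuous; ``m_rounded`` is the display value.
    ``flags`` collects non-fatal conditions ("infinite", "fit_failure",
    "discarded_extreme", ...) — failures are data, not exceptions.
    """

    method: str
    m_hat: float
    p_hat: Optional[float] = None
    mu_hat: Optional[float] = None
    sigma_hat: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    flags: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    @property
    def m_rounded(self) -> Optional[int]:
        if not math.isfinite(self.m_hat):
            return None
        return int(round(self.m_hat))

    @property
    def ok(self) -> bool:
        return math.isfinite(self.m_hat) and "fit_failure" not in self.flags


def _require_nondegenerate(d: DiscoveryMatrix) -> None:
    if d.degenerate:
        raise UndefinedEstimateError("estimators are undefined for a j=0 matrix")


def naive_p(d: DiscoveryMatrix) -> HomogeneousParams:
    """p-hat = x.. / (n*j): the raw detection rate of the observed matrix.

    Biased upward because undiscovered problems would contribute zero
    columns; consequently m is underestimated.
    """
    _require_nondegenerate(d)
    return HomogeneousParams(d.total_detections / (d.n * d.j))


def normalized_p(d: DiscoveryMatrix) -> HomogeneousParams:
    """Hertzum-Jacobsen normalization of the naive estimate.

    Rescales p-hat from its achievable range [1/n, 1] onto [0, 1]; the
    boundary case p-hat = 1/n maps to 0 and makes the deduced m infinite.
    """
    _require_nondegenerate(d)
    if d.n < 2:
        raise UndefinedEstimateError("normalized estimator needs n >= 2")
    p = naive_p(d).p
    return HomogeneousParams((p - 1.0 / d.n) / (1.0 - 1.0 / d.n))


def _gt_adjustment(d: DiscoveryMatrix) -> float:
    # proportion of singleton problems among all detection events
    singletons = int((d.column_sums == 1).sum())
    return singletons / d.total_detections


def good_turing_p(d: DiscoveryMatrix) -> HomogeneousParams:
    """Good-Turing discounted estimate p-hat / (1 + GT).

    GT is the share of singletons (problems seen exactly once) among all
    detection events; discounting enlarges the probability space to allow
    for unseen problems.
    """
    _require_nondegenerate(d)
    return HomogeneousParams(naive_p(d).p / (1.0 + _gt_adjustment(d)))


def double_deflation_p(d: DiscoveryMatrix) -> HomogeneousParams:
    """Lewis's average of the Good-Turing and double-deflation terms:

        1/2 * p/(1+GT)  +  1/2 * (p - 1/n) * (1 - 1/n)
    """
    _require_nondegenerate(d)
    if d.n < 2:
        raise UndefinedEstimateError("double-deflation needs n >= 2")
    p = naive_p(d).p
    gt_term = p / (1.0 + _gt_adjustment(d))
    deflation = (p - 1.0 / d.n) * (1.0 - 1.0 / d.n)
    return HomogeneousParams(0.5 * gt_term + 0.5 * deflation)


def discovery_proportion(p: float, n: int) -> float:
    """P(X > 0) = 1 - (1-p)^n: chance a problem is seen by >= 1 of n users."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return -math.expm1(n * math.log1p(-p)) if p < 1.0 else 1.0


def deduce_m(j: int, p: float, n: int) -> float:
    """Invert j = (1 - (1-p)^n) * m for m.

    Returns ``inf`` when the discovery proportion is zero (p = 0), the
    pathology of the normalized estimator on all-singleton matrices.
    """
    if j < 1:
        raise UndefinedEstimateError("deduce_m needs j >= 1")
    frac = discovery_proportion(p, n)
    return math.inf if frac == 0.0 else j / frac


def zt_binomial_pmf(k, n: int, p: float):
    """Zero-truncated binomial pmf: Bin(n,p) conditioned on k > 0."""
    k = np.asarray(k)
    base = stats.binom.pmf(k, n, p)
    denom = -math.expm1(n * math.log1p(-p)) if 0.0 < p <= 1.0 else 0.0
    out = np.where(k > 0, base / denom if denom > 0 else np.nan, 0.0)
    return out if out.ndim else float(out)


_EPS = 1e-9  # optimization bounds for p


def fit_zt_binomial(column_sums, n: int) -> tuple[HomogeneousParams, dict]:
    """Maximum-likelihood p under the zero-truncated binomial margin model.

    The likelihood is unimodal in p for fixed data, so a bounded 1-D
    search on (eps, 1-eps) suffices.  Returns the fit and a diagnostics
    dict (converged flag, log-likelihood).
    """
    ks = np.asarray(column_sums, dtype=float)
    if ks.size == 0:
        raise UndefinedEstimateError("empty margin")
    if ((ks < 1) | (ks > n)).any():
        raise ValueError("column sums must lie in 1..n")

    def nll(p: float) -> float:
        logp0 = n * math.log1p(-p)
        ll = (
            np.sum(stats.binom.logpmf(ks, n, p))
            - ks.size * math.log(-math.expm1(logp0))
        )
        return -ll

    res = optimize.minimize_scalar(
        nll, bounds=(_EPS, 1.0 - _EPS), method="bounded",
        options={"xatol": 1e-12},
    )
    diagnostics = {"converged": bool(res.success), "loglik": -float(res.fun)}
    return HomogeneousParams(float(res.x)), diagnostics


_P_ESTIMATORS = {
    "naive": naive_p,
    "normalized": normalized_p,
    "gt": good_turing_p,
    "dd": double_deflation_p,
}

MARGIN_METHODS = tuple(_P_ESTIMATORS) + ("ztb",)


def estimate_m_margin(d: DiscoveryMatrix, method: str) -> EstimateResult:
    """Run one margin-based method end to end: fit p, deduce m.

    ``method`` is one of ``naive``, ``normalized``, ``gt``, ``dd``
    (plug-in estimates) or ``ztb`` (zero-truncated binomial MLE).
    """
    _require_nondegenerate(d)
    diagnostics: dict = {}
    if method == "ztb":
        params, diagnostics = fit_zt_binomial(d.column_sums, d.n)
        if not diagnostics["converged"]:
            return EstimateResult(
                method=method, m_hat=math.nan, p_hat=params.p,
                flags=("fit_failure",), diagnostics=diagnostics,
            )
    elif method in _P_ESTIMATORS:
        params = _P_ESTIMATORS[method](d)
    else:
        raise ValueError(f"unknown margin method {method!r}")
    m_hat = deduce_m(d.j, params.p, d.n)
    flags = ("infinite",) if math.isinf(m_hat) else ()
    return EstimateResult(
        method=method, m_hat=m_hat, p_hat=params.p, flags=flags,
        diagnostics=diagnostics,
    )
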