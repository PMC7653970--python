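"""Seeded generation of discovery matrices under the logit-normal model.

Each simulated study draws per-problem detection probabilities
p_l = logistic(z_l), z_l ~ Normal(mu, sigma), then Bernoulli cells, and
truncates the zero columns to obtain the observed matrix.  Replicates use
counter-based substreams keyed by (seed, setting, replicate index), so
any replicate can be regenerated independently and in any order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit

from .discovery_matrix import CompleteMatrix, DiscoveryMatrix, truncate_zero_columns
from .lnbzt import HeterogeneityParams, q_vector

__all__ = [
    "SimulationSetting",
    "simulate_complete",
    "simulate_observed",
    "expected_detection_rate",
    "expected_discovery_fraction",
]


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of a simulation design.

    ``mu`` is on the logit scale (e.g. logit(0.1) for an average
    detection probability near 10%); ``S`` is the number of replicates.
    """

    m: int
    mu: float
    sigma: float
    n: int
    S: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.S < 1:
            raise ValueError("m, n and S must all be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def from_probability(
        cls, m: int, p: float, sigma: float, n: int, S: int = 20_000, seed: int = 0
    ) -> "SimulationSetting":
        """Build a setting giving mu as a probability (logit applied)."""
        return cls(m=m, mu=float(logit(p)), sigma=sigma, n=n, S=S, seed=seed)

    @property
    def params(self) -> HeterogeneityParams:
        return HeterogeneityParams(self.mu, self.sigma)

    def with_seed(self, seed: int) -> "SimulationSetting":
        return replace(self, seed=seed)

    def stream(self, replicate_index: int) -> np.random.Generator:
        """Independent RNG substream for one replicate."""
        tag = f"{self.m}|{self.mu:.12g}|{self.sigma:.12g}|{self.n}".encode()
        setting_hash = zlib.crc32(tag)
        ss = np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(setting_hash, int(replicate_index))
        )
        return np.random.default_rng(ss)


def simulate_complete(
    setting: SimulationSetting, replicate_index: int = 0
) -> CompleteMatrix:
    """Draw one complete n-by-m matrix; ground truth attached."""
    rng = setting.stream(replicate_index)
    z = setting.mu + setting.sigma * rng.standard_normal(setting.m)
    probs = expit(z)
    cells = (rng.random((setting.n, setting.m)) < probs).astype(np.int8)
    return CompleteMatrix(cells, truth=setting.params, detect_probs=probs)


def simulate_observed(
    setting: SimulationSetting, replicate_index: int = 0
) -> DiscoveryMatrix:
    """Complete draw followed by zero-column truncation; j <= m always.

    An all-zero draw yields the degenerate j = 0 matrix; callers count
    and skip those (their probability is negligible at realistic
    settings but not zero).
    """
    return truncate_zero_columns(simulate_complete(setting, replicate_index))


def expected_detection_rate(params: HeterogeneityParams) -> float:
    """E[p] under the logit-normal, by quadrature — the expected cell mean
    of a complete matrix."""
    return params.mean_p


def expected_discovery_fraction(params: HeterogeneityParams, n: int) -> float:
    """E[1 - (1-p)^n]: expected fraction of the m problems discovered by
    n participants (the heterogeneous analogue of the shifted-geometric
    discovery proportion)."""
    return 1.0 - float(q_vector(n, params)[0])
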