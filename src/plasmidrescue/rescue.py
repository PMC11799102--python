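"""Population-level rescue probability and rescue-time distribution.

The resident wild-type population declines deterministically,
``N(t) = N0 exp(s(n,0) t)``.  Each division of a wild-type cell produces a
successfully establishing mutation with probability ``u * n * P_est`` (at most
one mutation per division), so successful mutations form an inhomogeneous
Poisson process with intensity ``u n P_est lambda_0 N(t)``.  Rescue occurs when
this process has at least one event:

    P_rescue = 1 - exp(-u n N0 (1 + s0) / |s0| * P_est),      s0 = s(n, 0) < 0,

and the (rescue-conditioned) time of the first successful mutation has the
closed-form CDF obtained by truncating the intensity integral at ``t``.
Rescue depends on ``u`` and ``N0`` only through their product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .branching import establishment_probability
from .model_core import FitnessModel

__all__ = [
    "RescueSetting",
    "wildtype_decay",
    "rescue_probability",
    "rescue_time_cdf",
    "median_rescue_time",
    "mean_rescue_time",
    "sample_rescue_times",
]


@dataclass(frozen=True)
class RescueSetting:
    """Parameters of one rescue scenario.

    ``u`` and ``N0`` may be given separately, or only their product ``uN0``
    (the analytic formulas depend on nothing else); ``P_est`` may be supplied
    or is computed from the model and replication mode on first use.
    """

    model: FitnessModel
    mode: str = "regular"
    u: Optional[float] = None
    N0: Optional[float] = None
    uN0: Optional[float] = None
    P_est: Optional[float] = None

    def __post_init__(self):
        if self.uN0 is None and (self.u is None or self.N0 is None):
            raise ValueError("provide either uN0 or both u and N0")
        if self.u is not None and self.u < 0:
            raise ValueError(f"mutation probability u must be >= 0, got {self.u}")
        if self.N0 is not None and self.N0 <= 0:
            raise ValueError(f"initial population N0 must be > 0, got {self.N0}")
        if self.model.s(0) >= 0:
            raise ValueError("rescue scenario requires a declining wild type: s(n,0) < 0")

    @property
    def mutational_input(self) -> float:
        """The product ``u * N0``."""
        if self.uN0 is not None:
            return float(self.uN0)
        return float(self.u * self.N0)

    def establishment(self) -> float:
        if self.P_est is not None:
            return float(self.P_est)
        return establishment_probability(self.model, self.mode)


def wildtype_decay(setting: RescueSetting, t: float) -> float:
    """Deterministic wild-type population size ``N0 exp(s(n,0) t)``.

    ``N0`` defaults to 1 when only the product ``uN0`` is specified (the decay
    curve then gives the declining fraction)."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    N0 = setting.N0 if setting.N0 is not None else 1.0
    return N0 * np.exp(setting.model.s(0) * t)


def _exponent(setting: RescueSetting) -> float:
    """The full Poisson exponent ``u n N0 (1+s0)/|s0| P_est``."""
    s0 = setting.model.s(0)
    return (setting.mutational_input * setting.model.n
            * (1.0 + s0) / abs(s0) * setting.establishment())


def rescue_probability(setting: RescueSetting) -> float:
    """Probability that at least one successfully establishing mutation occurs
    before the wild-type population is gone."""
    return float(-np.expm1(-_exponent(setting)))


def rescue_time_cdf(setting: RescueSetting, t: float) -> float:
    """CDF of the time ``T`` of the first successful rescue mutation,
    conditional on rescue occurring."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    p_rescue = rescue_probability(setting)
    if p_rescue == 0.0:
        raise ValueError("rescue probability is 0; the conditional time "
                         "distribution is undefined")
    s0 = setting.model.s(0)
    partial = _exponent(setting) * (1.0 - np.exp(s0 * t))
    return float(-np.expm1(-partial) / p_rescue)


def median_rescue_time(setting: RescueSetting) -> float:
    """Median of the conditional rescue-time distribution (by bisection)."""
    hi = 1.0
    while rescue_time_cdf(setting, hi) < 0.5:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("median bracket search failed")
    return float(brentq(lambda t: rescue_time_cdf(setting, t) - 0.5, 0.0, hi,
                        xtol=1e-10))


def mean_rescue_time(setting: RescueSetting) -> float:
    """Mean of the conditional rescue-time distribution,
    ``int_0^inf (1 - CDF(t)) dt`` by adaptive quadrature."""
    p_rescue = rescue_probability(setting)
    if p_rescue == 0.0:
        raise ValueError("rescue probability is 0; the conditional time "
                         "distribution is undefined")
    val, _ = quad(lambda t: 1.0 - rescue_time_cdf(setting, t), 0.0, np.inf,
                  limit=200, epsabs=1e-10, epsrel=1e-10)
    return float(val)


def sample_rescue_times(setting: RescueSetting, size: int, seed: int) -> np.ndarray:
    """Draw conditional rescue times by inverse-CDF sampling."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=size)
    p_rescue = rescue_probability(setting)
    if p_rescue == 0.0:
        raise ValueError("rescue probability is 0; nothing to sample")
    s0 = setting.model.s(0)
    a = _exponent(setting)
    # invert  u = (1 - exp(-a (1 - e^{s0 t}))) / P_rescue
    inner = 1.0 + np.log1p(-u * p_rescue) / a
    return np.log(inner) / s0
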