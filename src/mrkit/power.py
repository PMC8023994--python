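"""Power for MR with a binary outcome.

The non-centrality approximation used by the mRnd web calculator
(Brion/Burgess style): for a true OR per SD of exposure ``or_alt``, an
instrument explaining a fraction ``r2_xz`` of exposure variance, case
fraction ``K`` and total sample size ``n``,

    power = Phi( |ln or_alt| * sqrt(n * r2_xz * K * (1-K)) - z_{1-alpha/2} ).

The constants are exposed (plain functions of the spec) so alternative
approximations can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.optimize import brentq

__all__ = ["PowerSpec", "mr_power_binary", "detectable_or", "required_r2"]


@dataclass(frozen=True)
class PowerSpec:
    n: int  # total sample size
    r2_xz: float  # exposure variance explained by the instrument
    K: float  # case fraction
    or_alt: float  # alternative-hypothesis OR per SD of exposure
    alpha: float = 0.05  # two-sided level

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.r2_xz < 1.0:
            raise ValueError("r2_xz must lie in (0,1)")
        if not 0.0 < self.K < 1.0:
            raise ValueError("K must lie in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")


def mr_power_binary(spec: PowerSpec) -> float:
    """Two-sided power in [0,1] under the NCP approximation above."""
    ncp = abs(math.log(spec.or_alt)) * math.sqrt(
        spec.n * spec.r2_xz * spec.K * (1.0 - spec.K)
    )
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


def detectable_or(
    n: int, r2_xz: float, K: float, *, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Smallest OR > 1 detectable with the given power (root of the formula)."""
    f = lambda or_alt: mr_power_binary(PowerSpec(n, r2_xz, K, or_alt, alpha)) - power
    return float(brentq(f, 1.0 + 1e-9, 100.0))


def required_r2(
    n: int, K: float, or_alt: float, *, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Instrument strength r² needed for the given power against ``or_alt``."""
    f = lambda r2: mr_power_binary(PowerSpec(n, r2, K, or_alt, alpha)) - power
    return float(brentq(f, 1e-12, 1.0 - 1e-12))
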