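"""Result containers shared across MR estimators."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from any MR method.

    ``estimate``/``se``/``ci`` are on the estimation scale (``scale`` is one
    of ``log_odds_per_sd``, ``risk_difference_per_sd``, ``linear_per_sd``);
    odds ratios are exponentiated only at the reporting layer via
    :meth:`or_ci`.
    """

    method: str
    estimate: float
    se: float
    p: float
    scale: str
    n_snps: int | None = None
    n_individuals: int | None = None
    ci: tuple[float, float] | None = None
    notes: str = ""

    def __post_init__(self):
        if self.ci is None:
            object.__setattr__(
                self, "ci", (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)
            )

    def or_ci(self) -> tuple[float, float, float]:
        """(OR, lower, upper) — only meaningful on the log-odds scale."""
        return math.exp(self.estimate), math.exp(self.ci[0]), math.exp(self.ci[1])


def wald_p(estimate: float, se: float) -> float:
    return 2.0 * stats.norm.sf(abs(estimate) / se)


@dataclass
class DiagnosticStats:
    """Instrument-strength and pleiotropy diagnostics.

    ``sargan`` / ``cochran_q`` are None when not applicable (exactly
    identified model / single SNP).
    """

    first_stage_F: float | None = None
    conditional_F: dict | None = None  # exposure name -> F
    sargan: float | None = None
    sargan_df: int | None = None
    sargan_p: float | None = None
    cochran_q: float | None = None
    cochran_q_df: int | None = None
    cochran_q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
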