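"""Factorial MR: 2x2 median split of two genetic risk scores.

Individuals are cross-classified as below/above the median of each GRS
(values equal to the median count as high), giving four categories with
the low/low group as reference.  Logistic regression of the outcome on
three category dummies plus covariates tests whether genetically proxied
high levels of both exposures confer more risk than either alone — under
additive log-odds effects the high/high log-OR is the sum of the two
single-high log-ORs.  A continuous GRS x GRS interaction model is provided
as a supplementary, more efficient check (median dichotomization discards
information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimates import Z95
from .simulate import IndividualCohort
from .onesample import _resolve_covariates, _resolve_trait

__all__ = ["FactorialResult", "factorial_split", "factorial_logistic", "grs_interaction"]

CATEGORIES = ("low/low", "high/low", "low/high", "high/high")


@dataclass
class FactorialResult:
    """Per-category counts and ORs versus the low/low reference."""

    table: pd.DataFrame  # category, n, cases, or, ci_low, ci_high, p
    medians: tuple[float, float]

    def log_or(self, category: str) -> tuple[float, float]:
        row = self.table.set_index("category").loc[category]
        return float(row["log_or"]), float(row["log_or_se"])


def factorial_split(grs1: np.ndarray, grs2: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Four-level category vector from median splits of two scores.

    high = score >= median (ties go high).  Categories: low/low, high/low,
    low/high, high/high, where the first position refers to ``grs1``.
    """
    g1, g2 = np.asarray(grs1, float), np.asarray(grs2, float)
    if g1.shape != g2.shape:
        raise ValueError("score vectors must have the same length")
    m1, m2 = float(np.median(g1)), float(np.median(g2))
    if np.all(g1 == g1[0]) or np.all(g2 == g2[0]):
        raise ValueError("constant GRS: median split impossible")
    hi1, hi2 = g1 >= m1, g2 >= m2
    cats = np.where(
        hi1 & hi2, "high/high", np.where(hi1, "high/low", np.where(hi2, "low/high", "low/low"))
    )
    return cats, (m1, m2)


def factorial_logistic(
    cohort: IndividualCohort,
    categories: np.ndarray,
    outcome="oa",
    covariates=("sex",),
    *,
    medians: tuple[float, float] = (float("nan"), float("nan")),
) -> FactorialResult:
    """Logistic regression of the outcome on category dummies vs low/low."""
    y = _resolve_trait(cohort, outcome)
    C = _resolve_covariates(cohort, covariates)
    counts = {c: int(np.sum(categories == c)) for c in CATEGORIES}
    empty = [c for c in CATEGORIES if counts[c] == 0]
    if empty:
        raise ValueError(f"empty factorial categories {empty}; counts: {counts}")
    dummies = np.column_stack([(categories == c).astype(float) for c in CATEGORIES[1:]])
    W = np.column_stack([np.ones(len(y))] + ([C] if C is not None else []))
    fit = sm.Logit(y, np.column_stack([dummies, W])).fit(disp=0, maxiter=200)

    rows = [
        {
            "category": "low/low",
            "n": counts["low/low"],
            "cases": int(y[categories == "low/low"].sum()),
            "log_or": 0.0,
            "log_or_se": float("nan"),
            "or": 1.0,
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "p": float("nan"),
        }
    ]
    for i, c in enumerate(CATEGORIES[1:]):
        b, se = float(fit.params[i]), float(fit.bse[i])
        rows.append(
            {
                "category": c,
                "n": counts[c],
                "cases": int(y[categories == c].sum()),
                "log_or": b,
                "log_or_se": se,
                "or": math.exp(b),
                "ci_low": math.exp(b - Z95 * se),
                "ci_high": math.exp(b + Z95 * se),
                "p": float(fit.pvalues[i]),
            }
        )
    return FactorialResult(table=pd.DataFrame(rows), medians=medians)


def grs_interaction(
    cohort: IndividualCohort,
    grs1: np.ndarray,
    grs2: np.ndarray,
    outcome="oa",
    covariates=("sex",),
) -> dict:
    """Continuous GRS x GRS interaction (experimental alternative to the split)."""
    y = _resolve_trait(cohort, outcome)
    C = _resolve_covariates(cohort, covariates)
    g1 = (grs1 - grs1.mean()) / grs1.std()
    g2 = (grs2 - grs2.mean()) / grs2.std()
    W = np.column_stack([np.ones(len(y))] + ([C] if C is not None else []))
    X = np.column_stack([g1 * g2, g1, g2, W])
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b, se = float(fit.params[0]), float(fit.bse[0])
    return {"coef": b, "se": se, "or": math.exp(b), "p": float(fit.pvalues[0])}
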