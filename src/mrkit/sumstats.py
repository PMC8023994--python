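"""GWAS summary-statistic records: reading, harmonization and pre-processing.

The atoms of summary-data MR are per-SNP association records (beta, SE, p,
effect-allele frequency, sample size) for an exposure and an outcome.  This
module reads such tables from TSV/CSV, aligns an exposure/outcome pair of
records to a common effect allele, reconstructs betas from p-values when a
meta-analysis reports only z-score directions (the Rietveld-style
reconstruction used when betas and SEs cannot be pooled across assays), and
computes the variance in a trait explained by a SNP (the quantity compared
by Steiger directionality filtering).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SNPAssociation",
    "HarmonizedSNP",
    "SumstatsError",
    "RowError",
    "read_sumstats",
    "harmonize",
    "harmonize_tables",
    "beta_from_p",
    "beta_to_p",
    "variance_explained",
    "write_harmonized",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset(_COMPLEMENT)

#: EAF window inside which a palindromic (A/T or G/C) SNP cannot be aligned
#: by frequency and is dropped from harmonization.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table or record."""


class RowError(SumstatsError):
    """A single data row violated an invariant; carries the line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's per-allele association with one trait.

    ``beta`` is per effect-allele copy: SD units for a continuous trait,
    log-odds for a binary one.  ``other_allele`` and ``eaf`` may be None
    when the source table does not print them; operations that need them
    (allele harmonization, beta reconstruction) will say so.
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    p: float
    n: int | None = None
    eaf: float | None = None
    other_allele: str | None = None
    trait_type: str = "continuous"  # or "binary" (beta on the log-odds scale)

    def __post_init__(self):
        if self.effect_allele not in _BASES:
            raise SumstatsError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not A/C/G/T"
            )
        if self.other_allele is not None:
            if self.other_allele not in _BASES:
                raise SumstatsError(
                    f"{self.snp_id}: other allele {self.other_allele!r} is not A/C/G/T"
                )
            if self.other_allele == self.effect_allele:
                raise SumstatsError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise SumstatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise SumstatsError(f"{self.snp_id}: eaf must lie strictly in (0,1), got {self.eaf}")
        if not 0.0 < self.p <= 1.0:
            raise SumstatsError(f"{self.snp_id}: p must lie in (0,1], got {self.p}")
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"{self.snp_id}: unknown trait_type {self.trait_type!r}")
        self._check_z_consistency()

    def _check_z_consistency(self) -> None:
        # |beta|/se should agree with the z implied by p to ~10% relative
        # tolerance; tables round aggressively so only warn beyond that.
        if self.p >= 1.0 or self.p <= 1e-300:
            return
        z_p = stats.norm.isf(self.p / 2.0)
        z_obs = abs(self.beta) / self.se
        if z_p > 0.5 and abs(z_obs - z_p) > 0.10 * z_p:
            warnings.warn(
                f"{self.snp_id}: |beta|/se = {z_obs:.2f} disagrees with the z-score "
                f"implied by p ({z_p:.2f}) by more than 10%",
                stacklevel=3,
            )

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        if self.other_allele is None:
            return False
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedSNP:
    """An exposure/outcome pair of associations on a shared effect allele.

    Carries the Wald-ratio ingredients: gamma (SNP->exposure) with its SE
    and Gamma (SNP->outcome, log-odds for a binary outcome) with its SE.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    eaf: float | None = None
    flipped: bool = False
    n_exposure: int | None = None
    n_outcome: int | None = None

    def __post_init__(self):
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise SumstatsError(f"{self.snp_id}: harmonized SEs must be > 0")


_MANDATORY = ("snp_id", "effect_allele", "beta", "se", "p")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_type: str = "continuous",
    or_scale: bool = False,
    se_on_or_scale: bool = False,
    n: int | None = None,
    strict: bool = False,
) -> list[SNPAssociation]:
    """Read a TSV/CSV summary-statistics table into association records.

    ``column_map`` maps field names (``snp_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``p``, ``n``) to column
    names in the file.  With ``or_scale`` the beta column holds an odds
    ratio and is log-transformed; the SE column is taken to be on the
    log-odds scale already unless ``se_on_or_scale`` (then it is converted
    by the delta method, se_log = se_OR / OR).

    Rows violating record invariants are reported with their line number;
    by default they are skipped with a warning (``strict=True`` raises).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cmap = dict(column_map or {})
    for fieldname in _MANDATORY:
        col = cmap.get(fieldname, fieldname)
        if col not in df.columns:
            raise SumstatsError(f"{path.name}: missing mandatory column {col!r} (for {fieldname})")

    records: list[SNPAssociation] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            get = lambda f, default=None: row[cmap.get(f, f)] if cmap.get(f, f) in df.columns else default
            beta = float(get("beta"))
            se = float(get("se"))
            if or_scale:
                if beta <= 0:
                    raise SumstatsError(f"odds ratio must be > 0, got {beta}")
                if se_on_or_scale:
                    se = se / beta
                beta = math.log(beta)
            raw_n = get("n", n)
            raw_eaf = get("eaf")
            raw_oa = get("other_allele")
            rec = SNPAssociation(
                snp_id=str(get("snp_id")),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=None if raw_oa is None or pd.isna(raw_oa) else str(raw_oa).upper(),
                eaf=None if raw_eaf is None or pd.isna(raw_eaf) else float(raw_eaf),
                beta=beta,
                se=se,
                p=float(get("p")),
                n=None if raw_n is None or pd.isna(raw_n) else int(raw_n),
                trait_type=trait_type,
            )
        except (SumstatsError, TypeError) as exc:
            err = RowError(line, str(exc))
            if strict:
                raise err from exc
            warnings.warn(str(err), stacklevel=2)
            continue
        except ValueError as exc:  # unparseable numeric
            err = RowError(line, f"unparseable value: {exc}")
            if strict:
                raise err from exc
            warnings.warn(str(err), stacklevel=2)
            continue
        records.append(rec)
    return records


def _alleles(rec: SNPAssociation) -> tuple[str, str | None]:
    return rec.effect_allele, rec.other_allele


def harmonize(exposure: SNPAssociation, outcome: SNPAssociation) -> HarmonizedSNP | None:
    """Align an exposure/outcome record pair to the exposure's effect allele.

    If the outcome's effect allele matches the exposure's other allele
    (directly or as strand complement), the outcome beta sign and EAF are
    flipped and ``flipped=True`` recorded.  Palindromic SNPs (A/T, G/C)
    with EAF inside the ambiguous window are dropped (returns None with a
    warning) because strand cannot be resolved by frequency.
    """
    if exposure.snp_id != outcome.snp_id:
        raise SumstatsError(f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")

    e_ea, e_oa = _alleles(exposure)
    o_ea, o_oa = _alleles(outcome)

    if exposure.is_palindromic():
        eafs = [x for x in (exposure.eaf, outcome.eaf) if x is not None]
        lo, hi = PALINDROMIC_EAF_WINDOW
        if not eafs or any(lo <= f <= hi for f in eafs):
            warnings.warn(
                f"{exposure.snp_id}: palindromic SNP with ambiguous EAF; excluded",
                stacklevel=2,
            )
            return None
        # align by frequency: same minor/major orientation -> same allele
        same = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        return _build(exposure, outcome, flipped=not same)

    # direct match
    if o_ea == e_ea and (e_oa is None or o_oa is None or o_oa == e_oa):
        return _build(exposure, outcome, flipped=False)
    if e_oa is not None and o_ea == e_oa and (o_oa is None or o_oa == e_ea):
        return _build(exposure, outcome, flipped=True)
    # strand complement
    if o_ea == _COMPLEMENT[e_ea] and (
        e_oa is None or o_oa is None or o_oa == _COMPLEMENT[e_oa]
    ):
        return _build(exposure, outcome, flipped=False)
    if e_oa is not None and o_ea == _COMPLEMENT[e_oa] and (
        o_oa is None or o_oa == _COMPLEMENT[e_ea]
    ):
        return _build(exposure, outcome, flipped=True)
    raise SumstatsError(
        f"{exposure.snp_id}: irreconcilable alleles "
        f"exposure {e_ea}/{e_oa} vs outcome {o_ea}/{o_oa}"
    )


def _build(exposure: SNPAssociation, outcome: SNPAssociation, flipped: bool) -> HarmonizedSNP:
    Gamma = -outcome.beta if flipped else outcome.beta
    eaf = exposure.eaf
    if eaf is None and outcome.eaf is not None:
        eaf = 1.0 - outcome.eaf if flipped else outcome.eaf
    return HarmonizedSNP(
        snp_id=exposure.snp_id,
        gamma=exposure.beta,
        se_gamma=exposure.se,
        Gamma=Gamma,
        se_Gamma=outcome.se,
        eaf=eaf,
        flipped=flipped,
        n_exposure=exposure.n,
        n_outcome=outcome.n,
    )


def harmonize_tables(
    exposure: Iterable[SNPAssociation], outcome: Iterable[SNPAssociation]
) -> list[HarmonizedSNP]:
    """Harmonize two record lists on shared snp_ids, dropping unmatched SNPs."""
    out_by_id = {r.snp_id: r for r in outcome}
    result = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        h = harmonize(exp, out)
        if h is not None:
            result.append(h)
    return result


def beta_from_p(p: float, sign: float, eaf: float, n: int) -> tuple[float, float]:
    """Reconstruct (beta, se) in SD units from a two-sided p-value.

    z = sign * Phi^-1(1 - p/2); se = 1/sqrt(2 f (1-f) (n + z^2)); beta = z*se.
    Used when a z-score meta-analysis reports no pooled betas.
    """
    if not 0.0 < p <= 1.0:
        if p == 0.0:
            raise SumstatsError("p = 0: supply a z-score directly instead of a p-value")
        raise SumstatsError(f"p must lie in (0,1], got {p}")
    if not 0.0 < eaf < 1.0:
        raise SumstatsError(f"eaf must lie strictly in (0,1), got {eaf}")
    if n < 2:
        raise SumstatsError(f"n must be >= 2, got {n}")
    z = math.copysign(1.0, sign) * stats.norm.isf(p / 2.0)
    se = 1.0 / math.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z * z))
    return z * se, se


def beta_to_p(beta: float, se: float) -> float:
    """Two-sided normal p-value from an estimate and its SE.

    Floored at 1e-300 (the conventional GWAS cap) so records built from
    extreme z-scores stay representable.
    """
    return max(2.0 * stats.norm.sf(abs(beta) / se), 1e-300)


def variance_explained(
    assoc: SNPAssociation | None = None,
    *,
    beta: float | None = None,
    se: float | None = None,
    n: int | None = None,
) -> float:
    """Fraction of trait variance explained by one SNP: r2 = t^2/(t^2 + n - 2).

    For binary traits this is computed on the log-odds scale — an
    approximation to a liability-scale r2, adequate for the ordinal
    comparison Steiger filtering makes.
    """
    if assoc is not None:
        beta, se, n = assoc.beta, assoc.se, assoc.n
    if beta is None or se is None or n is None:
        raise SumstatsError("variance_explained needs beta, se and n")
    if n < 3:
        raise SumstatsError(f"n must be >= 3, got {n}")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def write_harmonized(harmonized: Sequence[HarmonizedSNP], path: str | Path) -> None:
    """Write a harmonized exposure/outcome table as TSV with a `flipped` column."""
    df = pd.DataFrame(
        {
            "snp_id": [h.snp_id for h in harmonized],
            "gamma": [h.gamma for h in harmonized],
            "se_gamma": [h.se_gamma for h in harmonized],
            "Gamma": [h.Gamma for h in harmonized],
            "se_Gamma": [h.se_Gamma for h in harmonized],
            "eaf": [h.eaf for h in harmonized],
            "flipped": [h.flipped for h in harmonized],
        }
    )
    df.to_csv(path, sep="\t", index=False)
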