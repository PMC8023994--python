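"""Config-driven orchestration of the full MR workflow.

``run_study`` executes, on one synthetic cohort (or user-supplied summary
statistics for the two-sample stage): simulation, the staged observational
logistic models (with a sex-stratified repeat), one-sample MR under three
instrument sets (all SNPs, excluding the IGF-BP3-associated trio, the
single intronic SNP), two-sample MR with the full diagnostic battery,
multivariable MR with the mediator GRS, factorial MR, and the binary-MR
power calculation.  Each stage writes a TSV whose header comment carries
the seed, a config hash and the package version; any stage failure aborts
with the stage name while prior outputs persist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimates import MREstimate
from .factorial import factorial_logistic, factorial_split
from .mvmr import mvmr_tsls
from .observational import staged_logistic, stratified_run
from .onesample import InstrumentSet, build_grs, instrument_covariate_check, tsls, two_stage_logistic
from .power import PowerSpec, mr_power_binary
from .simulate import (
    CohortConfig,
    OutcomeSpec,
    bmi_like_snps,
    calibrate_intercept_empirical,
    cohort_to_sumstats,
    igf1_like_snps,
    simulate_cohort,
    write_cohort,
)
from .sumstats import harmonize_tables, read_sumstats
from .twosample import ivw, mr_egger, steiger_filter, weighted_median
from .datasets import IGFBP3_SNPS, INTRONIC_IGF1_SNP

log = logging.getLogger("mrkit")


@dataclass
class RunConfig:
    """Flat configuration for :func:`run_study` (YAML-loadable)."""

    seed: int = 20201007
    n_individuals: int = 20_000
    theta: float = math.log(1.35)
    prevalence: float = 0.032
    mediator_theta: float = 0.2
    mediator_effect: float = 0.1
    pleiotropy: float = 0.0
    confounder_on_exposure: float = 0.3
    confounder_on_outcome: float = 0.2
    n_mediator_snps: int = 63
    # optional user summary statistics for the two-sample stage
    exposure_sumstats: str | None = None
    outcome_sumstats: str | None = None
    # generic row filter: drop rows where this boolean phenotype column is true
    exclude_flag: str | None = None
    bootstrap: int = 0
    effects_model: str = "auto"
    power: dict = field(
        default_factory=lambda: {"r2_xz": 0.02, "K": 0.032, "or_alt": 1.35, "alpha": 0.05}
    )
    output_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("exposure_sumstats", "outcome_sumstats"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _estimate_row(label: str, est: MREstimate) -> dict:
    row = {
        "analysis": label,
        "method": est.method,
        "estimate": est.estimate,
        "se": est.se,
        "ci_low": est.ci[0],
        "ci_high": est.ci[1],
        "p": est.p,
        "scale": est.scale,
        "n_snps": est.n_snps,
        "n_individuals": est.n_individuals,
    }
    if est.scale == "log_odds_per_sd":
        o, lo, hi = est.or_ci()
        row.update({"or": o, "or_ci_low": lo, "or_ci_high": hi})
    return row


class StudyRunner:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._meta = (
            f"# seed={config.seed} config_hash={config.hash()} mrkit_version={__version__}"
        )

    def _write(self, df: pd.DataFrame, name: str) -> None:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(self._meta + "\n")
            df.to_csv(fh, sep="\t", index=False)
        log.info("wrote %s (%d rows)", path, len(df))

    def run(self) -> dict:
        stages = [
            ("simulate", self._stage_simulate),
            ("observational", self._stage_observational),
            ("onesample", self._stage_onesample),
            ("twosample", self._stage_twosample),
            ("mvmr", self._stage_mvmr),
            ("factorial", self._stage_factorial),
            ("power", self._stage_power),
        ]
        results = {}
        for name, fn in stages:
            log.info("stage %s ...", name)
            try:
                results[name] = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return results

    # -- stages ----------------------------------------------------------

    def _stage_simulate(self):
        c = self.config
        base = CohortConfig(
            n_individuals=c.n_individuals,
            snps=igf1_like_snps(alpha=c.pleiotropy),
            mediator_snps=bmi_like_snps(c.n_mediator_snps),
            outcomes=[
                OutcomeSpec("oa", -3.0, theta=c.theta, mediator_theta=c.mediator_theta)
            ],
            mediator_effect=c.mediator_effect,
            confounder_on_exposure=c.confounder_on_exposure,
            confounder_on_outcome=c.confounder_on_outcome,
            seed=c.seed,
        )
        intercept = calibrate_intercept_empirical(base, "oa", c.prevalence)
        base.outcomes = [
            OutcomeSpec("oa", intercept, theta=c.theta, mediator_theta=c.mediator_theta)
        ]
        self.cohort = simulate_cohort(base)
        self.table = self.cohort.to_frame()
        if c.exclude_flag:
            keep = ~self.table[c.exclude_flag].astype(bool)
            log.info("row filter %s drops %d rows", c.exclude_flag, int((~keep).sum()))
            self.table = self.table[keep].reset_index(drop=True)
        write_cohort(self.cohort, self.outdir / "cohort")
        self.exposure_stats = cohort_to_sumstats(
            self.cohort, "exposure", snps=[s.snp_id for s in base.snps]
        )
        self.instruments = InstrumentSet.from_sumstats(self.exposure_stats, label="all")
        return {"prevalence": self.cohort.truth.prevalence["oa"]}

    def _stage_observational(self):
        stages = [
            ("unadjusted", []),
            ("age_sex", ["sex"]),
            ("age_sex_cov", ["sex", "cov1"]),
            ("age_sex_cov_mediator", ["sex", "cov1", "mediator"]),
        ]
        res = staged_logistic(self.table, "exposure_measured", "oa", stages)
        rows = [dataclasses.asdict(r) for r in res]
        self._write(pd.DataFrame(rows), "observational.tsv")
        strat = stratified_run(
            self.table,
            "sex",
            lambda sub: staged_logistic(sub, "exposure_measured", "oa", stages[:1])[0],
            outcome="oa",
        )
        self._write(
            pd.DataFrame(
                [dict(stratum=k, **dataclasses.asdict(v)) for k, v in strat.items()]
            ),
            "observational_stratified.tsv",
        )
        return res

    def _stage_onesample(self):
        sets = {
            "all": self.instruments,
            "excl_igfbp3": self.instruments.subset(
                [s for s in self.instruments.snp_ids if s not in IGFBP3_SNPS],
                "excl-IGFBP3",
            ),
            "single_intronic": self.instruments.subset([INTRONIC_IGF1_SNP], "single-intronic"),
        }
        rows, diag_rows = [], []
        for label, iset in sets.items():
            grs = build_grs(self.cohort, iset)
            est = two_stage_logistic(
                self.cohort, grs, "exposure", "oa", ("sex",),
                bootstrap=self.config.bootstrap, seed=self.config.seed,
            )
            rows.append(_estimate_row(f"1SMR GRS {label}", est))
            est_rd, diag = tsls(self.cohort, grs, "exposure", "oa", ("sex",))
            rows.append(_estimate_row(f"1SMR 2SLS {label}", est_rd))
            diag_rows.append({"analysis": label, **dataclasses.asdict(diag)})
        # per-SNP-instrumented 2SLS with the full dosage block (Sargan applies)
        est_multi, diag_multi = tsls(
            self.cohort, list(self.instruments.snp_ids), "exposure", "oa", ("sex",)
        )
        rows.append(_estimate_row("1SMR 2SLS per-SNP", est_multi))
        diag_rows.append({"analysis": "per-SNP", **dataclasses.asdict(diag_multi)})
        self._write(pd.DataFrame(rows), "onesample.tsv")
        self._write(pd.DataFrame(diag_rows), "onesample_diagnostics.tsv")
        grs_all = build_grs(self.cohort, self.instruments)
        self._write(
            instrument_covariate_check(self.cohort, grs_all, list(self.cohort.covariates)),
            "instrument_covariate_check.tsv",
        )
        return rows

    def _stage_twosample(self):
        c = self.config
        if c.exposure_sumstats and c.outcome_sumstats:
            exp = read_sumstats(c.exposure_sumstats, trait_type="continuous")
            out = read_sumstats(c.outcome_sumstats, trait_type="binary")
        else:
            exp = self.exposure_stats
            out = cohort_to_sumstats(
                self.cohort, "oa", snps=[a.snp_id for a in self.exposure_stats]
            )
        harmonized = harmonize_tables(exp, out)
        retained, steiger = steiger_filter(harmonized)
        self._write(steiger, "steiger.tsv")
        rows = []
        est, diag = ivw(retained, effects_model=c.effects_model)
        rows.append({**_estimate_row("2SMR", est), "cochran_q": diag.cochran_q,
                     "cochran_q_p": diag.cochran_q_p})
        egger_est, egger_diag = mr_egger(retained)
        rows.append({**_estimate_row("2SMR", egger_est),
                     "egger_intercept": egger_diag.egger_intercept,
                     "egger_intercept_p": egger_diag.egger_intercept_p})
        rows.append(_estimate_row("2SMR", weighted_median(retained, seed=c.seed)))
        self._write(pd.DataFrame(rows), "twosample.tsv")
        return rows

    def _stage_mvmr(self):
        bmi_stats = cohort_to_sumstats(
            self.cohort, "mediator",
            snps=[s.snp_id for s in self.cohort.truth.config.mediator_snps],
        )
        grs1 = build_grs(self.cohort, self.instruments)
        grs2 = build_grs(self.cohort, InstrumentSet.from_sumstats(bmi_stats, "mediator"))
        self._grs = (grs1, grs2)
        res = mvmr_tsls(
            self.cohort, [grs1, grs2], ("exposure", "mediator"), "oa", ("sex",),
            stage2="logistic",
        )
        rows = [
            {**_estimate_row(f"MVMR direct {name}", est),
             "conditional_F": res.conditional_F[name]}
            for name, est in res.direct_effects.items()
        ]
        self._write(pd.DataFrame(rows), "mvmr.tsv")
        return res

    def _stage_factorial(self):
        cats, medians = factorial_split(*self._grs)
        res = factorial_logistic(
            self.cohort, cats, "oa", ("sex",), medians=medians
        )
        self._write(res.table, "factorial.tsv")
        return res

    def _stage_power(self):
        c = self.config
        spec = PowerSpec(n=c.n_individuals, **c.power)
        df = pd.DataFrame(
            [{**dataclasses.asdict(spec), "power": mr_power_binary(spec)}]
        )
        self._write(df, "power.tsv")
        return df


def run_study(config: RunConfig) -> dict:
    """Execute the full synthetic-study workflow; returns per-stage results."""
    return StudyRunner(config).run()
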