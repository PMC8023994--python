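"""Simulate the reference synthetic cohort.

Draws a hip-OA-like cohort (n=50,000; eight instrument SNPs with the
published per-allele effects; causal effect ln(1.35) log-odds per SD;
prevalence calibrated to 3.2%; confounding on both exposure and outcome)
plus a BMI-like mediator panel, writes the full cohort to scratch/ (large)
and a compact per-SNP summary-association table to results/.
"""

from pathlib import Path

import pandas as pd

from mrkit.pipeline import RunConfig
from mrkit.simulate import cohort_to_sumstats, simulate_cohort, write_cohort
from mrkit.scenarios import HIP_PREVALENCE, HIP_THETA
from mrkit.simulate import CohortConfig, OutcomeSpec, bmi_like_snps, calibrate_intercept_empirical, igf1_like_snps

ROOT = Path(__file__).resolve().parents[1]
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "scratch").mkdir(exist_ok=True)

base = CohortConfig(
    n_individuals=50_000,
    snps=igf1_like_snps(),
    mediator_snps=bmi_like_snps(63),
    outcomes=[OutcomeSpec("oa", -3.0, theta=HIP_THETA, mediator_theta=0.2)],
    mediator_effect=0.1,
    confounder_on_exposure=0.3,
    confounder_on_outcome=0.2,
    seed=20201007,
)
base.outcomes = [OutcomeSpec("oa", calibrate_intercept_empirical(base, "oa", HIP_PREVALENCE),
                             theta=HIP_THETA, mediator_theta=0.2)]
cohort = simulate_cohort(base)
write_cohort(cohort, ROOT / "scratch" / "cohort")

rows = []
for trait in ("exposure", "oa"):
    for a in cohort_to_sumstats(cohort, trait, snps=[s.snp_id for s in base.snps]):
        rows.append({"trait": trait, "snp_id": a.snp_id, "eaf": a.eaf,
                     "beta": a.beta, "se": a.se, "p": a.p, "n": a.n})
pd.DataFrame(rows).to_csv(ROOT / "results" / "cohort_sumstats.tsv", sep="\t", index=False)

print(f"cohort n={cohort.n}, prevalence {cohort.truth.prevalence['oa']:.4f} "
      f"(target {HIP_PREVALENCE}), exposure SD {cohort.exposure.std():.3f}")
print("full cohort in scratch/cohort; per-SNP associations in results/cohort_sumstats.tsv")
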