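"""Two-sample MR on the published instrument table.

Runs the full summary-data battery (per-SNP Wald ratios, IVW, MR-Egger,
weighted median, Cochran's Q, Steiger filtering) on the bundled eight-SNP
IGF-1 instrument table, for hip and knee OA, with and without the three
IGF-BP3-associated SNPs, and for the single intronic IGF1 SNP alone.

Key findings this reproduces:
* single intronic SNP: OR 1.92 (hip), 1.26 (knee) per SD of IGF-1;
* five-SNP IVW excluding IGF-BP3 SNPs: OR 1.30 (knee);
* heterogeneity collapses when the IGF-BP3 SNPs are removed (hip Q 32->5);
* Steiger filtering excludes no SNPs (all instruments explain far more
  variance in IGF-1 than in OA).

Writes results/two_sample_published.tsv and results/steiger_published.tsv.
"""

import math
from pathlib import Path

import pandas as pd

from mrkit.datasets import load_igf1_harmonized
from mrkit.twosample import cochran_q, ivw, mr_egger, steiger_filter, wald_ratio, weighted_median

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_EXPOSURE, N_OUTCOME = 30_884, 455_221

rows, steiger_rows = [], []
for joint in ("hip", "knee"):
    for label, exclude in (("all 8 SNPs", False), ("excl. IGF-BP3 SNPs", True)):
        snps = load_igf1_harmonized(joint, exclude_igfbp3=exclude)
        retained, report = steiger_filter(snps, N_EXPOSURE, N_OUTCOME)
        steiger_rows.append(report.assign(joint=joint, subset=label))
        est, diag = ivw(retained, effects_model="fixed")
        egger, ediag = mr_egger(retained)
        wm = weighted_median(retained, seed=20201007)
        for e, extra in (
            (est, {"cochran_q": diag.cochran_q, "cochran_q_p": diag.cochran_q_p}),
            (egger, {"egger_intercept": ediag.egger_intercept,
                     "egger_intercept_p": ediag.egger_intercept_p}),
            (wm, {}),
        ):
            o, lo, hi = e.or_ci()
            rows.append({"joint": joint, "subset": label, "method": e.method,
                         "or": o, "ci_low": lo, "ci_high": hi, "p": e.p,
                         "n_snps": e.n_snps, **extra})
    single = next(h for h in load_igf1_harmonized(joint) if h.snp_id == "rs978458")
    r = wald_ratio(single)
    rows.append({"joint": joint, "subset": "single intronic SNP", "method": "Wald ratio",
                 "or": math.exp(r.theta), "ci_low": math.exp(r.theta - 1.96 * r.se),
                 "ci_high": math.exp(r.theta + 1.96 * r.se), "p": r.p, "n_snps": 1})

table = pd.DataFrame(rows)
table.to_csv(OUT / "two_sample_published.tsv", sep="\t", index=False)
pd.concat(steiger_rows).to_csv(OUT / "steiger_published.tsv", sep="\t", index=False)

hip_all = [wald_ratio(h) for h in load_igf1_harmonized("hip")]
hip_sub = [wald_ratio(h) for h in load_igf1_harmonized("hip", exclude_igfbp3=True)]
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nhip heterogeneity: Q = {cochran_q(hip_all)[0]:.1f} (8 SNPs) -> "
      f"{cochran_q(hip_sub)[0]:.1f} (excl. IGF-BP3)")
print("Steiger exclusions:", int((~pd.concat(steiger_rows)["direction_ok"]).sum()))
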