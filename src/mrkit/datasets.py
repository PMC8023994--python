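"""Bundled instrument tables.

``igf1_instruments.tsv`` transcribes the published associations of the eight
IGF-1 instrument SNPs with standardized serum IGF-1 (per effect-allele beta,
SE, p) and with hospital-diagnosed hip and knee osteoarthritis (OR with SE on
the log-odds scale), as estimated in UK Biobank adjusted for sex, genotyping
chip and 10 principal components.  Three SNPs are flagged as also associated
with IGF-BP3 (rs1065656, rs646776, rs700753); rs978458 is the single intronic
IGF1 SNP used as a minimal instrument.  The source table prints neither EAF
nor the non-effect allele, so those fields are absent here.
"""

from __future__ import annotations

import contextlib
import importlib.resources
import warnings
from pathlib import Path

import pandas as pd

from .sumstats import HarmonizedSNP, SNPAssociation

IGFBP3_SNPS = ("rs1065656", "rs646776", "rs700753")
INTRONIC_IGF1_SNP = "rs978458"

#: Approximate analysis sample sizes: the one-sample MR sub-population for
#: both exposure and outcome columns of the bundled table.
N_ONESAMPLE = 332_059


@contextlib.contextmanager
def _quiet_rounding():
    # The table prints SEs to one significant figure, so the z/p
    # cross-check flags rounding, not real inconsistency.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*disagrees with the z-score.*")
        yield


def _fixture_path() -> Path:
    return Path(str(importlib.resources.files("mrkit").joinpath("data/igf1_instruments.tsv")))


def load_igf1_table() -> pd.DataFrame:
    """The bundled instrument table as a DataFrame, one row per SNP."""
    return pd.read_csv(_fixture_path(), sep="\t")


def load_igf1_exposure(n: int = N_ONESAMPLE) -> list[SNPAssociation]:
    """SNP -> IGF-1 association records (SD units per effect allele)."""
    df = load_igf1_table()
    with _quiet_rounding():
        return [
            SNPAssociation(
                snp_id=r.snp_id,
                effect_allele=r.effect_allele,
                beta=r.beta_igf1,
                se=r.se_igf1,
                p=r.p_igf1,
                n=n,
                trait_type="continuous",
            )
            for r in df.itertuples()
        ]


def load_igf1_outcome(joint: str, n: int = N_ONESAMPLE) -> list[SNPAssociation]:
    """SNP -> OA association records for ``joint`` in {'hip','knee'} (log-odds)."""
    import math

    if joint not in ("hip", "knee"):
        raise ValueError(f"joint must be 'hip' or 'knee', got {joint!r}")
    df = load_igf1_table()
    with _quiet_rounding():
        return [
            SNPAssociation(
                snp_id=r.snp_id,
                effect_allele=r.effect_allele,
                beta=math.log(getattr(r, f"or_{joint}")),
                se=getattr(r, f"se_{joint}"),
                p=getattr(r, f"p_{joint}"),
                n=n,
                trait_type="binary",
            )
            for r in df.itertuples()
        ]


def load_igf1_harmonized(
    joint: str, *, exclude_igfbp3: bool = False, n: int = N_ONESAMPLE
) -> list[HarmonizedSNP]:
    """Exposure/outcome pairs for ``joint``, already on a shared effect allele.

    Both columns of the bundled table are reported on the same effect
    allele, so no flipping is needed; this constructs the harmonized
    records directly.
    """
    exp = {a.snp_id: a for a in load_igf1_exposure(n)}
    out = {a.snp_id: a for a in load_igf1_outcome(joint, n)}
    pairs = []
    for snp_id, e in exp.items():
        if exclude_igfbp3 and snp_id in IGFBP3_SNPS:
            continue
        o = out[snp_id]
        pairs.append(
            HarmonizedSNP(
                snp_id=snp_id,
                gamma=e.beta,
                se_gamma=e.se,
                Gamma=o.beta,
                se_Gamma=o.se,
                flipped=False,
                n_exposure=e.n,
                n_outcome=o.n,
            )
        )
    return pairs
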