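"""ChIP-qPCR enrichment arithmetic.

Enrichment is expressed relative to a known fraction of pre-IP chromatin
("percent input", default 10%), assuming perfect amplification efficiency
(E = 2, one doubling per cycle):

    percent_input = 100 * 2**(Ct_input - log2(1/input_fraction) - Ct_IP)

Modification signals are then normalized to histone H3 occupancy at the same
locus and to a reference locus (the actin 1-1 promoter in the study design).
Technical qPCR replicates are averaged on the Ct scale (geometric on the
quantity scale); biological replicates are summarized on the enrichment
scale (mean and SD).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

EFFICIENCY = 2.0
DEFAULT_INPUT_FRACTION = 0.10
ANTIBODIES = ("H3", "H3K9ac", "H3K4me3", "H3K27me3")
LOCI = ("target_5prime", "target_3prime", "reference_promoter")

CT_COLUMNS = [
    "sample_id",
    "antibody",
    "locus",
    "bio_rep",
    "tech_rep",
    "ct_ip",
    "ct_input",
    "input_fraction",
]


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    antibody: str
    locus: str
    ct_ip: float
    ct_input: float
    input_fraction: float = DEFAULT_INPUT_FRACTION
    bio_rep: int = 1
    tech_rep: int = 1

    def __post_init__(self) -> None:
        for ct in (self.ct_ip, self.ct_input):
            if not (0 < ct < 45):
                raise ValidationError(f"implausible Ct value {ct}")
        if not (0 < self.input_fraction <= 1):
            raise ValidationError(f"input_fraction must be in (0,1], got {self.input_fraction}")


def percent_input(record: QpcrRecord) -> float:
    """Percent of input recovered in the IP, assuming E=2 amplification."""
    if record.input_fraction <= 0:
        raise ValidationError("input_fraction must be positive")
    ct_input_adj = record.ct_input - math.log(1.0 / record.input_fraction, EFFICIENCY)
    return 100.0 * EFFICIENCY ** (ct_input_adj - record.ct_ip)


def normalize_to_reference(target_enr: float, reference_enr: float) -> float:
    """Target enrichment relative to the reference-locus enrichment."""
    if reference_enr == 0:
        raise ValidationError("reference enrichment is zero")
    return target_enr / reference_enr


def normalize_to_h3(mod_enr: float, h3_enr_same_locus: Optional[float]) -> float:
    """Histone-modification enrichment relative to H3 occupancy at that locus."""
    if h3_enr_same_locus is None or not np.isfinite(h3_enr_same_locus):
        raise ValidationError("missing H3 record for this locus")
    if h3_enr_same_locus == 0:
        raise ValidationError("H3 enrichment is zero")
    return mod_enr / h3_enr_same_locus


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    return df


def aggregate_replicates(
    records: pd.DataFrame,
    h3_antibody: str = "H3",
    reference_locus: str = "reference_promoter",
) -> pd.DataFrame:
    """Full enrichment report from a well-level Ct table.

    Per (sample, antibody, locus): technical replicates are averaged on the
    Ct scale, each biological replicate yields one percent-input value, the
    H3- and reference-normalizations are applied within each biological
    replicate, and mean/SD are taken across biological replicates (SD is NA
    for a single replicate).
    """
    df = records.copy()
    if "input_fraction" not in df.columns:
        df["input_fraction"] = DEFAULT_INPUT_FRACTION

    tech = (
        df.groupby(["sample_id", "antibody", "locus", "bio_rep"], sort=False)
        .agg(ct_ip=("ct_ip", "mean"), ct_input=("ct_input", "mean"),
             input_fraction=("input_fraction", "first"))
        .reset_index()
    )
    tech["percent_input"] = [
        percent_input(
            QpcrRecord(r.sample_id, r.antibody, r.locus, r.ct_ip, r.ct_input,
                       r.input_fraction, int(r.bio_rep))
        )
        for r in tech.itertuples()
    ]

    # per biological replicate: H3 at the same locus, then the reference locus
    h3 = tech[tech["antibody"] == h3_antibody].set_index(["sample_id", "locus", "bio_rep"])[
        "percent_input"
    ]

    def _h3_at(row):
        try:
            return h3.loc[(row.sample_id, row.locus, row.bio_rep)]
        except KeyError:
            return np.nan

    tech["h3_same_locus"] = [_h3_at(r) for r in tech.itertuples()]
    tech["h3_norm"] = tech["percent_input"] / tech["h3_same_locus"]

    ref = tech[tech["locus"] == reference_locus].set_index(
        ["sample_id", "antibody", "bio_rep"]
    )
    ref_pi = ref["percent_input"]
    ref_h3n = ref["h3_norm"]

    def _ref(row, series):
        try:
            return series.loc[(row.sample_id, row.antibody, row.bio_rep)]
        except KeyError:
            return np.nan

    tech["ref_norm"] = tech["percent_input"] / [_ref(r, ref_pi) for r in tech.itertuples()]
    tech["h3_ref_norm"] = tech["h3_norm"] / [_ref(r, ref_h3n) for r in tech.itertuples()]

    report = (
        tech.groupby(["sample_id", "antibody", "locus"], sort=False)
        .agg(
            n_bio_reps=("bio_rep", "nunique"),
            percent_input_mean=("percent_input", "mean"),
            percent_input_sd=("percent_input", lambda x: x.std(ddof=1)),
            h3_norm_mean=("h3_norm", "mean"),
            h3_norm_sd=("h3_norm", lambda x: x.std(ddof=1)),
            ref_norm_mean=("ref_norm", "mean"),
            ref_norm_sd=("ref_norm", lambda x: x.std(ddof=1)),
            h3_ref_norm_mean=("h3_ref_norm", "mean"),
            h3_ref_norm_sd=("h3_ref_norm", lambda x: x.std(ddof=1)),
        )
        .reset_index()
    )
    return report
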