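"""Knockdown-aware total-count-scaling normalization.

Standard total-count scaling is biased in dsRNA-feeding knockdown samples:
large amounts of siRNAs against the knockdown gene inflate the library.
The correction used here removes, per sample, the knockdown-gene-mapped
reads K from the genome-mapped total T (itself computed after excluding
structural-RNA and feeding-vector reads), and scales every region count by

    R_hat = R * M / (T - K),

where M is the maximum of (T_i - K_i) over the n samples of the cohort.
Exactly one sample therefore has scaling factor 1 and all factors are >= 1;
the normalization is linear in R and invariant to uniform duplication of a
sample's reads (up to the cohort-wide M).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateLibraryError, ValidationError
from .smallrna import ReadAssignments


@dataclass
class SampleLibrary:
    """One sample's normalization bookkeeping plus its raw region counts."""

    sample_id: str
    T: int  # genome-mapped reads after structural/feeding exclusions
    K: int  # knockdown-gene-mapped reads
    counts: Optional[pd.DataFrame] = None  # raw region counts (region, length, sense, antisense)

    def __post_init__(self) -> None:
        if self.K < 0 or self.T < 0:
            raise ValidationError("T and K must be non-negative")
        if self.T <= self.K:
            raise DegenerateLibraryError(
                f"sample {self.sample_id}: T={self.T} <= K={self.K}"
            )

    @property
    def effective_size(self) -> int:
        return self.T - self.K


def compute_T_K(
    assignments: ReadAssignments,
    genome_ref_ids: Iterable[str],
    knockdown_ref_ids: Iterable[str],
    sample_id: str,
    exclude_ref_ids: Iterable[str] = (),
    counts: Optional[pd.DataFrame] = None,
) -> SampleLibrary:
    """Derive T and K for one sample from its two-round alignment result.

    ``genome_ref_ids`` enumerate the references that count as "the genome"
    (the macronuclear surrogate scaffold plus coding-sequence annotation);
    ``exclude_ref_ids`` are feeding-vector/structural references whose reads
    are dropped from T (structural contaminants were already removed in
    round 1). ``knockdown_ref_ids`` are the CDS references of the gene(s)
    being knocked down in this sample.
    """
    genome = set(genome_ref_ids)
    kd = set(knockdown_ref_ids)
    excluded_reads = assignments.mapped_to(exclude_ref_ids) if exclude_ref_ids else set()
    genome_reads = assignments.mapped_to(genome) - excluded_reads
    kd_reads = assignments.mapped_to(kd) & genome_reads
    return SampleLibrary(sample_id, T=len(genome_reads), K=len(kd_reads), counts=counts)


@dataclass
class CohortScaling:
    M: int
    factors: dict[str, float] = field(default_factory=dict)

    def factor(self, sample_id: str) -> float:
        if sample_id not in self.factors:
            raise ValidationError(f"sample {sample_id!r} not part of the cohort scaling")
        return self.factors[sample_id]


def cohort_scaling(samples: Sequence[SampleLibrary]) -> CohortScaling:
    """M = max over samples of (T - K); per-sample factor M/(T-K)."""
    if not samples:
        raise ValidationError("empty cohort")
    M = max(s.effective_size for s in samples)
    return CohortScaling(M, {s.sample_id: M / s.effective_size for s in samples})


def normalize(R, sample: SampleLibrary, scaling: CohortScaling):
    """R_hat = R * M / (T - K); accepts scalars, arrays or Series."""
    return R * scaling.factor(sample.sample_id)


def normalize_counts(sample: SampleLibrary, scaling: CohortScaling) -> pd.DataFrame:
    """Raw count table with normalized sense/antisense columns appended."""
    if sample.counts is None:
        raise ValidationError(f"sample {sample.sample_id} carries no counts")
    f = scaling.factor(sample.sample_id)
    out = sample.counts.copy()
    out["sense_norm"] = out["sense"] * f
    out["antisense_norm"] = out["antisense"] * f
    return out


def fold_change(
    kd_value,
    ctrl_value,
    knockdown: SampleLibrary,
    control: SampleLibrary,
    scaling: CohortScaling,
    pseudocount: float = 0.0,
) -> tuple[float, float]:
    """Normalized knockdown/control ratio and its log2.

    Returns (NaN, NaN) with a warning when the normalized control count is
    zero and no pseudocount is requested; zeros are not fabricated away.
    """
    num = normalize(kd_value, knockdown, scaling) + pseudocount
    den = normalize(ctrl_value, control, scaling) + pseudocount
    if den == 0:
        warnings.warn("control normalized count is 0; fold change undefined", stacklevel=2)
        return float("nan"), float("nan")
    ratio = num / den
    return ratio, float(np.log2(ratio)) if ratio > 0 else float("-inf")


def fold_change_table(
    knockdown: SampleLibrary,
    control: SampleLibrary,
    scaling: CohortScaling,
    length: int = 23,
    strand: str = "antisense",
) -> pd.DataFrame:
    """Per-region fold changes of (by default) 23 nt antisense counts."""
    if knockdown.counts is None or control.counts is None:
        raise ValidationError("both samples need count tables")
    kd = knockdown.counts[knockdown.counts["length"] == length].set_index("region")
    ct = control.counts[control.counts["length"] == length].set_index("region")
    if not kd.index.equals(ct.index):
        raise ValidationError("mismatched region definitions between samples")
    rows = []
    for region in kd.index:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratio, log2 = fold_change(
                float(kd.loc[region, strand]), float(ct.loc[region, strand]),
                knockdown, control, scaling,
            )
        rows.append(
            {
                "region": region,
                "role": kd.loc[region, "role"],
                "length": length,
                "strand": strand,
                "knockdown_raw": kd.loc[region, strand],
                "control_raw": ct.loc[region, strand],
                "fold_change": ratio,
                "log2_fold_change": log2,
            }
        )
    return pd.DataFrame(rows)
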