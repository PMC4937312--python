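"""Tiny sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default nucleotide composition, AT-rich like the Paramecium macronuclear genome
DEFAULT_AT_FRACTION = 0.72


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, n: int, at_fraction: float = DEFAULT_AT_FRACTION) -> str:
    """Random nucleotide string with the given A+T fraction (A=T, C=G)."""
    p_at = at_fraction / 2.0
    p_cg = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(np.array(list("ATCG")), size=n, p=[p_at, p_at, p_cg, p_cg]))


def is_acgt(seq: str) -> bool:
    return all(c in "ACGT" for c in seq.upper())
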