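import numpy as np
import pytest
from hypothesis import settings

from sirnascope.genemodels import GeneModel
from sirnascope.sequtils import random_seq
from sirnascope.synthetic_data import SampleSpec, SimConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_gene(rng=None, gene_id="G", exon_lengths=(120, 80, 100), intron_lengths=(25, 30),
              start=0, coding_strand="+", reference_id="ref"):
    """Small gene model with random sequence and canonical splice motifs."""
    rng = rng or np.random.default_rng(42)
    total = sum(exon_lengths) + sum(intron_lengths)
    seq = list(random_seq(rng, total))
    exons, pos = [], 0
    for i, e in enumerate(exon_lengths):
        exons.append((start + pos, start + pos + e))
        pos += e
        if i < len(intron_lengths):
            s, t = pos, pos + intron_lengths[i]
            seq[s], seq[s + 1], seq[t - 2], seq[t - 1] = "G", "T", "A", "G"
            pos = t
    return GeneModel(gene_id, reference_id, coding_strand, tuple(exons), "".join(seq), start)


@pytest.fixture
def gene():
    return make_gene()


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions for fast unit/integration tests."""
    return SimConfig(
        seed=3,
        scaffold_length=6000,
        gene_offset=2500,
        n_primary=800,
        n_junction=120,
        n_intron=120,
        n_background=2500,
        n_structural=300,
        n_feeding=400,
        n_long_reads=400,
    )


@pytest.fixture(scope="session")
def kd_sample():
    return SampleSpec(
        "KD", "knockdown", "RDR2",
        {"primary_antisense": 0.2, "primary_sense": 0.5, "junction_antisense": 0.2,
         "intron_antisense": 0.2, "secondary_antisense": 0.3},
    )
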