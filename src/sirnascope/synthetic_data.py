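"""Seeded synthetic cohorts emulating the transgene/endogenous-gene system.

The generator builds a macronuclear genome surrogate (an AT-rich scaffold
with a five-intron target gene embedded), a truncated transgene construct,
contaminant/structural and feeding-gene references, and then emits:

* small-RNA reads (17-25 nt, modal length 23) by class — primary reads from
  the transgene insert, exon-exon junction reads from the spliced mRNA,
  intron-overlapping reads, secondary reads confined to the transgene-absent
  regions of the endogenous gene, background reads from the rest of the
  scaffold, structural-RNA contaminants and dsRNA-feeding reads;
* long RNA reads sampled from transcripts that retain each intron
  independently with a configurable probability, plus a configurable
  fraction of antisense (bidirectional-transcription) reads that retain the
  sense introns and may splice out a planted antisense intron;
* a well-level ChIP-qPCR Ct table with planted enrichment effects.

Every read carries a truth-table row. Identical seeds give byte-identical
outputs; each generator stage draws from its own RNG stream derived from the
master seed, so adding a stage never perturbs earlier outputs.

Secondary abundance semantics: the configured fraction (default 0.05 for the
first secondary region, 0.01 for the second) fixes the region's 23 nt
antisense per-base coverage relative to the *realized mapped* 23 nt
antisense per-base coverage of the transgene-covered region, which is how
the study quantifies secondary-siRNA levels.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chipquant import CT_COLUMNS, DEFAULT_INPUT_FRACTION
from .errors import ValidationError
from .genemodels import (
    GeneModel,
    RegionSet,
    Transgene,
    TransgeneSpec,
    build_transgene,
    derive_regions,
    spliced_sequence,
)
from .io import Read
from .sequtils import random_seq, revcomp
from .smallrna import ReferenceSet

# RNG stream ids (fixed; adding streams must not renumber existing ones)
_STAGE_REFS = 1
_STAGE_LONG = 2
_STAGE_CT = 3
_STAGE_SAMPLE_BASE = 100


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stage))))


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    role: str  # 'control' | 'knockdown'
    knockdown_gene: str  # gene targeted by dsRNA feeding in this sample
    multipliers: dict = field(default_factory=dict)  # siRNA-class -> expected-count factor

    def __post_init__(self) -> None:
        if self.role not in ("control", "knockdown"):
            raise ValidationError(f"unknown sample role {self.role!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0

    # reference geometry
    scaffold_id: str = "scaffold_51S"
    scaffold_length: int = 20000
    gene_offset: int = 10000
    gene_id: str = "NDtarget"
    exon_lengths: tuple = (560, 175, 175, 145, 145, 175)
    intron_lengths: tuple = (25, 25, 25, 25, 25)
    coding_strand: str = "+"
    antisense_intron: tuple = (640, 665)  # gene-local, inside exon 2

    # transgene construct (pTI-/- analogue by default)
    transgene_id: str = "pTI_dd"
    deletions: tuple = ((173, 529), (1340, 1500))
    replacements: tuple = ()  # entries: (interval, length, name) — foreign sequence is generated
    linearization_offset: int = 120
    region_prefix: str = "ND"
    secondary_names: tuple = ("ND-1", "ND-2")
    secondary_fractions: dict = field(default_factory=lambda: {"ND-1": 0.05, "ND-2": 0.01})

    # small-RNA classes
    n_primary: int = 10000
    n_junction: int = 1500
    n_intron: int = 1500
    n_background: int = 150000
    n_structural: int = 10000
    n_feeding: int = 15000
    length_probs: dict = field(
        default_factory=lambda: {
            17: 0.01, 18: 0.01, 19: 0.02, 20: 0.03, 21: 0.05,
            22: 0.08, 23: 0.70, 24: 0.06, 25: 0.04,
        }
    )
    antisense_body: float = 0.90
    antisense_5p: float = 0.25
    antisense_secondary: float = 0.95
    antisense_junction: float = 0.95
    antisense_intron_reads: float = 0.50

    # long-RNA simulation
    n_long_reads: int = 20000
    long_read_length: int = 100
    intron_retention: float | tuple = 0.10
    long_antisense_fraction: float = 0.15
    antisense_intron_splice_prob: float = 0.8

    # auxiliary references
    structural_length: int = 2000
    feeding_gene_length: int = 1200
    at_fraction: float = 0.72

    # ChIP-qPCR table
    ct_bio_sd: float = 0.02
    ct_tech_sd: float = 0.02

    samples: tuple = (
        SampleSpec("control_ICL7a", "control", "ICL7a"),
        SampleSpec(
            "RDR2_KD",
            "knockdown",
            "RDR2",
            {
                "primary_antisense": 0.2,
                "primary_sense": 0.5,
                "junction_antisense": 0.2,
                "junction_sense": 0.5,
                "intron_antisense": 0.2,
                "intron_sense": 0.5,
                "secondary_antisense": 0.3,
                "secondary_sense": 0.5,
            },
        ),
    )

    def __post_init__(self) -> None:
        probs = np.array(list(self.length_probs.values()), dtype=float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
            raise ValidationError("length_probs must sum to 1")
        for p in (
            self.antisense_body, self.antisense_5p, self.antisense_secondary,
            self.antisense_junction, self.antisense_intron_reads,
            self.long_antisense_fraction, self.antisense_intron_splice_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0,1]")
        for n in (self.n_primary, self.n_junction, self.n_intron, self.n_background,
                  self.n_structural, self.n_feeding, self.n_long_reads):
            if n < 0:
                raise ValidationError("read counts must be >= 0")
        roles = [s.role for s in self.samples]
        if roles.count("control") != 1:
            raise ValidationError("exactly one control sample required")

    @property
    def control_sample(self) -> SampleSpec:
        return next(s for s in self.samples if s.role == "control")

    @property
    def gene_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        for key in ("exon_lengths", "intron_lengths", "antisense_intron",
                    "secondary_names"):
            d[key] = list(d[key])
        d["deletions"] = [list(iv) for iv in self.deletions]
        d["replacements"] = [
            {"interval": list(iv), "length": ln, "name": nm} for iv, ln, nm in self.replacements
        ]
        d["length_probs"] = {int(k): float(v) for k, v in self.length_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "samples" in d:
            d["samples"] = tuple(SampleSpec(**s) for s in d["samples"])
        for key in ("exon_lengths", "intron_lengths", "antisense_intron", "secondary_names"):
            if key in d:
                d[key] = tuple(d[key])
        if "deletions" in d:
            d["deletions"] = tuple(tuple(iv) for iv in d["deletions"])
        if "replacements" in d:
            d["replacements"] = tuple(
                (tuple(r["interval"]), int(r["length"]), r["name"]) for r in d["replacements"]
            )
        if "length_probs" in d:
            d["length_probs"] = {int(k): float(v) for k, v in d["length_probs"].items()}
        if "intron_retention" in d and isinstance(d["intron_retention"], (list, tuple)):
            d["intron_retention"] = tuple(d["intron_retention"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SimConfig":
        """The packaged default study conditions."""
        from importlib.resources import files

        with (files("sirnascope") / "data" / "default_config.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# reference construction


@dataclass
class References:
    config: SimConfig
    scaffold_seq: str
    gene: GeneModel
    transgene: Transgene
    transgene_spec: TransgeneSpec
    mrna_id: str
    region_set: RegionSet
    structural_id: str
    feeding_refs: dict  # fed-gene id -> reference id
    targets: ReferenceSet
    contaminants: ReferenceSet
    genome_ref_ids: set

    @property
    def spliced(self):
        return spliced_sequence(self.gene)


def build_references(config: SimConfig) -> References:
    rng = stage_rng(config.seed, _STAGE_REFS)
    glen = config.gene_length

    gene_seq = list(random_seq(rng, glen, config.at_fraction))
    exons = []
    pos = 0
    for i, elen in enumerate(config.exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(config.intron_lengths):
            s, e = pos, pos + config.intron_lengths[i]
            gene_seq[s], gene_seq[s + 1] = "G", "T"  # canonical donor
            gene_seq[e - 2], gene_seq[e - 1] = "A", "G"  # canonical acceptor
            pos = e
    a_s, a_e = config.antisense_intron
    for s, e in [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]:
        if a_s < e and s < a_e:
            raise ValidationError("antisense intron must not overlap a sense intron")
    # bottom-strand GT...AG reads CT...AC on the top strand
    gene_seq[a_s], gene_seq[a_s + 1] = "C", "T"
    gene_seq[a_e - 2], gene_seq[a_e - 1] = "A", "C"
    gene_seq = "".join(gene_seq)

    scaffold = random_seq(rng, config.scaffold_length, config.at_fraction)
    off = config.gene_offset
    if off + glen > config.scaffold_length:
        raise ValidationError("gene does not fit on the scaffold")
    scaffold = scaffold[:off] + gene_seq + scaffold[off + glen :]

    gene = GeneModel(
        gene_id=config.gene_id,
        reference_id=config.scaffold_id,
        coding_strand=config.coding_strand,
        exons=tuple((a + off, b + off) for a, b in exons),
        sequence=gene_seq,
        start=off,
    )

    spec = TransgeneSpec(
        parent_gene_id=config.gene_id,
        deletions=tuple(tuple(iv) for iv in config.deletions),
        replacements=tuple(
            (tuple(iv), random_seq(rng, ln, config.at_fraction), nm)
            for iv, ln, nm in config.replacements
        ),
        linearization_offset=config.linearization_offset,
    )
    transgene = build_transgene(gene, spec, transgene_id=config.transgene_id, filler_rng=rng)
    region_set = derive_regions(
        gene, transgene, prefix=config.region_prefix,
        secondary_names=config.secondary_names or None,
    )

    sp = spliced_sequence(gene)
    mrna_id = f"{config.gene_id}_mRNA"
    structural_id = "rRNA_surrogate"
    structural_seq = random_seq(rng, config.structural_length, config.at_fraction)

    feeding_refs: dict[str, str] = {}
    target_seqs = {
        config.scaffold_id: scaffold,
        config.transgene_id: transgene.sequence,
        mrna_id: sp.mrna,
    }
    fed_genes = sorted({s.knockdown_gene for s in config.samples})
    for g in fed_genes:
        ref_id = f"{g}_cds"
        feeding_refs[g] = ref_id
        target_seqs[ref_id] = random_seq(rng, config.feeding_gene_length, config.at_fraction)

    genome_ref_ids = {config.scaffold_id, mrna_id, *feeding_refs.values()}
    return References(
        config=config,
        scaffold_seq=scaffold,
        gene=gene,
        transgene=transgene,
        transgene_spec=spec,
        mrna_id=mrna_id,
        region_set=region_set,
        structural_id=structural_id,
        feeding_refs=feeding_refs,
        targets=ReferenceSet(target_seqs),
        contaminants=ReferenceSet({structural_id: structural_seq}),
        genome_ref_ids=genome_ref_ids,
    )


# ---------------------------------------------------------------------------
# small-RNA simulation

TRUTH_COLUMNS = ["read_id", "clazz", "region", "origin_ref", "origin_start", "length", "sense"]


def _draw_lengths(rng, probs: Mapping[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(probs), dtype=int)
    p = np.array([probs[int(k)] for k in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=p / p.sum())


def _uniform_starts(rng, n: int, high_incl: np.ndarray | int) -> np.ndarray:
    """Uniform integer starts in [0, high_incl] (vectorized over per-read highs)."""
    return np.floor(rng.random(n) * (np.asarray(high_incl) + 1)).astype(int)


def _mult(sample: SampleSpec, clazz: str, antisense: np.ndarray) -> np.ndarray:
    m_as = float(sample.multipliers.get(f"{clazz}_antisense", 1.0))
    m_s = float(sample.multipliers.get(f"{clazz}_sense", 1.0))
    return np.where(antisense, m_as, m_s)


def simulate_small_rnas(
    config: SimConfig,
    refs: References,
    rng: np.random.Generator,
    sample: Optional[SampleSpec] = None,
) -> tuple[list[Read], pd.DataFrame]:
    """One sample's small-RNA reads plus their truth table.

    RNG draws are consumed in a fixed order independent of the knockdown
    multipliers, so a knockdown sample is an exact thinning of the reads the
    control draw would have produced from the same stream.
    """
    if sample is None:
        sample = config.control_sample
    tg = refs.transgene
    gene = refs.gene
    scaffold = refs.scaffold_seq
    sp = refs.spliced
    reads: list[Read] = []
    cols: dict[str, list] = {k: [] for k in TRUTH_COLUMNS}
    sid = sample.sample_id

    def emit(clazz, seqs, regions, origin_ref, origins, senses):
        base = len(reads)
        m = len(seqs)
        ids = [f"{sid}.{clazz}.{base + i:06d}" for i in range(m)]
        reads.extend(zip(ids, seqs))
        cols["read_id"].extend(ids)
        cols["clazz"].extend([clazz] * m)
        cols["region"].extend(regions)
        cols["origin_ref"].extend([origin_ref] * m)
        cols["origin_start"].extend(np.asarray(origins, dtype=int).tolist() if m else [])
        cols["length"].extend(len(s) for s in seqs)
        cols["sense"].extend(senses)

    # --- primary reads from the transgene insert ---------------------------
    insert_end = tg.insert_end
    parent_map = np.full(insert_end, -1, dtype=np.int64)
    for seg in tg.parent_segments:
        parent_map[seg.start : seg.end] = np.arange(seg.ref_start, seg.ref_end)
    foreign_name = np.empty(insert_end, dtype=object)
    for seg in tg.segments:
        if seg.kind == "foreign":
            foreign_name[seg.start : seg.end] = seg.name

    try:
        five = refs.region_set.get(f"{config.region_prefix}-5p")
    except KeyError:
        five = None

    n = config.n_primary
    Ls = _draw_lengths(rng, config.length_probs, n)
    max_L = int(Ls.max()) if n else 0
    if insert_end < max_L:
        raise ValidationError("transgene insert shorter than the longest read")
    starts = _uniform_starts(rng, n, insert_end - Ls)
    mids = starts + Ls // 2
    pmid = parent_map[mids]
    in5p = (
        (pmid >= five.start) & (pmid < five.end) if five is not None else np.zeros(n, bool)
    )
    anti = rng.random(n) < np.where(in5p, config.antisense_5p, config.antisense_body)
    keep = rng.random(n) < _mult(sample, "primary", anti)

    contiguous = (parent_map[starts] >= 0) & (
        parent_map[np.minimum(starts + Ls - 1, insert_end - 1)] == parent_map[starts] + Ls - 1
    )
    basis_23as = int(np.sum(keep & anti & (Ls == 23) & contiguous))

    seqs, regions, origins, senses = [], [], [], []
    gene_name = f"{config.region_prefix}gene"
    starts_l, Ls_l, anti_l = starts.tolist(), Ls.tolist(), anti.tolist()
    for i in np.flatnonzero(keep).tolist():
        s0, L = starts_l[i], Ls_l[i]
        sub = tg.sequence[s0 : s0 + L]
        seqs.append(revcomp(sub) if anti_l[i] else sub)
        if pmid[i] < 0:
            regions.append(foreign_name[mids[i]] or "foreign")
        elif in5p[i]:
            regions.append(f"{config.region_prefix}-5p")
        else:
            regions.append(gene_name)
        origins.append(s0)
        senses.append("antisense" if anti_l[i] else "sense")
    emit("primary", seqs, regions, config.transgene_id, origins, senses)

    # --- exon-exon junction reads from the spliced mRNA ---------------------
    n = config.n_junction
    if n and not sp.junctions:
        raise ValidationError("junction reads requested for an intron-less gene")
    j_idx = rng.integers(0, len(sp.junctions), size=n) if n else np.array([], dtype=int)
    Ls = _draw_lengths(rng, config.length_probs, n)
    offs = _uniform_starts(rng, n, Ls - 10)  # overhang >= 5 nt on each side
    jpos = np.array([sp.junctions[j] for j in j_idx], dtype=int) if n else np.array([], dtype=int)
    starts = np.clip(jpos - 5 - offs, 0, max(0, len(sp.mrna) - 25))
    anti = rng.random(n) < config.antisense_junction
    keep = rng.random(n) < _mult(sample, "junction", anti)
    seqs, regions, origins, senses = [], [], [], []
    starts_l, Ls_l, anti_l, j_l = starts.tolist(), Ls.tolist(), anti.tolist(), j_idx.tolist()
    for i in np.flatnonzero(keep).tolist():
        s0, L = starts_l[i], Ls_l[i]
        sub = sp.mrna[s0 : s0 + L]
        seqs.append(revcomp(sub) if anti_l[i] else sub)
        regions.append(f"junction{j_l[i] + 1}")
        origins.append(s0)
        senses.append("antisense" if anti_l[i] else "sense")
    emit("junction", seqs, regions, refs.mrna_id, origins, senses)

    # --- intron-overlapping reads from the genomic locus --------------------
    n = config.n_intron
    introns = gene.introns
    if n and not introns:
        raise ValidationError("intron reads requested for an intron-less gene")
    i_idx = rng.integers(0, len(introns), size=n) if n else np.array([], dtype=int)
    Ls = _draw_lengths(rng, config.length_probs, n)
    lo = np.array([introns[j][0] for j in i_idx], dtype=int) - Ls + 1 if n else np.array([], int)
    hi = np.array([introns[j][1] for j in i_idx], dtype=int) - 1 if n else np.array([], int)
    lo = np.maximum(lo, gene.start)
    hi = np.minimum(hi, gene.end - Ls)
    starts = lo + _uniform_starts(rng, n, hi - lo)
    anti = rng.random(n) < config.antisense_intron_reads
    keep = rng.random(n) < _mult(sample, "intron", anti)
    basis_23as += int(np.sum(keep & anti & (Ls == 23)))
    seqs, regions, origins, senses = [], [], [], []
    starts_l, Ls_l, anti_l, i_l = starts.tolist(), Ls.tolist(), anti.tolist(), i_idx.tolist()
    for i in np.flatnonzero(keep).tolist():
        s0, L = starts_l[i], Ls_l[i]
        sub = scaffold[s0 : s0 + L]
        seqs.append(revcomp(sub) if anti_l[i] else sub)
        regions.append(f"intron{i_l[i] + 1}")
        origins.append(s0)
        senses.append("antisense" if anti_l[i] else "sense")
    emit("intron", seqs, regions, config.scaffold_id, origins, senses)

    # --- secondary reads, calibrated to the realized primary coverage -------
    L_primary = sum(s.ref_end - s.ref_start for s in tg.parent_segments)
    q23as = config.length_probs.get(23, 0.0) * config.antisense_secondary
    for region in refs.region_set.by_role("secondary_only"):
        f = float(config.secondary_fractions.get(region.name, 0.0))
        n23 = int(round(f * basis_23as * region.length / L_primary))
        n_other = int(round(n23 * (1.0 - q23as) / q23as)) if q23as > 0 else 0
        # the planted 23 nt antisense complement
        starts = region.start + _uniform_starts(rng, n23, region.length - 23)
        anti = np.ones(n23, dtype=bool)
        keep = rng.random(n23) < _mult(sample, "secondary", anti)
        seqs = [revcomp(scaffold[int(s) : int(s) + 23]) for s in starts[keep]]
        emit("secondary", seqs, [region.name] * len(seqs), config.scaffold_id,
             starts[keep], ["antisense"] * len(seqs))
        # remaining lengths/strands, conditioned on not (23 nt & antisense)
        lengths = np.array(sorted(config.length_probs), dtype=int)
        p_len = np.array([config.length_probs[int(k)] for k in lengths], dtype=float)
        joint = np.concatenate(
            [p_len * (1 - config.antisense_secondary), p_len * config.antisense_secondary]
        )
        where23 = np.where(lengths == 23)[0]
        if len(where23):
            joint[len(lengths) + int(where23[0])] = 0.0
        joint = joint / joint.sum() if joint.sum() > 0 else joint
        pick = rng.choice(len(joint), size=n_other, p=joint) if n_other else np.array([], int)
        Ls = lengths[pick % len(lengths)]
        anti = pick >= len(lengths)
        starts = region.start + _uniform_starts(rng, n_other, region.length - Ls)
        keep = rng.random(n_other) < _mult(sample, "secondary", anti)
        seqs, origins, senses = [], [], []
        starts_l, Ls_l, anti_l = starts.tolist(), Ls.tolist(), anti.tolist()
        for i in np.flatnonzero(keep).tolist():
            s0, L = starts_l[i], Ls_l[i]
            sub = scaffold[s0 : s0 + L]
            seqs.append(revcomp(sub) if anti_l[i] else sub)
            origins.append(s0)
            senses.append("antisense" if anti_l[i] else "sense")
        emit("secondary", seqs, [region.name] * len(seqs), config.scaffold_id, origins, senses)

    # --- background reads from the rest of the scaffold ---------------------
    n = config.n_background
    Ls = _draw_lengths(rng, config.length_probs, n)
    left_room = gene.start - Ls  # last start keeping the read fully left of the gene
    right_room = len(scaffold) - gene.end - Ls
    p_left = gene.start / max(1, gene.start + (len(scaffold) - gene.end))
    side_left = rng.random(n) < p_left
    starts = np.where(
        side_left,
        _uniform_starts(rng, n, np.maximum(left_room, 0)),
        gene.end + _uniform_starts(rng, n, np.maximum(right_room, 0)),
    )
    anti = rng.random(n) < 0.5
    seqs, senses = [], []
    starts_l, Ls_l, anti_l = starts.tolist(), Ls.tolist(), anti.tolist()
    for i in range(n):
        s0 = starts_l[i]
        sub = scaffold[s0 : s0 + Ls_l[i]]
        seqs.append(revcomp(sub) if anti_l[i] else sub)
        senses.append("antisense" if anti_l[i] else "sense")
    emit("background", seqs, ["genome"] * n, config.scaffold_id, starts_l, senses)

    # --- structural contaminants and feeding reads ---------------------------
    for clazz, ref_id, seq_src, count in (
        ("structural", refs.structural_id, refs.contaminants.seqs[refs.structural_id],
         config.n_structural),
        ("feeding", refs.feeding_refs[sample.knockdown_gene],
         refs.targets.seqs[refs.feeding_refs[sample.knockdown_gene]], config.n_feeding),
    ):
        Ls = _draw_lengths(rng, config.length_probs, count)
        starts = _uniform_starts(rng, count, len(seq_src) - Ls)
        anti = rng.random(count) < 0.5
        seqs, senses = [], []
        starts_l, Ls_l, anti_l = starts.tolist(), Ls.tolist(), anti.tolist()
        for i in range(count):
            s0 = starts_l[i]
            sub = seq_src[s0 : s0 + Ls_l[i]]
            seqs.append(revcomp(sub) if anti_l[i] else sub)
            senses.append("antisense" if anti_l[i] else "sense")
        emit(clazz, seqs, [clazz] * count, ref_id, starts_l, senses)

    truth_df = pd.DataFrame(cols)
    return reads, truth_df


# ---------------------------------------------------------------------------
# long-RNA simulation

LONG_TRUTH_COLUMNS = [
    "read_id", "clazz", "retained_introns", "transcript_start", "length",
    "antisense_intron_spliced",
]


def simulate_long_rnas(
    config: SimConfig,
    refs: References,
    rng: np.random.Generator,
) -> tuple[list[Read], pd.DataFrame]:
    """Long reads from sense transcripts with per-intron retention, plus
    antisense reads from bidirectional transcription."""
    gene = refs.gene
    introns_local = [(s - gene.start, e - gene.start) for s, e in gene.introns]
    k = len(introns_local)
    L = config.long_read_length
    n = config.n_long_reads

    p = config.intron_retention
    p_vec = np.full(k, p) if np.isscalar(p) else np.asarray(p, dtype=float)
    if p_vec.shape != (k,):
        raise ValidationError(f"intron_retention must be scalar or length {k}")

    # isoform cache by retention mask
    g = gene.sequence
    iso_cache: dict[int, str] = {}

    def isoform(mask: int) -> str:
        if mask not in iso_cache:
            seq_parts, pos = [], 0
            for i, (s, e) in enumerate(introns_local):
                seq_parts.append(g[pos:s])
                if mask >> i & 1:
                    seq_parts.append(g[s:e])
                pos = e
            seq_parts.append(g[pos:])
            iso_cache[mask] = "".join(seq_parts)
        return iso_cache[mask]

    if L > len(isoform(0)):
        raise ValidationError("read length exceeds the fully spliced transcript")

    a_s, a_e = config.antisense_intron
    as_variant_spliced = revcomp(g[:a_s] + g[a_e:])
    as_variant_full = revcomp(g)

    anti = rng.random(n) < config.long_antisense_fraction
    ret = rng.random((n, k)) < p_vec[None, :]
    as_spliced = rng.random(n) < config.antisense_intron_splice_prob
    u_start = rng.random(n)

    reads: list[Read] = []
    truth: list[tuple] = []
    for i in range(n):
        if anti[i]:
            transcript = as_variant_spliced if as_spliced[i] else as_variant_full
            retained = ",".join(str(j + 1) for j in range(k))  # nascent: all retained
            clazz = "long_antisense"
            spliced_flag = bool(as_spliced[i])
        else:
            mask = int(sum(1 << j for j in range(k) if ret[i, j]))
            transcript = isoform(mask)
            retained = ",".join(str(j + 1) for j in range(k) if ret[i, j])
            clazz = "long_sense"
            spliced_flag = False
        start = int(u_start[i] * (len(transcript) - L + 1))
        rid = f"long.{clazz}.{i:06d}"
        reads.append((rid, transcript[start : start + L]))
        truth.append((rid, clazz, retained, start, L, spliced_flag))
    return reads, pd.DataFrame(truth, columns=LONG_TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# ChIP-qPCR table with planted effects

# percent-input building blocks: H3 occupancy per (sample, locus), reference-
# locus percent input per antibody, and the planted fully-normalized values.
_H3_PERCENT_INPUT = {
    ("wildtype", "target_5prime"): 8.0,
    ("wildtype", "target_3prime"): 8.0,
    ("wildtype", "reference_promoter"): 10.0,
    ("transgenic", "target_5prime"): 12.0,
    ("transgenic", "target_3prime"): 14.0,
    ("transgenic", "reference_promoter"): 10.0,
}
_REFERENCE_PERCENT_INPUT = {"H3": 10.0, "H3K9ac": 5.0, "H3K4me3": 5.0, "H3K27me3": 2.0}
#: fully normalized (H3- and reference-normalized) planted chain values;
#: H3K27me3 at the 3'-CDS carries the planted 4-fold transgenic/wildtype gain
PLANTED_CHAIN = {
    ("H3K9ac", "target_5prime"): {"wildtype": 2.0, "transgenic": 0.7},
    ("H3K9ac", "target_3prime"): {"wildtype": 1.5, "transgenic": 0.9},
    ("H3K4me3", "target_5prime"): {"wildtype": 2.2, "transgenic": 0.8},
    ("H3K4me3", "target_3prime"): {"wildtype": 1.4, "transgenic": 0.9},
    ("H3K27me3", "target_5prime"): {"wildtype": 0.5, "transgenic": 1.2},
    ("H3K27me3", "target_3prime"): {"wildtype": 0.625, "transgenic": 2.5},
}


def planted_percent_input() -> dict:
    """Percent-input truth per (sample, antibody, locus), derived so that the
    H3+reference normalization chain reproduces :data:`PLANTED_CHAIN`."""
    out = {}
    for (sample, locus), h3 in _H3_PERCENT_INPUT.items():
        out[(sample, "H3", locus)] = h3
    for ab, ref_pi in _REFERENCE_PERCENT_INPUT.items():
        for sample in ("wildtype", "transgenic"):
            out[(sample, ab, "reference_promoter")] = ref_pi
    for (ab, locus), values in PLANTED_CHAIN.items():
        for sample, chain in values.items():
            h3_locus = _H3_PERCENT_INPUT[(sample, locus)]
            h3_ref = _H3_PERCENT_INPUT[(sample, "reference_promoter")]
            ref_term = _REFERENCE_PERCENT_INPUT[ab] / h3_ref
            out[(sample, ab, locus)] = chain * h3_locus * ref_term
    return out


def simulate_ct_table(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_bio_reps: int = 3,
    n_tech_reps: int = 3,
) -> pd.DataFrame:
    """Well-level Ct table (three biological x three technical replicates)."""
    if rng is None:
        rng = stage_rng(config.seed, _STAGE_CT)
    rows = []
    truth = planted_percent_input()
    for (sample, ab, locus), pi in sorted(truth.items()):
        for b in range(1, n_bio_reps + 1):
            bio_pi = pi * 2.0 ** rng.normal(0.0, config.ct_bio_sd)
            for t in range(1, n_tech_reps + 1):
                ct_input = 24.0 + rng.normal(0.0, config.ct_tech_sd)
                ct_ip = (
                    ct_input
                    - math.log2(1.0 / DEFAULT_INPUT_FRACTION)
                    - math.log2(bio_pi / 100.0)
                    + rng.normal(0.0, config.ct_tech_sd)
                )
                rows.append((sample, ab, locus, b, t, ct_ip, ct_input, DEFAULT_INPUT_FRACTION))
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# whole cohorts


@dataclass
class SimulatedSample:
    spec: SampleSpec
    reads: list
    truth: pd.DataFrame


@dataclass
class Cohort:
    config: SimConfig
    refs: References
    samples: dict  # sample_id -> SimulatedSample
    long_reads: list
    long_truth: pd.DataFrame
    ct_table: pd.DataFrame

    @property
    def control(self) -> SimulatedSample:
        return self.samples[self.config.control_sample.sample_id]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate references, every sample's small RNAs, long reads and the
    ChIP Ct table, each from its own seed-derived RNG stream."""
    refs = build_references(config)
    samples: dict[str, SimulatedSample] = {}
    for i, spec in enumerate(config.samples):
        rng = stage_rng(config.seed, _STAGE_SAMPLE_BASE + i)
        reads, truth = simulate_small_rnas(config, refs, rng, spec)
        samples[spec.sample_id] = SimulatedSample(spec, reads, truth)
    long_reads, long_truth = simulate_long_rnas(config, refs, stage_rng(config.seed, _STAGE_LONG))
    ct = simulate_ct_table(config)
    return Cohort(config, refs, samples, long_reads, long_truth, ct)
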