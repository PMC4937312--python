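"""Small-RNA filtering, exact-match mapping and region quantification.

The mapping model follows the study design: reads of 17-25 nt are kept only
if they match a reference substring with zero mismatches (on either strand),
mapping is done in two rounds (contaminant/structural references first, then
the target references), and region counts resolve sense/antisense against
the annotated coding strand of the target gene.

Multi-mapped reads are counted at every locus they match and carry their
multimap count; boundary-straddling alignments count in every region they
overlap by at least one nucleotide.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ValidationError
from .genemodels import GeneModel, RegionSet, spliced_sequence
from .io import Read, open_sam_writer
from .sequtils import is_acgt, revcomp

LENGTH_RANGE = tuple(range(17, 26))


@dataclass(frozen=True)
class SmallReadAlignment:
    read_id: str
    reference_id: str
    start: int  # 0-based on the reference
    length: int
    strand: str  # '+': read equals reference substring; '-': reverse complement does
    multimap: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length


class ReferenceSet:
    """Named references for exact matching (sequences upper-cased).

    A k-mer position index (k = 17, the shortest read the filter admits) is
    built lazily and lets :func:`exact_match` verify candidate loci instead
    of scanning every reference per read; results are identical to a full
    sliding-window scan.
    """

    INDEX_K = 17

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = {name: s.upper() for name, s in seqs.items()}
        self._index: Optional[dict[str, list[tuple[str, int]]]] = None

    def __iter__(self):
        return iter(self.seqs.items())

    def __contains__(self, name: str) -> bool:
        return name in self.seqs

    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    def index(self) -> dict[str, list[tuple[str, int]]]:
        if self._index is None:
            k = self.INDEX_K
            idx: dict[str, list[tuple[str, int]]] = {}
            for ref_id, seq in self.seqs.items():
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((ref_id, pos))
            self._index = idx
        return self._index


def length_filter(reads: Iterable[Read], min_len: int = 17, max_len: int = 25) -> list[Read]:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    return [(rid, seq) for rid, seq in reads if min_len <= len(seq) <= max_len]


def exact_match(read_seq: str, refs: ReferenceSet, read_id: str = "read") -> list[SmallReadAlignment]:
    """Every zero-mismatch occurrence of the read on both strands of every reference."""
    read_seq = read_seq.upper()
    if not is_acgt(read_seq):
        warnings.warn(f"read {read_id} contains ambiguous bases; skipped", stacklevel=2)
        return []
    rc = revcomp(read_seq)
    n = len(read_seq)
    hits: list[tuple[str, int, str]] = []
    if n >= ReferenceSet.INDEX_K:
        idx = refs.index()
        seqs = refs.seqs
        for needle, strand in ((read_seq, "+"), (rc, "-")):
            for ref_id, pos in idx.get(needle[: ReferenceSet.INDEX_K], ()):
                if seqs[ref_id].startswith(needle, pos):
                    hits.append((ref_id, pos, strand))
    else:  # reads shorter than the index k-mer: full scan
        for ref_id, seq in refs:
            for needle, strand in ((read_seq, "+"), (rc, "-")):
                pos = seq.find(needle)
                while pos != -1:
                    hits.append((ref_id, pos, strand))
                    pos = seq.find(needle, pos + 1)
    m = len(hits)
    return [
        SmallReadAlignment(read_id, ref_id, pos, n, strand, m) for ref_id, pos, strand in hits
    ]


@dataclass
class ReadAssignments:
    """Per-read outcome of the two-round alignment."""

    labels: dict[str, str]  # 'contaminant' | 'mapped' | 'unmapped'
    alignments: dict[str, list[SmallReadAlignment]]  # round-2 target alignments
    read_lengths: dict[str, int]

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def mapped_to(self, ref_ids: Iterable[str]) -> set[str]:
        """Ids of reads with at least one alignment to any of the given references."""
        wanted = set(ref_ids)
        return {
            rid
            for rid, alns in self.alignments.items()
            if any(a.reference_id in wanted for a in alns)
        }

    def flat_alignments(self) -> list[SmallReadAlignment]:
        out: list[SmallReadAlignment] = []
        for alns in self.alignments.values():
            out.extend(alns)
        return out


def two_round_align(
    reads: Iterable[Read],
    contaminant_refs: ReferenceSet,
    target_refs: ReferenceSet,
) -> ReadAssignments:
    """Round 1 against contaminant references, round 2 against targets.

    A read with any exact contaminant hit is labelled ``contaminant`` and
    excluded from round 2 (the study maps structural-RNA sources first and
    only carries unmatched reads to the genome).
    """
    if not target_refs.seqs:
        raise ValidationError("no target references")
    labels: dict[str, str] = {}
    alignments: dict[str, list[SmallReadAlignment]] = {}
    read_lengths: dict[str, int] = {}
    for rid, seq in reads:
        read_lengths[rid] = len(seq)
        if exact_match(seq, contaminant_refs, rid):
            labels[rid] = "contaminant"
            continue
        hits = exact_match(seq, target_refs, rid)
        if hits:
            labels[rid] = "mapped"
            alignments[rid] = hits
        else:
            labels[rid] = "unmapped"
    return ReadAssignments(labels, alignments, read_lengths)


# ---------------------------------------------------------------------------
# quantification


def alignments_frame(alignments: Iterable[SmallReadAlignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.read_id, a.reference_id, a.start, a.end, a.length, a.strand, a.multimap) for a in alignments],
        columns=["read_id", "reference_id", "start", "end", "length", "strand", "multimap"],
    )


def count_regions(
    alignments: Iterable[SmallReadAlignment] | pd.DataFrame,
    region_set: RegionSet,
    lengths: Sequence[int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Sense/antisense counts per (region, read length).

    An alignment is counted in every region its interval overlaps by >= 1 nt;
    sense means alignment strand equals the region's coding strand.
    """
    df = alignments if isinstance(alignments, pd.DataFrame) else alignments_frame(alignments)
    known_refs = set(df["reference_id"]) if len(df) else set()
    rows = []
    for region in region_set:
        if len(df):
            sub = df[
                (df["reference_id"] == region.reference_id)
                & (df["start"] < region.end)
                & (df["end"] > region.start)
            ]
        else:
            sub = df
        for L in lengths:
            at_len = sub[sub["length"] == L] if len(sub) else sub
            sense = int((at_len["strand"] == region.coding_strand).sum()) if len(at_len) else 0
            rows.append(
                {
                    "region": region.name,
                    "role": region.role,
                    "length": L,
                    "sense": sense,
                    "antisense": len(at_len) - sense,
                }
            )
    _ = known_refs  # regions on unseen references simply count zero
    return pd.DataFrame(rows)


def antisense_ratio(counts: pd.DataFrame, length: Optional[int] = 23) -> pd.DataFrame:
    """antisense/(sense+antisense) per region; NA when both counts are zero."""
    df = counts if length is None else counts[counts["length"] == length]
    agg = df.groupby(["region", "role"], sort=False)[["sense", "antisense"]].sum().reset_index()
    total = agg["sense"] + agg["antisense"]
    agg["antisense_ratio"] = np.where(total > 0, agg["antisense"] / total.where(total > 0, 1), np.nan)
    return agg


def length_histogram(
    alignments: Iterable[SmallReadAlignment] | pd.DataFrame,
    region_set: Optional[RegionSet] = None,
    lengths: Sequence[int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Read-length histogram 17..25 by region (or overall) and strand."""
    df = alignments if isinstance(alignments, pd.DataFrame) else alignments_frame(alignments)
    if region_set is None:
        rows = []
        for L in lengths:
            sub = df[df["length"] == L] if len(df) else df
            plus = int((sub["strand"] == "+").sum()) if len(sub) else 0
            rows.append({"region": "all", "length": L, "sense": plus, "antisense": len(sub) - plus})
        return pd.DataFrame(rows)
    return count_regions(df, region_set, lengths).rename(columns={})


def modal_length(hist: pd.DataFrame, region: Optional[str] = None, strand: Optional[str] = None) -> int:
    """Modal read length of a histogram, optionally restricted to a region/strand."""
    df = hist
    if region is not None:
        df = df[df["region"] == region]
    if strand == "sense":
        series = df.groupby("length")["sense"].sum()
    elif strand == "antisense":
        series = df.groupby("length")["antisense"].sum()
    else:
        series = df.groupby("length")[["sense", "antisense"]].sum().sum(axis=1)
    return int(series.idxmax())


# ---------------------------------------------------------------------------
# junction / intron classification

JUNCTION_OVERHANG = 4  # minimum nt on each side of an exon-exon boundary


def _occurrences(needle: str, hay: str) -> list[int]:
    out = []
    pos = hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def classify_junction_intron(
    reads: Iterable[Read], gene: GeneModel
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Classify small reads as exon-exon junction reads or intron reads.

    A junction read matches the spliced mRNA (either strand) across an
    exon-exon boundary with more than :data:`JUNCTION_OVERHANG` nt on each
    side and has no exact match to the unspliced genomic sequence (such reads
    can only derive from a spliced-RNA template). An intron read matches the
    genomic sequence overlapping an intron by >= 1 nt. The two classes are
    disjoint by construction.
    """
    introns = gene.introns
    table_columns = ["kind", "index", "sense", "antisense", "antisense_ratio"]
    if not introns:
        return pd.DataFrame(columns=table_columns), {}
    sp = spliced_sequence(gene)
    genomic = gene.sequence
    mrna = sp.mrna
    coding = gene.coding_strand

    n_i, n_j = len(introns), len(sp.junctions)
    counts = {
        ("intron", i): {"sense": 0, "antisense": 0} for i in range(n_i)
    }
    counts.update({("junction", j): {"sense": 0, "antisense": 0} for j in range(n_j)})
    per_read: dict[str, str] = {}

    for rid, seq in reads:
        seq = seq.upper()
        if not is_acgt(seq):
            continue
        rc = revcomp(seq)
        L = len(seq)
        g_hits = [(p, "+") for p in _occurrences(seq, genomic)] + [
            (p, "-") for p in _occurrences(rc, genomic)
        ]
        if g_hits:
            called = False
            for pos, strand in g_hits:
                a, b = pos + gene.start, pos + gene.start + L
                sense = "sense" if strand == coding else "antisense"
                for i, (s, e) in enumerate(introns):
                    if a < e and s < b:
                        counts[("intron", i)][sense] += 1
                        called = True
            if called:
                per_read[rid] = "intron"
            continue
        m_hits = [(p, "+") for p in _occurrences(seq, mrna)] + [
            (p, "-") for p in _occurrences(rc, mrna)
        ]
        called = False
        for pos, strand in m_hits:
            sense = "sense" if strand == coding else "antisense"
            for j, jpos in enumerate(sp.junctions):
                if pos + JUNCTION_OVERHANG <= jpos <= pos + L - JUNCTION_OVERHANG:
                    counts[("junction", j)][sense] += 1
                    called = True
        if called:
            per_read[rid] = "junction"

    rows = []
    for (kind, idx), c in counts.items():
        total = c["sense"] + c["antisense"]
        rows.append(
            {
                "kind": kind,
                "index": idx + 1,
                "sense": c["sense"],
                "antisense": c["antisense"],
                "antisense_ratio": c["antisense"] / total if total else np.nan,
            }
        )
    table = pd.DataFrame(rows).sort_values(["kind", "index"]).reset_index(drop=True)
    return table, per_read


# ---------------------------------------------------------------------------
# SAM export


def write_sam(
    path,
    assignments: ReadAssignments,
    reads: Mapping[str, str],
    refs: ReferenceSet,
) -> None:
    """Write mapped alignments as SAM.

    Reverse-strand alignments are stored reverse-complemented with flag 16;
    secondary hits of a multi-mapped read get flag 256 and all carry the
    multimap count in the NH tag. Output order is deterministic:
    (reference, start, strand, read_id).
    """
    ordered = sorted(
        assignments.flat_alignments(),
        key=lambda a: (a.reference_id, a.start, a.strand, a.read_id),
    )
    seen: set[str] = set()
    with open_sam_writer(path, refs.lengths()) as sam:
        tids = {name: i for i, name in enumerate(refs.lengths())}
        for a in ordered:
            seq = reads[a.read_id].upper()
            rec = _aligned_segment(sam, tids, a, seq, secondary=a.read_id in seen)
            sam.write(rec)
            seen.add(a.read_id)


def _aligned_segment(sam, tids, a: SmallReadAlignment, seq: str, secondary: bool):
    rec = pysam.AlignedSegment(sam.header)
    rec.query_name = a.read_id
    rec.reference_id = tids[a.reference_id]
    rec.reference_start = a.start
    rec.mapping_quality = 255
    rec.cigarstring = f"{a.length}M"
    flag = 0
    if a.strand == "-":
        flag |= 16
        seq = revcomp(seq)
    if secondary:
        flag |= 256
    rec.flag = flag
    rec.query_sequence = seq
    rec.set_tag("NH", a.multimap)
    return rec
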