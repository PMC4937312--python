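"""Long-read spliced alignment and per-intron splice-rate estimation.

Long reads (>60 nt after trimming) are aligned against the *enumerated
isoform set* of a gene model: every retain/splice combination of its
annotated introns (2^n isoforms, n <= 8) plus the plain genomic sequence,
on both strands, allowing up to one mismatch. The best alignment (fewest
mismatches, then fewest gaps, then leftmost) is mapped back to genomic
blocks and gaps.

Per intron, an aligned read is a *spliced* candidate when it aligns to the
exon region on both sides with a gap exactly at the intron, *un-spliced*
when its aligned blocks extend more than four basepairs into the intron
from a boundary, and excluded otherwise (1-4 bp incursions without a gap,
or reads touching only one flank). The splice rate of an intron is
n_spliced / (n_spliced + n_unspliced).

A separate scan looks for *antisense introns*: gaps of plausible intron
length in antisense reads, with GT...AG boundaries on the read's strand,
that do not coincide with any annotated sense intron.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genemodels import GeneModel, Interval
from .io import Read, open_sam_writer
from .sequtils import revcomp

MIN_LONG_READ_LENGTH = 60  # strict: reads longer than this are kept
UNSPLICED_MIN_INCURSION = 4  # > 4 bp into the intron marks a read un-spliced
MAX_ISOFORM_INTRONS = 8


def filter_long_reads(reads: Iterable[Read], min_len: int = MIN_LONG_READ_LENGTH) -> list[Read]:
    """Keep reads strictly longer than ``min_len`` nucleotides."""
    return [(rid, seq) for rid, seq in reads if len(seq) > min_len]


@dataclass(frozen=True)
class LongReadAlignment:
    read_id: str
    reference_id: str
    strand: str  # '+': read matches top strand forward
    blocks: tuple[Interval, ...]  # genomic reference coordinates, sorted
    mismatches: int

    @property
    def gaps(self) -> tuple[Interval, ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(b - a for a, b in self.blocks)


class IsoformAligner:
    """Model-guided aligner over the 2^n retain/splice isoforms of a gene."""

    def __init__(self, gene: GeneModel, max_mismatches: int = 1, seed_len: int = 16):
        introns = gene.introns
        if len(introns) > MAX_ISOFORM_INTRONS:
            raise ValidationError(
                f"{len(introns)} introns exceed the isoform-enumeration limit "
                f"({MAX_ISOFORM_INTRONS})"
            )
        self.gene = gene
        self.max_mismatches = max_mismatches
        self.seed_len = seed_len
        self.isoforms: list[tuple[tuple[Interval, ...], str]] = []
        n = len(introns)
        for mask in range(2 ** n):
            retained = [introns[i] for i in range(n) if mask >> i & 1]
            blocks = self._blocks_with(retained)
            seq = "".join(gene.subseq(a, b) for a, b in blocks)
            self.isoforms.append((blocks, seq))

    def _blocks_with(self, retained: Sequence[Interval]) -> tuple[Interval, ...]:
        pieces = sorted([*self.gene.exons, *retained])
        merged: list[Interval] = []
        for a, b in pieces:
            if merged and merged[-1][1] == a:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        return tuple(merged)

    # -- candidate offsets on one isoform sequence --------------------------
    def _candidate_offsets(self, needle: str, hay: str) -> set[int]:
        offs: set[int] = set()
        L = len(needle)
        pos = hay.find(needle)
        while pos != -1:  # exact occurrences
            offs.add(pos)
            pos = hay.find(needle, pos + 1)
        if self.max_mismatches >= 1:
            half = L // 2
            for seed, shift in ((needle[:half], 0), (needle[half:], half)):
                pos = hay.find(seed)
                while pos != -1:
                    off = pos - shift
                    if 0 <= off <= len(hay) - L:
                        offs.add(off)
                    pos = hay.find(seed, pos + 1)
        return offs

    @staticmethod
    def _hamming(a: str, b: str, limit: int) -> int:
        mm = 0
        for x, y in zip(a, b):
            if x != y:
                mm += 1
                if mm > limit:
                    return mm
        return mm

    @staticmethod
    def _slice_blocks(blocks: Sequence[Interval], off: int, length: int) -> tuple[Interval, ...]:
        """Genomic blocks of isoform interval [off, off+length)."""
        out: list[Interval] = []
        pos = 0
        for a, b in blocks:
            blen = b - a
            lo = max(off, pos)
            hi = min(off + length, pos + blen)
            if lo < hi:
                out.append((a + lo - pos, a + hi - pos))
            pos += blen
            if pos >= off + length:
                break
        return tuple(out)

    def align(self, read_id: str, seq: str) -> Optional[LongReadAlignment]:
        seq = seq.upper()
        rc = revcomp(seq)
        L = len(seq)
        best: dict[tuple[str, tuple[Interval, ...]], int] = {}
        # pass 1: exact occurrences only; any hit makes mismatch seeding moot
        for blocks, iso_seq in self.isoforms:
            if L > len(iso_seq):
                continue
            for needle, strand in ((seq, "+"), (rc, "-")):
                pos = iso_seq.find(needle)
                while pos != -1:
                    best.setdefault((strand, self._slice_blocks(blocks, pos, L)), 0)
                    pos = iso_seq.find(needle, pos + 1)
        if not best and self.max_mismatches >= 1:
            for blocks, iso_seq in self.isoforms:
                if L > len(iso_seq):
                    continue
                for needle, strand in ((seq, "+"), (rc, "-")):
                    for off in self._candidate_offsets(needle, iso_seq):
                        mm = self._hamming(needle, iso_seq[off : off + L], self.max_mismatches)
                        if mm > self.max_mismatches:
                            continue
                        key = (strand, self._slice_blocks(blocks, off, L))
                        if key not in best or mm < best[key]:
                            best[key] = mm
        if not best:
            return None
        (strand, blocks), mm = min(
            best.items(),
            key=lambda kv: (kv[1], len(kv[0][1]) - 1, kv[0][1][0][0], kv[0][0] != "+"),
        )
        return LongReadAlignment(read_id, self.gene.reference_id, strand, blocks, mm)


def align_long(
    read: Read, gene: GeneModel, aligner: Optional[IsoformAligner] = None
) -> Optional[LongReadAlignment]:
    """Align one long read against a gene's isoform set (convenience wrapper)."""
    if aligner is None:
        aligner = IsoformAligner(gene)
    return aligner.align(*read)


# ---------------------------------------------------------------------------
# splice classification


def classify_splice(
    aln: LongReadAlignment, intron: Interval, gene: Optional[GeneModel] = None
) -> str:
    """'spliced', 'unspliced' or 'not_candidate' for one intron."""
    if gene is not None and tuple(intron) not in gene.introns:
        raise ValidationError(f"intron {intron} not in gene model")
    s, e = intron
    if (s, e) in aln.gaps:
        return "spliced"
    pen = 0
    for a, b in aln.blocks:
        if a <= s < b:  # enters the intron across (or at) its 5' boundary
            pen = max(pen, min(b, e) - s)
        if a < e <= b:  # enters across the 3' boundary
            pen = max(pen, e - max(a, s))
    if pen > UNSPLICED_MIN_INCURSION:
        return "unspliced"
    return "not_candidate"


@dataclass
class SpliceCallSummary:
    """Per-intron spliced/un-spliced candidate counts and rates.

    ``splice_rate_raw`` is the plain read-count fraction
    n_spliced/(n_spliced+n_unspliced). ``splice_rate`` additionally
    normalizes each class by its start-position footprint: for reads of
    length L over an intron of length I, a spliced candidate can start at
    L-1 transcript positions (the read must cross the junction with >=1 nt
    on each side) while an un-spliced call can arise from L+I+1-2c positions
    (incursion deeper than c-1=4 bp from either boundary), so raw read
    counting over-weights un-spliced transcripts by roughly (L+I-9)/(L-1).
    The corrected rate estimates the fraction of *transcripts* spliced at
    the intron and converges to 1 - retention probability.
    """

    table: pd.DataFrame

    @property
    def mean_rate(self) -> float:
        """Unweighted mean of per-intron (footprint-corrected) splice rates."""
        return float(self.table["splice_rate"].mean())


def splice_rates(
    alignments: Iterable[LongReadAlignment],
    gene: GeneModel,
    strands: Sequence[str] = ("+", "-"),
    footprint_correction: bool = True,
) -> SpliceCallSummary:
    introns = gene.introns
    counts = {iv: {"spliced": 0, "unspliced": 0, "not_candidate": 0} for iv in introns}
    lensum = {iv: 0 for iv in introns}
    for aln in alignments:
        if aln.strand not in strands:
            continue
        lo, hi = aln.span
        for iv in introns:
            s, e = iv
            if lo < e and s < hi:
                call = classify_splice(aln, iv)
                counts[iv][call] += 1
                if call != "not_candidate":
                    lensum[iv] += aln.aligned_length
    rows = []
    c_thr = UNSPLICED_MIN_INCURSION + 1
    for i, iv in enumerate(introns):
        c = counts[iv]
        denom = c["spliced"] + c["unspliced"]
        raw = c["spliced"] / denom if denom else np.nan
        rate = raw
        if footprint_correction and denom:
            mean_len = lensum[iv] / denom
            intron_len = iv[1] - iv[0]
            w_s = mean_len - 1
            w_u = mean_len + intron_len + 1 - 2 * c_thr
            if w_s > 0 and w_u > 0:
                ws_s = c["spliced"] / w_s
                ws_u = c["unspliced"] / w_u
                rate = ws_s / (ws_s + ws_u)
        rows.append(
            {
                "intron": i + 1,
                "start": iv[0],
                "end": iv[1],
                "n_spliced": c["spliced"],
                "n_unspliced": c["unspliced"],
                "n_excluded_ambiguous": c["not_candidate"],
                "splice_rate_raw": raw,
                "splice_rate": rate,
            }
        )
    return SpliceCallSummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# antisense intron detection

ANTISENSE_GAP_RANGE = (18, 35)  # plausible Paramecium intron lengths


def detect_antisense_introns(
    reads: Iterable[Read],
    gene: GeneModel,
    min_gap: int = ANTISENSE_GAP_RANGE[0],
    max_gap: int = ANTISENSE_GAP_RANGE[1],
    seed_len: int = 18,
) -> pd.DataFrame:
    """Scan reads for one novel splice gap with intron-like boundaries.

    Reports gaps of 18-35 nt that are not equal to any annotated sense
    intron and read GT...AG on the strand the read aligns to, each with its
    supporting read count and whether supporting reads retain the sense
    introns they overlap.
    """
    g = gene.sequence
    glen = len(g)
    local_introns = {(s - gene.start, e - gene.start) for s, e in gene.introns}
    candidates: dict[tuple[int, int, str], dict] = {}

    for rid, seq in reads:
        seq = seq.upper()
        L = len(seq)
        if L <= 2 * seed_len:
            continue
        for oriented, strand in ((seq, "+"), (revcomp(seq), "-")):
            hit = _split_align(oriented, g, glen, min_gap, max_gap, seed_len, strand)
            if hit is None:
                continue
            gs, ge, blocks = hit
            if (gs, ge) in local_introns:
                continue
            key = (gs + gene.start, ge + gene.start, strand)
            rec = candidates.setdefault(
                key, {"support": 0, "support_retaining_sense_introns": 0}
            )
            rec["support"] += 1
            overlapped = [
                iv for iv in local_introns if iv[0] < blocks[-1][1] and blocks[0][0] < iv[1]
            ]
            if overlapped and all(
                any(a <= s_ and e_ <= b for a, b in blocks) for s_, e_ in overlapped
            ):
                rec["support_retaining_sense_introns"] += 1
            break  # one call per read
    rows = [
        {
            "start": k[0],
            "end": k[1],
            "length": k[1] - k[0],
            "strand": k[2],
            "support": v["support"],
            "support_retaining_sense_introns": v["support_retaining_sense_introns"],
        }
        for k, v in candidates.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["support", "start"], ascending=[False, True])
        .reset_index(drop=True)
        if rows
        else pd.DataFrame(
            columns=["start", "end", "length", "strand", "support", "support_retaining_sense_introns"]
        )
    )


def _split_align(oriented, g, glen, min_gap, max_gap, seed_len, strand):
    """Find prefix+suffix exact match with one gap; return gene-local gap and blocks."""
    L = len(oriented)
    p = g.find(oriented[:seed_len])
    while p != -1:
        # extend the prefix
        L1 = seed_len
        while p + L1 < glen and L1 < L and g[p + L1] == oriented[L1]:
            L1 += 1
        if L1 < L:
            suffix_seed = oriented[-seed_len:]
            q = g.find(suffix_seed, p + L1)
            while q != -1:
                gap_len = q - p - (L - seed_len)
                if min_gap <= gap_len <= max_gap:
                    # extend the suffix backwards; j0 = smallest valid split point
                    k = 0
                    while (
                        q - 1 - k >= 0
                        and L - seed_len - 1 - k >= 0
                        and g[q - 1 - k] == oriented[L - seed_len - 1 - k]
                    ):
                        k += 1
                    j0 = L - seed_len - k
                    for j in range(max(1, j0), min(L1, L - 1) + 1):
                        gs, ge = p + j, p + j + gap_len
                        if ge > glen:
                            continue
                        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
                        if g[gs : gs + 2] == donor and g[ge - 2 : ge] == acceptor:
                            return gs, ge, ((p, gs), (ge, ge + (L - j)))
                q = g.find(suffix_seed, q + 1)
        p = g.find(oriented[:seed_len], p + 1)
    return None


# ---------------------------------------------------------------------------
# coverage and export


@dataclass
class StrandCoverage:
    top: np.ndarray
    bottom: np.ndarray

    def to_bedgraph(self, path, reference_id: str) -> None:
        """Run-length bedGraph; bottom-strand depth is written negative."""
        with open(path, "w") as fh:
            for arr, sign in ((self.top, 1), (self.bottom, -1)):
                vals = sign * arr
                start = 0
                for i in range(1, len(vals) + 1):
                    if i == len(vals) or vals[i] != vals[start]:
                        if vals[start] != 0:
                            fh.write(f"{reference_id}\t{start}\t{i}\t{vals[start]}\n")
                        start = i


def strand_coverage(
    alignments: Iterable[LongReadAlignment], reference_length: int
) -> StrandCoverage:
    """Per-base depth by strand from aligned blocks only (gaps contribute 0)."""
    top = np.zeros(reference_length, dtype=np.int64)
    bottom = np.zeros(reference_length, dtype=np.int64)
    for aln in alignments:
        arr = top if aln.strand == "+" else bottom
        for a, b in aln.blocks:
            arr[a:b] += 1
    return StrandCoverage(top, bottom)


def write_long_sam(
    path,
    alignments: Iterable[LongReadAlignment],
    reads: dict[str, str],
    reference_lengths: dict[str, int],
) -> None:
    """SAM export with N CIGAR operations for splice gaps."""
    import pysam

    ordered = sorted(alignments, key=lambda a: (a.reference_id, a.span[0], a.strand, a.read_id))
    with open_sam_writer(path, reference_lengths) as sam:
        tids = {name: i for i, name in enumerate(reference_lengths)}
        for a in ordered:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = tids[a.reference_id]
            rec.reference_start = a.span[0]
            rec.mapping_quality = 255
            cigar = []
            for i, (s, e) in enumerate(a.blocks):
                if i:
                    cigar.append(f"{s - a.blocks[i - 1][1]}N")
                cigar.append(f"{e - s}M")
            rec.cigarstring = "".join(cigar)
            seq = reads[a.read_id].upper()
            rec.flag = 16 if a.strand == "-" else 0
            rec.query_sequence = revcomp(seq) if a.strand == "-" else seq
            rec.set_tag("NM", a.mismatches)
            sam.write(rec)
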