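"""Gene models, truncated-transgene construction and analysis regions.

A :class:`GeneModel` is a single gene on a reference sequence: ordered exons
(0-based, half-open, in reference coordinates), the intervening introns, the
genomic sequence of the gene span, and an annotated coding strand.

A :class:`Transgene` is built from a parent gene by excising deletions and/or
substituting foreign fragments (e.g. a yeast toxin-gene fragment), optionally
followed by a stretch of plasmid "linearization" filler. The construct keeps
an invertible coordinate map back to the parent, which is what lets the
analysis partition the parent gene into transgene-shared (primary-capable)
and transgene-absent (secondary-only) regions: siRNAs mapping to the latter
can only have been produced from the endogenous locus (transitivity).

Coordinates are 0-based half-open internally; GFF3 export is 1-based
inclusive and BED export 0-based half-open, per the usual dialects.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .sequtils import random_seq

Interval = tuple[int, int]


def _check_intervals(ivals: Sequence[Interval], lo: int, hi: int, what: str) -> tuple[Interval, ...]:
    ivals = tuple((int(a), int(b)) for a, b in sorted(ivals))
    prev_end = None
    for a, b in ivals:
        if not (lo <= a < b <= hi):
            raise ValidationError(f"{what} ({a},{b}) out of range [{lo},{hi})")
        if prev_end is not None and a < prev_end:
            raise ValidationError(f"{what} overlap at ({a},{b})")
        prev_end = b
    return ivals


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon/intron structure and sequence on a reference.

    ``sequence`` is the genomic sequence of the span ``[start, start+len)``
    on ``reference_id``; ``exons`` are in reference coordinates.
    """

    gene_id: str
    reference_id: str
    coding_strand: str
    exons: tuple[Interval, ...]
    sequence: str
    start: int = 0

    def __post_init__(self) -> None:
        if self.coding_strand not in "+-" or len(self.coding_strand) != 1:
            raise ValidationError(f"coding_strand must be '+' or '-', got {self.coding_strand!r}")
        if not self.exons:
            raise ValidationError("a gene needs at least one exon")
        exons = _check_intervals(self.exons, self.start, self.end, "exon")
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "sequence", self.sequence.upper())
        if exons[0][0] != self.start or exons[-1][1] != self.end:
            raise ValidationError("gene span must begin and end with an exon")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def local(self, pos: int) -> int:
        """Reference coordinate -> gene-local coordinate."""
        return pos - self.start

    def subseq(self, a: int, b: int) -> str:
        """Sequence of reference interval [a, b) (must lie within the span)."""
        if not (self.start <= a <= b <= self.end):
            raise ValidationError(f"interval ({a},{b}) outside gene span")
        return self.sequence[a - self.start : b - self.start]


@dataclass(frozen=True)
class SplicedSequence:
    """Spliced mRNA of a gene with the exon-exon junction bookkeeping.

    ``junctions`` are mRNA coordinates: junction *j* sits between mRNA
    positions ``junctions[j]-1`` and ``junctions[j]``.
    """

    mrna: str
    junctions: tuple[int, ...]
    exons: tuple[Interval, ...]  # reference coordinates

    def mrna_to_genomic(self, pos: int) -> int:
        if not (0 <= pos < len(self.mrna)):
            raise ValidationError(f"mRNA position {pos} out of range")
        off = 0
        for a, b in self.exons:
            if pos < off + (b - a):
                return a + (pos - off)
            off += b - a
        raise AssertionError("unreachable")

    def genomic_to_mrna(self, pos: int) -> Optional[int]:
        """mRNA coordinate of a genomic position, or None if intronic."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                return off + (pos - a)
            off += b - a
        return None


def spliced_sequence(gene: GeneModel) -> SplicedSequence:
    """Concatenate exon sequences; one junction per intron."""
    parts = [gene.subseq(a, b) for a, b in gene.exons]
    junctions = []
    off = 0
    for p in parts[:-1]:
        off += len(p)
        junctions.append(off)
    return SplicedSequence("".join(parts), tuple(junctions), gene.exons)


# ---------------------------------------------------------------------------
# transgene construction


@dataclass(frozen=True)
class TransgeneSpec:
    """Edits producing a truncated construct from a parent gene.

    Intervals are gene-local (relative to the parent transcription start).
    ``replacements`` entries are ``((start, end), foreign_sequence, name)``.
    """

    parent_gene_id: str
    deletions: tuple[Interval, ...] = ()
    replacements: tuple[tuple[Interval, str, str], ...] = ()
    linearization_offset: int = 0
    promoter: str = "bidirectional"

    def __post_init__(self) -> None:
        if self.promoter not in ("bidirectional", "unidirectional"):
            raise ValidationError(f"unknown promoter kind {self.promoter!r}")
        if self.linearization_offset < 0:
            raise ValidationError("linearization_offset must be >= 0")
        dels = tuple((int(a), int(b)) for a, b in self.deletions)
        repls = tuple(((int(a), int(b)), str(s).upper(), str(n)) for (a, b), s, n in self.replacements)
        object.__setattr__(self, "deletions", dels)
        object.__setattr__(self, "replacements", repls)
        ivals = sorted([*dels, *(iv for iv, _, _ in repls)])
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise ValidationError("deletions/replacements overlap")
        for a, b in ivals:
            if a < 0 or b <= a:
                raise ValidationError(f"bad edit interval ({a},{b})")

    # -- YAML round-trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parent_gene_id": self.parent_gene_id,
            "deletions": [list(iv) for iv in self.deletions],
            "replacements": [
                {"interval": list(iv), "sequence": s, "name": n}
                for iv, s, n in self.replacements
            ],
            "linearization_offset": self.linearization_offset,
            "promoter": self.promoter,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransgeneSpec":
        return cls(
            parent_gene_id=d["parent_gene_id"],
            deletions=tuple(tuple(iv) for iv in d.get("deletions", [])),
            replacements=tuple(
                (tuple(r["interval"]), r["sequence"], r["name"])
                for r in d.get("replacements", [])
            ),
            linearization_offset=int(d.get("linearization_offset", 0)),
            promoter=d.get("promoter", "bidirectional"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransgeneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Segment:
    """One tile of the transgene coordinate map."""

    start: int
    end: int
    kind: str  # 'parent' | 'foreign' | 'filler'
    ref_start: int = -1  # parent reference coordinates (parent segments only)
    ref_end: int = -1
    name: str = ""


@dataclass(frozen=True)
class Transgene:
    transgene_id: str
    parent_gene_id: str
    sequence: str
    segments: tuple[Segment, ...]
    junctions: tuple[int, ...]  # transgene positions of artificial junctions

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValidationError("coordinate map does not tile the transgene")
            pos = seg.end
        if pos != len(self.sequence):
            raise ValidationError("coordinate map does not cover the transgene")

    @property
    def parent_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "parent")

    @property
    def parent_intervals(self) -> tuple[Interval, ...]:
        """Parent reference intervals present in the construct (sorted)."""
        return tuple(sorted((s.ref_start, s.ref_end) for s in self.parent_segments))

    @property
    def insert_end(self) -> int:
        """End of the biological insert (everything before linearization filler)."""
        end = 0
        for s in self.segments:
            if s.kind != "filler":
                end = s.end
        return end

    def map_to_parent(self, pos: int) -> Optional[int]:
        """Parent reference coordinate of a transgene position (None if foreign/filler)."""
        for s in self.segments:
            if s.start <= pos < s.end:
                return s.ref_start + (pos - s.start) if s.kind == "parent" else None
        raise ValidationError(f"transgene position {pos} out of range")

    def map_from_parent(self, ref_pos: int) -> Optional[int]:
        """Transgene coordinate of a parent reference position (None if absent)."""
        for s in self.parent_segments:
            if s.ref_start <= ref_pos < s.ref_end:
                return s.start + (ref_pos - s.ref_start)
        return None


def build_transgene(
    gene: GeneModel,
    spec: TransgeneSpec,
    transgene_id: Optional[str] = None,
    filler_rng: Optional[np.random.Generator] = None,
) -> Transgene:
    """Apply a :class:`TransgeneSpec` to a parent gene.

    The result's sequence equals the parent sequence with deletions excised
    and replacements substituted, followed by ``linearization_offset`` bases
    of seeded random filler (plasmid sequence retained downstream of the
    insert in the linearized construct).
    """
    if spec.parent_gene_id != gene.gene_id:
        raise ValidationError(
            f"spec targets {spec.parent_gene_id!r}, gene is {gene.gene_id!r}"
        )
    span = len(gene.sequence)
    edits = sorted(
        [(a, b, "", "") for a, b in spec.deletions]
        + [(a, b, s, n) for (a, b), s, n in spec.replacements]
    )
    for a, b, _, _ in edits:
        if b > span:
            raise ValidationError(f"edit interval ({a},{b}) outside parent span [0,{span})")

    segments: list[Segment] = []
    seq_parts: list[str] = []
    pos = 0  # gene-local walk position
    out = 0  # transgene position

    def _parent_chunk(a: int, b: int) -> None:
        nonlocal out
        if b <= a:
            return
        segments.append(
            Segment(out, out + (b - a), "parent", gene.start + a, gene.start + b)
        )
        seq_parts.append(gene.sequence[a:b])
        out += b - a

    for a, b, fseq, fname in edits:
        _parent_chunk(pos, a)
        if fseq:
            segments.append(Segment(out, out + len(fseq), "foreign", name=fname))
            seq_parts.append(fseq)
            out += len(fseq)
        pos = b
    _parent_chunk(pos, span)

    if spec.linearization_offset:
        rng = filler_rng if filler_rng is not None else np.random.default_rng(170529)
        filler = random_seq(rng, spec.linearization_offset)
        segments.append(Segment(out, out + len(filler), "filler", name="linearization_filler"))
        seq_parts.append(filler)
        out += len(filler)

    # artificial junctions: abutting non-adjacent parent coordinates, and
    # foreign inserts flanked by parent sequence on both sides
    junctions: list[int] = []
    nonfiller = [s for s in segments if s.kind != "filler"]
    for prev, nxt in zip(nonfiller, nonfiller[1:]):
        if prev.kind == "parent" and nxt.kind == "parent" and prev.ref_end != nxt.ref_start:
            junctions.append(nxt.start)
        if prev.kind == "parent" and nxt.kind == "foreign":
            after = nonfiller[nonfiller.index(nxt) + 1 :]
            if any(s.kind == "parent" for s in after):
                junctions.append(nxt.start)

    return Transgene(
        transgene_id=transgene_id or f"{gene.gene_id}_tg",
        parent_gene_id=gene.gene_id,
        sequence="".join(seq_parts),
        segments=tuple(segments),
        junctions=tuple(junctions),
    )


# ---------------------------------------------------------------------------
# analysis regions


@dataclass(frozen=True)
class Region:
    name: str
    reference_id: str
    start: int
    end: int
    role: str  # 'primary_capable' | 'secondary_only' | 'foreign'
    coding_strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSet:
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValidationError("region names must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_role(self, role: str) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.role == role)

    def union_length(self, role: str) -> int:
        return sum(r.length for r in self.by_role(role))

    def to_bed(self, path) -> None:
        """BED6 plus a 7th column carrying the region role."""
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(
                    f"{r.reference_id}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.coding_strand}\t{r.role}\n"
                )

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        regions = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                regions.append(
                    Region(f[3], f[0], int(f[1]), int(f[2]), f[6], f[5])
                )
        return cls(tuple(regions))


def _merge_adjacent(ivals: Sequence[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for a, b in sorted(ivals):
        if merged and merged[-1][1] == a:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def derive_regions(
    gene: GeneModel,
    transgene: Transgene,
    prefix: str = "ND",
    secondary_names: Optional[Sequence[str]] = None,
) -> RegionSet:
    """Partition the parent gene into primary-capable and secondary-only regions.

    Parent intervals present in the construct can template primary siRNAs;
    intervals absent from it can only yield secondary siRNAs produced at the
    endogenous locus. Foreign inserts become regions on the transgene itself.
    A 5' sub-region (the ND-5' analogue) is emitted from the transcription
    start to the first intron, clipped at the first transgene-absent interval
    so it stays transgene-shared.
    """
    if transgene.parent_gene_id != gene.gene_id:
        raise ValidationError("transgene was not derived from this gene")

    present = _merge_adjacent(transgene.parent_intervals)
    absent: list[Interval] = []
    pos = gene.start
    for a, b in present:
        if a > pos:
            absent.append((pos, a))
        pos = b
    if pos < gene.end:
        absent.append((pos, gene.end))

    regions: list[Region] = []
    if secondary_names is not None and len(secondary_names) != len(absent):
        raise ValidationError(
            f"{len(secondary_names)} secondary names for {len(absent)} secondary regions"
        )
    for i, (a, b) in enumerate(absent):
        name = secondary_names[i] if secondary_names else f"{prefix}-{i + 1}"
        regions.append(Region(name, gene.reference_id, a, b, "secondary_only", gene.coding_strand))

    gene_name = f"{prefix}gene"
    for i, (a, b) in enumerate(present):
        name = gene_name if len(present) == 1 else f"{gene_name}-{i + 1}"
        regions.append(Region(name, gene.reference_id, a, b, "primary_capable", gene.coding_strand))

    # 5' sub-region relative to the coding orientation
    introns = gene.introns
    if gene.coding_strand == "+":
        stops = [s for s, _ in introns] + [a for a, _ in absent if a > gene.start]
        limit = min(stops) if stops else gene.end
        if limit > gene.start:
            regions.append(
                Region(f"{prefix}-5p", gene.reference_id, gene.start, limit, "primary_capable", "+")
            )
    else:
        stops = [e for _, e in introns] + [b for _, b in absent if b < gene.end]
        limit = max(stops) if stops else gene.start
        if limit < gene.end:
            regions.append(
                Region(f"{prefix}-5p", gene.reference_id, limit, gene.end, "primary_capable", "-")
            )

    for seg in transgene.segments:
        if seg.kind == "foreign":
            regions.append(
                Region(seg.name, transgene.transgene_id, seg.start, seg.end, "foreign", "+")
            )

    rs = RegionSet(tuple(regions))
    # invariant: secondary regions never overlap a transgene-mapped interval
    for r in rs.by_role("secondary_only"):
        for a, b in present:
            if r.start < b and a < r.end:
                raise AssertionError("secondary region overlaps transgene-shared interval")
    return rs


# ---------------------------------------------------------------------------
# GFF3 import/export (1-based inclusive on disk)

_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def gene_to_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.reference_id}\tsirnascope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.coding_strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(g.exons):
                fh.write(
                    f"{g.reference_id}\tsirnascope\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.coding_strand}\t.\tID={g.gene_id}.exon{i + 1};Parent={g.gene_id}\n"
                )


def genes_from_gff3(path, sequences: Mapping[str, str]) -> list[GeneModel]:
    """Read gene models written by :func:`gene_to_gff3` (gene + exon features)."""
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(_ATTR_RE.findall(f[8]))
            if f[2] == "gene":
                gene_rows[attrs["ID"]] = {
                    "reference_id": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            elif f[2] == "exon":
                exon_rows.setdefault(attrs["Parent"], []).append((int(f[3]) - 1, int(f[4])))
    genes = []
    for gid, row in gene_rows.items():
        ref_seq = sequences[row["reference_id"]]
        genes.append(
            GeneModel(
                gene_id=gid,
                reference_id=row["reference_id"],
                coding_strand=row["strand"],
                exons=tuple(sorted(exon_rows.get(gid, [(row["start"], row["end"])]))),
                sequence=ref_seq[row["start"] : row["end"]],
                start=row["start"],
            )
        )
    return genes
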