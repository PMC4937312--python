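"""File-format helpers: FASTA, FASTQ, SAM and plain tables.

Readers go through established parsers (Bio.SeqIO for FASTA, pysam for
FASTQ/SAM); writers for the line-oriented formats are simple and direct.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Read = tuple[str, str]  # (read_id, sequence)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[Read]:
    with pysam.FastxFile(str(path)) as fh:
        return [(entry.name, entry.sequence.upper()) for entry in fh]


def write_fastq(path, reads: Iterable[Read], quality_char: str = "I") -> None:
    """Constant-quality FASTQ; qualities are never used downstream."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def sam_header(reference_lengths: Mapping[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }


def open_sam_writer(path, reference_lengths: Mapping[str, int]) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), "w", header=sam_header(reference_lengths))
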