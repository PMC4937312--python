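"""Isoform-guided long-read alignment and splice classification."""
import itertools

import numpy as np
import pytest

from sirnascope.errors import ValidationError
from sirnascope.genemodels import spliced_sequence
from sirnascope.sequtils import random_seq, revcomp
from sirnascope.splicing import (
    IsoformAligner,
    LongReadAlignment,
    classify_splice,
    detect_antisense_introns,
    filter_long_reads,
    splice_rates,
    strand_coverage,
    write_long_sam,
)

from conftest import make_gene


def brute_force_best(read, gene, max_mm=1):
    """Exhaustive all-isoform, all-offset, both-strand aligner (independent
    of the production implementation's seeding and block arithmetic)."""
    introns = gene.introns
    candidates = {}
    for mask in itertools.product([0, 1], repeat=len(introns)):
        positions = []
        pos = gene.start
        for keep, (s, e) in zip(mask, introns):
            positions.extend(range(pos, s))
            if keep:
                positions.extend(range(s, e))
            pos = e
        positions.extend(range(pos, gene.end))
        iso = "".join(gene.sequence[p - gene.start] for p in positions)
        for needle, strand in ((read, "+"), (revcomp(read), "-")):
            L = len(needle)
            for off in range(len(iso) - L + 1):
                mm = sum(a != b for a, b in zip(needle, iso[off : off + L]))
                if mm > max_mm:
                    continue
                covered = positions[off : off + L]
                blocks, start = [], covered[0]
                for prev, cur in zip(covered, covered[1:]):
                    if cur != prev + 1:
                        blocks.append((start, prev + 1))
                        start = cur
                blocks.append((start, covered[-1] + 1))
                key = (strand, tuple(blocks))
                if key not in candidates or mm < candidates[key]:
                    candidates[key] = mm
    if not candidates:
        return None
    (strand, blocks), mm = min(
        candidates.items(),
        key=lambda kv: (kv[1], len(kv[0][1]) - 1, kv[0][1][0][0], kv[0][0] != "+"),
    )
    return strand, blocks, mm


class TestFilterLongReads:
    def test_strictly_longer_than_60(self):
        reads = [("a", "A" * 60), ("b", "A" * 61)]
        assert filter_long_reads(reads) == [("b", "A" * 61)]

    def test_empty_and_identity(self):
        assert filter_long_reads([]) == []
        reads = [(f"r{i}", "A" * 100) for i in range(3)]
        assert filter_long_reads(reads) == reads


class TestIsoformAligner:
    def test_spliced_read_gets_gaps_at_all_overlapped_introns(self, gene):
        sp = spliced_sequence(gene)
        read = sp.mrna[60 : 60 + 180]  # spans both junctions
        aln = IsoformAligner(gene).align("r", read)
        assert aln is not None and aln.mismatches == 0
        assert aln.gaps == gene.introns

    def test_single_substitution_keeps_blocks(self, gene):
        sp = spliced_sequence(gene)
        read = list(sp.mrna[60 : 60 + 180])
        read[90] = "C" if read[90] != "C" else "G"
        aln = IsoformAligner(gene).align("r", "".join(read))
        assert aln is not None and aln.mismatches == 1
        assert aln.gaps == gene.introns

    def test_antisense_read_aligns_on_reverse_strand(self, gene):
        read = revcomp(gene.sequence[30:150])  # nascent: introns retained
        aln = IsoformAligner(gene).align("r", read)
        assert aln is not None and aln.strand == "-"
        assert aln.blocks == ((30, 150),)

    def test_unalignable_read_returns_none(self, gene):
        rng = np.random.default_rng(9)
        assert IsoformAligner(gene).align("r", random_seq(rng, 80)) is None

    def test_too_many_introns_rejected(self):
        gene = make_gene(exon_lengths=(30,) * 10, intron_lengths=(20,) * 9)
        with pytest.raises(ValidationError):
            IsoformAligner(gene)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        gene = make_gene(rng, exon_lengths=(150, 120, 140), intron_lengths=(25, 28))
        aligner = IsoformAligner(gene)
        sp = spliced_sequence(gene)
        n_checked = 0
        for trial in range(120):
            kind = trial % 4
            if kind == 0:
                src = sp.mrna
            elif kind == 1:
                src = gene.sequence
            elif kind == 2:  # retain intron 1 only
                s, e = gene.introns[1]
                src = gene.sequence[: s - gene.start] + gene.sequence[e - gene.start :]
            else:
                src = random_seq(rng, 300)
            L = int(rng.integers(65, 120))
            p = int(rng.integers(0, len(src) - L))
            read = list(src[p : p + L])
            if rng.random() < 0.5:  # inject one substitution
                i = int(rng.integers(0, L))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            aln = aligner.align("r", read)
            oracle = brute_force_best(read, gene)
            if oracle is None:
                assert aln is None
            else:
                assert aln is not None
                assert (aln.strand, aln.blocks, aln.mismatches) == oracle
            n_checked += 1
        assert n_checked >= 100


class TestClassifySplice:
    def _aln(self, blocks):
        return LongReadAlignment("r", "ref", "+", tuple(blocks), 0)

    def test_gap_exactly_at_intron_is_spliced(self, gene):
        s, e = gene.introns[0]
        aln = self._aln([(s - 40, s), (e, e + 40)])
        assert classify_splice(aln, (s, e), gene) == "spliced"

    def test_five_bp_incursion_is_unspliced(self, gene):
        s, e = gene.introns[0]
        aln = self._aln([(s - 60, s + 5)])
        assert classify_splice(aln, (s, e), gene) == "unspliced"

    def test_four_bp_incursion_without_gap_is_not_candidate(self, gene):
        s, e = gene.introns[0]
        aln = self._aln([(s - 60, s + 4)])
        assert classify_splice(aln, (s, e), gene) == "not_candidate"

    def test_three_prime_incursion_also_counts(self, gene):
        s, e = gene.introns[0]
        aln = self._aln([(e - 5, e + 60)])
        assert classify_splice(aln, (s, e), gene) == "unspliced"

    def test_unknown_intron_rejected(self, gene):
        aln = self._aln([(0, 50)])
        with pytest.raises(ValidationError):
            classify_splice(aln, (1, 2), gene)

    def test_calls_partition_intron_overlapping_reads(self, gene):
        """Every alignment overlapping an intron gets exactly one of the
        three calls, and summary counts add up."""
        rng = np.random.default_rng(13)
        aligner = IsoformAligner(gene)
        sp = spliced_sequence(gene)
        alns = []
        for i in range(150):
            src = sp.mrna if rng.random() < 0.5 else gene.sequence
            L = 80
            p = int(rng.integers(0, len(src) - L))
            aln = aligner.align(f"r{i}", src[p : p + L])
            if aln:
                alns.append(aln)
        summary = splice_rates(alns, gene)
        for _, row in summary.table.iterrows():
            s, e = row["start"], row["end"]
            overlapping = sum(
                1 for a in alns if a.span[0] < e and s < a.span[1]
            )
            assert (
                row["n_spliced"] + row["n_unspliced"] + row["n_excluded_ambiguous"]
                == overlapping
            )


class TestSpliceRates:
    def test_nine_to_one_raw_rate(self, gene):
        s, e = gene.introns[0]
        spliced = [LongReadAlignment(f"s{i}", "ref", "+", ((s - 30, s), (e, e + 30)), 0)
                   for i in range(9)]
        unspliced = [LongReadAlignment("u", "ref", "+", ((s - 30, e + 30),), 0)]
        summary = splice_rates(spliced + unspliced, gene, footprint_correction=False)
        assert summary.table["splice_rate_raw"].iloc[0] == pytest.approx(0.9)

    def test_no_candidates_is_na(self, gene):
        summary = splice_rates([], gene)
        assert summary.table["splice_rate"].isna().all()


class TestAntisenseIntrons:
    def _gene_with_antisense_intron(self):
        from sirnascope.genemodels import GeneModel

        rng = np.random.default_rng(17)
        base = make_gene(rng, exon_lengths=(200, 180, 150), intron_lengths=(25, 25))
        seq = list(base.sequence)
        a_s, a_e = 60, 85  # inside exon 1; bottom strand reads GT...AG
        seq[a_s], seq[a_s + 1], seq[a_e - 2], seq[a_e - 1] = "C", "T", "A", "C"
        gene = GeneModel(base.gene_id, base.reference_id, "+", base.exons,
                         "".join(seq), base.start)
        return gene, (a_s, a_e)

    def test_planted_antisense_intron_is_reported(self):
        gene, (a_s, a_e) = self._gene_with_antisense_intron()
        g = gene.sequence
        transcript = revcomp(g[:a_s] + g[a_e:])  # antisense with the intron spliced
        junction = len(g) - a_e  # transcript position of the splice point
        reads = [
            (f"r{i}", transcript[junction - 60 + i * 4 : junction - 60 + i * 4 + 90])
            for i in range(10)
        ]
        hits = detect_antisense_introns(reads, gene)
        assert ((hits["start"] == a_s) & (hits["end"] == a_e) & (hits["strand"] == "-")).any()

    def test_sense_reads_only_yield_nothing(self):
        gene, _ = self._gene_with_antisense_intron()
        reads = [("r", gene.sequence[10:110])]
        assert detect_antisense_introns(reads, gene).empty

    def test_gap_equal_to_sense_intron_is_excluded(self):
        """An antisense read whose only gap coincides with an annotated sense
        intron is not a novel antisense intron."""
        gene, _ = self._gene_with_antisense_intron()
        s, e = gene.introns[0]
        s, e = s - gene.start, e - gene.start
        g = gene.sequence
        transcript = revcomp(g[:s] + g[e:])
        pos = len(g) - e - 45  # place the gap mid-read
        reads = [("r", transcript[pos : pos + 90])]
        hits = detect_antisense_introns(reads, gene)
        assert not ((hits["start"] == s) & (hits["end"] == e)).any() if len(hits) else True


class TestStrandCoverage:
    def test_single_ungapped_read(self):
        aln = LongReadAlignment("r", "ref", "+", ((10, 110),), 0)
        cov = strand_coverage([aln], 200)
        assert cov.top.sum() == 100 and (cov.top[10:110] == 1).all()
        assert cov.bottom.sum() == 0

    def test_duplicate_reads_stack(self):
        aln = LongReadAlignment("r", "ref", "-", ((10, 60),), 0)
        cov = strand_coverage([aln, aln], 100)
        assert (cov.bottom[10:60] == 2).all()

    def test_coverage_conserves_block_lengths(self, gene):
        alns = [
            LongReadAlignment("a", "ref", "+", ((5, 50), (80, 120)), 0),
            LongReadAlignment("b", "ref", "-", ((30, 90),), 0),
        ]
        cov = strand_coverage(alns, 300)
        assert cov.top.sum() + cov.bottom.sum() == sum(
            b - a for aln in alns for a, b in aln.blocks
        )

    def test_bedgraph_and_sam_export(self, gene, tmp_path):
        sp = spliced_sequence(gene)
        read = sp.mrna[60 : 60 + 150]
        aln = IsoformAligner(gene).align("r", read)
        write_long_sam(tmp_path / "long.sam", [aln], {"r": read}, {"ref": 400})
        sam_text = (tmp_path / "long.sam").read_text()
        assert "N" in sam_text.split("\n")[2].split("\t")[5]  # gapped CIGAR
        cov = strand_coverage([aln], 400)
        cov.to_bedgraph(tmp_path / "cov.bedgraph", "ref")
        lines = (tmp_path / "cov.bedgraph").read_text().strip().split("\n")
        assert all(len(l.split("\t")) == 4 for l in lines)
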