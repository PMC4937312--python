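"""Exact-match mapping, region counting and junction/intron classification."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from sirnascope.errors import ValidationError
from sirnascope.genemodels import Region, RegionSet, spliced_sequence
from sirnascope.sequtils import random_seq, revcomp
from sirnascope.smallrna import (
    ReferenceSet,
    antisense_ratio,
    classify_junction_intron,
    count_regions,
    exact_match,
    length_filter,
    length_histogram,
    modal_length,
    two_round_align,
    write_sam,
)

from conftest import make_gene


def naive_exact_match(read, refs):
    """Sliding-window oracle: all 0-mismatch hits on both strands."""
    read = read.upper()
    rc = revcomp(read)
    hits = set()
    for ref_id, seq in refs:
        for i in range(len(seq) - len(read) + 1):
            window = seq[i : i + len(read)]
            if window == read:
                hits.add((ref_id, i, "+"))
            if window == rc:
                hits.add((ref_id, i, "-"))
    return hits


class TestLengthFilter:
    def test_bounds_inclusive(self):
        reads = [(f"r{n}", "A" * n) for n in (16, 17, 23, 25, 26)]
        kept = length_filter(reads)
        assert sorted(len(s) for _, s in kept) == [17, 23, 25]

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_uniform_23mers_pass_unchanged(self):
        reads = [(f"r{i}", "ACGTA" * 4 + "CGT") for i in range(5)]
        assert length_filter(reads) == reads

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            length_filter([], min_len=25, max_len=17)


class TestExactMatch:
    def test_unique_forward_hit(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 2000)
        read = ref[500:523]
        refs = ReferenceSet({"r": ref})
        hits = exact_match(read, refs)
        if len(hits) == 1:  # random sequence may rarely repeat a 23-mer
            assert (hits[0].reference_id, hits[0].start, hits[0].strand) == ("r", 500, "+")

    def test_revcomp_hit_reported_on_reverse_strand(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 2000)
        read = revcomp(ref[800:823])
        hits = exact_match(read, ReferenceSet({"r": ref}))
        assert any(h.start == 800 and h.strand == "-" for h in hits)

    def test_ambiguous_bases_skip_with_warning(self):
        with pytest.warns(UserWarning):
            assert exact_match("ACGTN" * 4, ReferenceSet({"r": "ACGT" * 100})) == []

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, int(rng.integers(200, 3000)))
        refs = ReferenceSet({"a": ref, "b": random_seq(rng, 500)})
        n = int(rng.integers(17, 26))
        if rng.random() < 0.7:  # planted read
            pos = int(rng.integers(0, len(ref) - n))
            read = ref[pos : pos + n]
            if rng.random() < 0.5:
                read = revcomp(read)
        else:
            read = random_seq(rng, n)
        hits = exact_match(read, refs)
        assert {(h.reference_id, h.start, h.strand) for h in hits} == naive_exact_match(read, refs)
        for h in hits:
            assert h.multimap == len(hits)

    def test_short_reads_use_scan_path(self):
        ref = "AAACCCGGGTTTAAACCC"
        hits = exact_match("CCCGGG", ReferenceSet({"r": ref}))
        assert {(h.reference_id, h.start, h.strand) for h in hits} == naive_exact_match(
            "CCCGGG", ReferenceSet({"r": ref})
        ) == {("r", 3, "+"), ("r", 3, "-")}


class TestTwoRoundAlign:
    def test_contaminant_hit_excludes_from_round_two(self):
        seq = "ACGTACGTACGTACGTACGTACG"
        cont = ReferenceSet({"rRNA": "TT" + seq + "GG"})
        targets = ReferenceSet({"genome": "AA" + seq + "CC"})
        asg = two_round_align([("r1", seq)], cont, targets)
        assert asg.labels["r1"] == "contaminant"
        assert "r1" not in asg.alignments

    def test_unmatched_read_is_unmapped(self):
        asg = two_round_align(
            [("r1", "ACGTACGTACGTACGTA")],
            ReferenceSet({"c": "TTTT" * 30}),
            ReferenceSet({"t": "GGGG" * 30}),
        )
        assert asg.labels["r1"] == "unmapped"

    def test_empty_targets_rejected(self):
        with pytest.raises(ValidationError):
            two_round_align([], ReferenceSet({"c": "ACGT"}), ReferenceSet({}))


def _regions():
    return RegionSet((
        Region("left", "chr", 100, 200, "primary_capable", "+"),
        Region("right", "chr", 200, 300, "secondary_only", "+"),
    ))


class TestRegionCounting:
    def test_straddling_alignment_counts_in_both_regions(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 400)
        refs = ReferenceSet({"chr": ref})
        inside = ref[120:143]
        straddle = ref[190:213]
        asg = two_round_align([("in", inside), ("str", straddle)], ReferenceSet({}), refs)
        counts = count_regions(asg.flat_alignments(), _regions())
        by = counts.groupby("region")[["sense", "antisense"]].sum().sum(axis=1)
        assert by["left"] == 2  # inside + straddler
        assert by["right"] == 1  # straddler only

    def test_counts_conserved_over_disjoint_regions(self):
        rng = np.random.default_rng(3)
        ref = random_seq(rng, 400)
        refs = ReferenceSet({"chr": ref})
        reads = [(f"r{i}", ref[int(p) : int(p) + 20]) for i, p in
                 enumerate(rng.integers(100, 280, size=50))]
        asg = two_round_align(reads, ReferenceSet({}), refs)
        alns = [a for a in asg.flat_alignments() if 100 <= a.start and a.end <= 300]
        inner = [a for a in alns if not (a.start < 200 < a.end)]  # drop straddlers
        counts = count_regions(inner, _regions())
        assert counts[["sense", "antisense"]].sum().sum() == len(inner)

    def test_sense_resolved_against_coding_strand(self):
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 400)
        refs = ReferenceSet({"chr": ref})
        minus_regions = RegionSet((Region("g", "chr", 100, 300, "primary_capable", "-"),))
        asg = two_round_align([("fw", ref[150:173])], ReferenceSet({}), refs)
        counts = count_regions(asg.flat_alignments(), minus_regions)
        # a top-strand read is antisense to a minus-strand gene
        assert counts["antisense"].sum() >= 1 and counts["sense"].sum() == 0


class TestAntisenseRatio:
    @pytest.mark.parametrize(
        "sense,antisense,expected",
        [(0, 10, 1.0), (10, 10, 0.5), (10, 0, 0.0)],
    )
    def test_ratio_values(self, sense, antisense, expected):
        import pandas as pd

        counts = pd.DataFrame(
            [{"region": "x", "role": "primary_capable", "length": 23,
              "sense": sense, "antisense": antisense}]
        )
        assert antisense_ratio(counts)["antisense_ratio"].iloc[0] == expected

    def test_zero_denominator_is_na(self):
        import pandas as pd

        counts = pd.DataFrame(
            [{"region": "x", "role": "r", "length": 23, "sense": 0, "antisense": 0}]
        )
        assert np.isnan(antisense_ratio(counts)["antisense_ratio"].iloc[0])

    def test_invariant_under_uniform_count_scaling(self):
        import pandas as pd

        counts = pd.DataFrame(
            [{"region": "x", "role": "r", "length": 23, "sense": 7, "antisense": 13}]
        )
        r1 = antisense_ratio(counts)["antisense_ratio"].iloc[0]
        scaled = counts.assign(sense=counts.sense * 5, antisense=counts.antisense * 5)
        assert antisense_ratio(scaled)["antisense_ratio"].iloc[0] == pytest.approx(r1)


class TestLengthHistogram:
    def test_totals_conserved(self):
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 1000)
        refs = ReferenceSet({"chr": ref})
        reads = []
        for i in range(60):
            n = int(rng.integers(17, 26))
            p = int(rng.integers(0, len(ref) - n))
            reads.append((f"r{i}", ref[p : p + n]))
        asg = two_round_align(reads, ReferenceSet({}), refs)
        alns = asg.flat_alignments()
        hist = length_histogram(alns)
        assert hist[["sense", "antisense"]].sum().sum() == len(alns)

    def test_modal_length_of_planted_peak(self):
        import pandas as pd

        hist = pd.DataFrame(
            [{"region": "all", "length": L, "sense": 5, "antisense": 50 if L == 23 else 2}
             for L in range(17, 26)]
        )
        assert modal_length(hist, strand="antisense") == 23


class TestJunctionIntron:
    def test_constructed_junction_and_intron_reads(self):
        gene = make_gene(exon_lengths=(120, 80, 100), intron_lengths=(25, 30))
        sp = spliced_sequence(gene)
        j = sp.junctions[0]
        junction_read = sp.mrna[j - 12 : j + 11]  # 12|11 split across the boundary
        s, e = gene.introns[0]
        intron_read = gene.sequence[s + 1 : s + 24]  # wholly inside the intron
        table, per_read = classify_junction_intron(
            [("jr", junction_read), ("ir", revcomp(intron_read))], gene
        )
        assert per_read == {"jr": "junction", "ir": "intron"}
        assert table.set_index(["kind", "index"]).loc[("junction", 1), "sense"] == 1
        assert table.set_index(["kind", "index"]).loc[("intron", 1), "antisense"] == 1

    def test_classes_are_disjoint(self):
        gene = make_gene(exon_lengths=(120, 80, 100), intron_lengths=(25, 30))
        sp = spliced_sequence(gene)
        reads = []
        for j in sp.junctions:
            reads.append((f"j{j}", sp.mrna[j - 11 : j + 12]))
        for s, e in gene.introns:
            reads.append((f"i{s}", gene.sequence[s - 5 : s + 18]))
        _, per_read = classify_junction_intron(reads, gene)
        for rid, call in per_read.items():
            assert call == ("junction" if rid.startswith("j") else "intron")

    def test_exonic_read_matches_neither_class(self):
        gene = make_gene(exon_lengths=(120, 80, 100), intron_lengths=(25, 30))
        read = gene.sequence[10:33]  # deep inside exon 1
        table, per_read = classify_junction_intron([("e", read)], gene)
        assert per_read == {}

    def test_intronless_gene_yields_empty_table(self):
        gene = make_gene(exon_lengths=(200,), intron_lengths=())
        table, _ = classify_junction_intron([("r", gene.sequence[5:28])], gene)
        assert table.empty


def test_sam_round_trip(tmp_path):
    from sirnascope.pipeline import load_alignments

    rng = np.random.default_rng(6)
    ref = random_seq(rng, 500)
    refs = ReferenceSet({"chr": ref})
    reads = [("fw", ref[100:123]), ("rv", revcomp(ref[200:223]))]
    asg = two_round_align(reads, ReferenceSet({}), refs)
    path = tmp_path / "out.sam"
    write_sam(path, asg, dict(reads), refs)
    back = load_alignments(path)
    assert {(a.read_id, a.start, a.strand) for a in back} >= {("fw", 100, "+"), ("rv", 200, "-")}
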