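"""Stage orchestration: simulate -> map -> quantify -> normalize -> splice
-> chip -> report.

Each stage reads its inputs from, and writes its outputs to, a single run
directory in documented text formats (FASTA/FASTQ/GFF3/BED/SAM/TSV/JSON),
so any stage can be re-entered or fed externally produced data later. A run
is deterministic for a fixed config and seed.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .chipquant import aggregate_replicates, read_ct_table
from .errors import ValidationError
from .genemodels import RegionSet, gene_to_gff3, genes_from_gff3
from .io import read_fasta, read_fastq, write_fasta, write_fastq
from .normalization import (
    SampleLibrary,
    cohort_scaling,
    fold_change_table,
    normalize_counts,
)
from .smallrna import (
    ReferenceSet,
    alignments_frame,
    antisense_ratio,
    classify_junction_intron,
    count_regions,
    length_filter,
    length_histogram,
    SmallReadAlignment,
    two_round_align,
    write_sam,
)
from .splicing import (
    IsoformAligner,
    detect_antisense_introns,
    filter_long_reads,
    splice_rates,
    strand_coverage,
    write_long_sam,
)
from .synthetic_data import Cohort, SimConfig, simulate_cohort


def config_hash(config: SimConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate


def stage_simulate(config: SimConfig, outdir: Path) -> Cohort:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    refs = cohort.refs

    write_fasta(outdir / "references.fasta", refs.targets.seqs)
    write_fasta(outdir / "contaminants.fasta", refs.contaminants.seqs)
    gene_to_gff3([refs.gene], outdir / "gene_models.gff3")
    refs.region_set.to_bed(outdir / "regions.bed")
    config.to_yaml(outdir / "sim_config.yaml")
    refs.transgene_spec.to_yaml(outdir / "transgene_spec.yaml")
    meta = {
        "gene_id": refs.gene.gene_id,
        "scaffold_id": config.scaffold_id,
        "transgene_id": config.transgene_id,
        "mrna_id": refs.mrna_id,
        "genome_ref_ids": sorted(refs.genome_ref_ids),
        "structural_ref_ids": [refs.structural_id],
        "feeding_refs": refs.feeding_refs,
        "samples": [
            {"sample_id": s.sample_id, "role": s.role, "knockdown_gene": s.knockdown_gene}
            for s in config.samples
        ],
        "transgene_parent_intervals": [list(iv) for iv in refs.transgene.parent_intervals],
    }
    (outdir / "refs_meta.json").write_text(json.dumps(meta, indent=1))

    for sid, sample in cohort.samples.items():
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        write_fastq(sdir / "reads.fastq", sample.reads)
        sample.truth.to_csv(sdir / "truth.tsv", sep="\t", index=False)
    write_fastq(outdir / "long_reads.fastq", cohort.long_reads)
    cohort.long_truth.to_csv(outdir / "long_truth.tsv", sep="\t", index=False)
    cohort.ct_table.to_csv(outdir / "chip_ct_table.tsv", sep="\t", index=False)
    return cohort


def _load_meta(outdir: Path) -> dict:
    return json.loads((Path(outdir) / "refs_meta.json").read_text())


# ---------------------------------------------------------------------------
# map


def stage_map(outdir: Path) -> None:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    targets = ReferenceSet(read_fasta(outdir / "references.fasta"))
    contaminants = ReferenceSet(read_fasta(outdir / "contaminants.fasta"))
    for sample in meta["samples"]:
        sdir = outdir / sample["sample_id"]
        reads = length_filter(read_fastq(sdir / "reads.fastq"))
        asg = two_round_align(reads, contaminants, targets)
        write_sam(sdir / "alignments.sam", asg, dict(reads), targets)
        with open(sdir / "assignments.tsv", "w") as fh:
            fh.write("read_id\tlabel\trefs\n")
            for rid, _ in reads:
                refs_hit = sorted({a.reference_id for a in asg.alignments.get(rid, [])})
                fh.write(f"{rid}\t{asg.labels[rid]}\t{';'.join(refs_hit)}\n")


def load_alignments(sam_path: Path) -> list[SmallReadAlignment]:
    out = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            out.append(
                SmallReadAlignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.query_length,
                    "-" if rec.is_reverse else "+",
                    rec.get_tag("NH") if rec.has_tag("NH") else 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# quantify


def primary_secondary_coverage(
    aln_df: pd.DataFrame,
    region_set: RegionSet,
    parent_intervals: Iterable[tuple[int, int]],
    scaffold_id: str,
    length: int = 23,
    strand: str = "antisense",
    coding_strand: str = "+",
) -> pd.DataFrame:
    """Mean per-base coverage of `length`-mers by region class.

    The transgene-covered row averages over the parent intervals actually
    present in the construct (not the overlapping named sub-regions), which
    is the denominator used for secondary/primary abundance ratios.
    """
    want_strand = (
        coding_strand if strand == "sense" else ("-" if coding_strand == "+" else "+")
    )
    sub = aln_df[
        (aln_df["reference_id"] == scaffold_id)
        & (aln_df["length"] == length)
        & (aln_df["strand"] == want_strand)
    ]

    def mean_cov(intervals) -> float:
        total_bases = 0
        total_len = 0
        for a, b in intervals:
            total_len += b - a
            if len(sub):
                ov = np.minimum(sub["end"], b) - np.maximum(sub["start"], a)
                total_bases += int(ov[ov > 0].sum())
        return total_bases / total_len if total_len else float("nan")

    rows = [
        {
            "region": "transgene_covered",
            "role": "primary_capable",
            "mean_coverage": mean_cov(list(parent_intervals)),
        }
    ]
    for r in region_set.by_role("secondary_only"):
        rows.append(
            {"region": r.name, "role": r.role, "mean_coverage": mean_cov([(r.start, r.end)])}
        )
    return pd.DataFrame(rows)


def stage_quantify(outdir: Path) -> None:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    region_set = RegionSet.from_bed(outdir / "regions.bed")
    seqs = read_fasta(outdir / "references.fasta")
    gene = genes_from_gff3(outdir / "gene_models.gff3", seqs)[0]

    counts_all, ratios_all, hist_all, ji_all, cov_all = [], [], [], [], []
    for sample in meta["samples"]:
        sid = sample["sample_id"]
        sdir = outdir / sid
        alns = load_alignments(sdir / "alignments.sam")
        df = alignments_frame(alns)
        counts = count_regions(df, region_set)
        counts.insert(0, "sample_id", sid)
        counts_all.append(counts)
        ratios = antisense_ratio(counts.drop(columns="sample_id"))
        ratios.insert(0, "sample_id", sid)
        ratios_all.append(ratios)
        hist = length_histogram(df, region_set)
        hist.insert(0, "sample_id", sid)
        hist_all.append(hist)
        reads = length_filter(read_fastq(sdir / "reads.fastq"))
        ji, _ = classify_junction_intron(reads, gene)
        ji.insert(0, "sample_id", sid)
        ji_all.append(ji)
        cov = primary_secondary_coverage(
            df, region_set,
            [tuple(iv) for iv in meta["transgene_parent_intervals"]],
            meta["scaffold_id"], coding_strand=gene.coding_strand,
        )
        cov.insert(0, "sample_id", sid)
        cov_all.append(cov)

    pd.concat(counts_all).to_csv(outdir / "region_counts_raw.tsv", sep="\t", index=False)
    pd.concat(ratios_all).to_csv(outdir / "antisense_ratios.tsv", sep="\t", index=False)
    pd.concat(hist_all).to_csv(outdir / "length_histograms.tsv", sep="\t", index=False)
    pd.concat(ji_all).to_csv(outdir / "junction_intron.tsv", sep="\t", index=False)
    pd.concat(cov_all).to_csv(outdir / "coverage_by_region.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalize


def libraries_from_run(
    outdir: Path,
    exclude_refs: Iterable[str] = (),
) -> list[SampleLibrary]:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    genome = set(meta["genome_ref_ids"])
    counts = pd.read_csv(outdir / "region_counts_raw.tsv", sep="\t")
    libs = []
    for sample in meta["samples"]:
        sid = sample["sample_id"]
        kd_ref = meta["feeding_refs"][sample["knockdown_gene"]]
        asg = pd.read_csv(outdir / sid / "assignments.tsv", sep="\t", keep_default_na=False)
        mapped = asg[asg["label"] == "mapped"]
        ref_sets = mapped["refs"].str.split(";")
        in_genome = ref_sets.apply(lambda rs: any(r in genome for r in rs))
        excluded = ref_sets.apply(lambda rs: any(r in set(exclude_refs) for r in rs))
        genome_reads = mapped[in_genome & ~excluded]
        T = len(genome_reads)
        K = int(genome_reads["refs"].str.split(";").apply(lambda rs: kd_ref in rs).sum())
        libs.append(
            SampleLibrary(sid, T, K, counts[counts["sample_id"] == sid].drop(columns="sample_id"))
        )
    return libs


def stage_normalize(
    outdir: Path,
    control_sample: Optional[str] = None,
    exclude_refs: Iterable[str] = (),
) -> dict:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    if control_sample is None:
        control_sample = next(s["sample_id"] for s in meta["samples"] if s["role"] == "control")
    libs = libraries_from_run(outdir, exclude_refs)
    scaling = cohort_scaling(libs)
    by_id = {lib.sample_id: lib for lib in libs}
    if control_sample not in by_id:
        raise ValidationError(f"control sample {control_sample!r} not in run")

    normed = []
    for lib in libs:
        df = normalize_counts(lib, scaling)
        df.insert(0, "sample_id", lib.sample_id)
        normed.append(df)
    pd.concat(normed).to_csv(outdir / "region_counts.tsv", sep="\t", index=False)

    fc_all = []
    for lib in libs:
        if lib.sample_id == control_sample:
            continue
        fc = fold_change_table(lib, by_id[control_sample], scaling)
        fc.insert(0, "sample_id", lib.sample_id)
        fc.insert(1, "control_id", control_sample)
        fc_all.append(fc)
    if fc_all:
        pd.concat(fc_all).to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["sample_id", "control_id", "region", "role", "length", "strand",
                     "knockdown_raw", "control_raw", "fold_change", "log2_fold_change"]
        ).to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)

    report = {
        "M": scaling.M,
        "samples": {
            lib.sample_id: {
                "T": lib.T,
                "K": lib.K,
                "effective_size": lib.effective_size,
                "factor": scaling.factor(lib.sample_id),
            }
            for lib in libs
        },
        "control_sample": control_sample,
    }
    (outdir / "normalization.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# splice


def stage_splice(outdir: Path) -> None:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    seqs = read_fasta(outdir / "references.fasta")
    gene = genes_from_gff3(outdir / "gene_models.gff3", seqs)[0]
    reads = filter_long_reads(read_fastq(outdir / "long_reads.fastq"))
    aligner = IsoformAligner(gene)
    alignments, unaligned = [], []
    for rid, seq in reads:
        aln = aligner.align(rid, seq)
        if aln is None:
            unaligned.append((rid, seq))
        else:
            alignments.append(aln)

    # sense-transcript splice rates; antisense (nascent) reads are analysed
    # separately via the antisense-intron scan
    summary = splice_rates(alignments, gene, strands=(gene.coding_strand,))
    table = summary.table.copy()
    table.loc[len(table)] = {
        "intron": "mean", "start": "", "end": "",
        "n_spliced": table["n_spliced"].sum(), "n_unspliced": table["n_unspliced"].sum(),
        "n_excluded_ambiguous": table["n_excluded_ambiguous"].sum(),
        "splice_rate": summary.mean_rate,
    }
    table.to_csv(outdir / "splice_rates.tsv", sep="\t", index=False)

    detect_antisense_introns(unaligned, gene).to_csv(
        outdir / "antisense_introns.tsv", sep="\t", index=False
    )
    cov = strand_coverage(alignments, len(seqs[meta["scaffold_id"]]))
    cov.to_bedgraph(outdir / "strand_coverage.bedgraph", meta["scaffold_id"])
    write_long_sam(
        outdir / "long_alignments.sam", alignments, dict(reads),
        {meta["scaffold_id"]: len(seqs[meta["scaffold_id"]])},
    )


# ---------------------------------------------------------------------------
# chip, report


def stage_chip(outdir: Path) -> pd.DataFrame:
    outdir = Path(outdir)
    report = aggregate_replicates(read_ct_table(outdir / "chip_ct_table.tsv"))
    report.to_csv(outdir / "chip_report.tsv", sep="\t", index=False)
    return report


ARTIFACTS = [
    "region_counts_raw.tsv",
    "region_counts.tsv",
    "fold_changes.tsv",
    "antisense_ratios.tsv",
    "length_histograms.tsv",
    "junction_intron.tsv",
    "splice_rates.tsv",
    "strand_coverage.bedgraph",
    "chip_report.tsv",
]


def stage_report(config: SimConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    norm = json.loads((outdir / "normalization.json").read_text())
    missing = [a for a in ARTIFACTS if not (outdir / a).exists()]
    if missing:
        raise ValidationError(f"missing artifacts: {missing}")
    sam_files = sorted(str(p.relative_to(outdir)) for p in outdir.glob("*/alignments.sam"))
    manifest = {
        "software": "sirnascope",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "normalization": norm,
        "artifacts": ARTIFACTS + sam_files + ["long_alignments.sam"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_pipeline(config: SimConfig, outdir: Path, seed: Optional[int] = None) -> dict:
    """End-to-end run; returns the manifest."""
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_map(outdir)
    stage_quantify(outdir)
    stage_normalize(outdir)
    stage_splice(outdir)
    stage_chip(outdir)
    return stage_report(config, outdir)
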