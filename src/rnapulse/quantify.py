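"""Read quantification: BAM alignments + GTF annotation -> per-gene
exonic/intronic expression tables.

Pre-mRNA signal is measured by reads on the intron complement of a gene,
total/mature signal by reads on the merged exon union; the labeled (4sU)
libraries contribute their exonic signal.  Coordinates follow the GTF
convention (1-based closed) at the I/O edges and half-open 0-based
internally.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .containers import TimeCourseExpression
from .kinetics import TimeGrid

__all__ = [
    "GeneAnnotation",
    "ExpressionTable",
    "load_annotation",
    "count_reads",
    "to_expression_units",
    "build_timecourse",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """Merged exon/intron structure of one gene.

    Intervals are half-open 0-based; exons are the union over all
    transcripts, introns the gaps of that union within the gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    introns: tuple

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intronic_length(self) -> int:
        return sum(e - s for s, e in self.introns)


@dataclass
class ExpressionTable:
    """Genes x samples expression matrix in one unit for one feature class."""

    matrix: pd.DataFrame
    unit: str
    library_sizes: pd.Series
    feature_class: str

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValueError("expression values must be nonnegative")


def _merge_intervals(ivs: list) -> list:
    ivs = sorted(ivs)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )


def load_annotation(gtf_path) -> dict[str, GeneAnnotation]:
    """Parse a GTF file into per-gene merged exon unions and introns.

    Introns are the complement of the exon union within the gene span
    (the gene feature's span when present, otherwise the exon span).
    Exon records without a gene_id are skipped with a warning.
    """
    import gffutils

    gtf_path = str(gtf_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    spans: dict[str, tuple] = {}
    n_skipped = 0
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            n_skipped += 1
            continue
        exons.setdefault(gid, []).append((feat.start - 1, feat.end))
        meta.setdefault(gid, (feat.seqid, feat.strand))
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is not None:
            spans[gid] = (feat.start - 1, feat.end)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} exon records without gene_id")

    genes = {}
    for gid, ivs in exons.items():
        merged = _merge_intervals(ivs)
        lo, hi = spans.get(gid, (merged[0][0], merged[-1][1]))
        introns = []
        prev = lo
        for s, e in merged:
            if s > prev:
                introns.append((prev, s))
            prev = max(prev, e)
        if hi > prev:
            introns.append((prev, hi))
        chrom, strand = meta[gid]
        genes[gid] = GeneAnnotation(
            gene_id=gid, chrom=chrom, strand=strand,
            exons=tuple(merged), introns=tuple(introns),
        )
    return genes


class CountResult(NamedTuple):
    exon: pd.Series
    intron: pd.Series
    library_size: int


def _build_trees(annotation: dict[str, GeneAnnotation]):
    ex, intr = {}, {}
    for g in annotation.values():
        for s, e in g.exons:
            ex.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
        for s, e in g.introns:
            intr.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
    return ex, intr


def count_reads(bam_path, annotation: dict[str, GeneAnnotation],
                mode: str = "unique-gene", junction: str = "exon",
                stranded: str | None = None,
                count_units: str = "reads") -> CountResult:
    """Assign reads to the exon/intron classes of genes.

    A read whose aligned blocks touch only the exon union of a single gene
    increments that gene's exon count; introns only, the intron count; a
    junction-ambiguous read (both classes) counts as exonic by default
    (it demonstrates spliced product) or is discarded with
    ``junction="discard"``.  Reads touching several genes are discarded
    under ``mode="unique-gene"``.  Secondary, supplementary, unmapped and
    duplicate-flagged reads are skipped.  ``count_units="fragments"``
    counts read pairs once (skips mate 2).  The returned library size is
    the number of reads passing the basic filters.
    """
    bam_path = str(bam_path)
    if junction not in ("exon", "discard"):
        raise ValueError("junction must be 'exon' or 'discard'")
    if mode not in ("unique-gene", "all"):
        raise ValueError("mode must be 'unique-gene' or 'all'")
    if stranded not in (None, "forward", "reverse"):
        raise ValueError("stranded must be None, 'forward' or 'reverse'")
    af = pysam.AlignmentFile(bam_path, "rb")
    try:
        if not af.has_index():
            raise ValueError(f"{bam_path} has no index; run samtools index first")
        ann_chroms = {g.chrom for g in annotation.values()}
        missing = sorted(ann_chroms - set(af.references))
        if missing:
            warnings.warn(
                f"annotation contigs absent from {os.path.basename(bam_path)}: "
                + ", ".join(missing)
            )
        ex_tree, in_tree = _build_trees(annotation)
        strand_of = {g.gene_id: g.strand for g in annotation.values()}
        genes = sorted(annotation)
        exon_c = dict.fromkeys(genes, 0)
        intron_c = dict.fromkeys(genes, 0)
        libsize = 0
        for read in af.fetch():
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate):
                continue
            libsize += 1
            if count_units == "fragments" and read.is_paired and read.is_read2:
                continue
            chrom = read.reference_name
            et = ex_tree.get(chrom)
            it = in_tree.get(chrom)
            if et is None and it is None:
                continue
            hits_ex, hits_in = set(), set()
            for s, e in read.get_blocks():
                if et is not None:
                    hits_ex |= {iv.data for iv in et.overlap(s, e)}
                if it is not None:
                    hits_in |= {iv.data for iv in it.overlap(s, e)}
            cand = hits_ex | hits_in
            if stranded is not None:
                rs = "-" if read.is_reverse else "+"
                want = rs if stranded == "forward" else ("-" if rs == "+" else "+")
                cand = {g for g in cand if strand_of[g] == want}
                hits_ex &= cand
                hits_in &= cand
            if not cand or (mode == "unique-gene" and len(cand) > 1):
                continue
            for g in cand:
                if g in hits_ex and g in hits_in:
                    if junction == "exon":
                        exon_c[g] += 1
                elif g in hits_ex:
                    exon_c[g] += 1
                else:
                    intron_c[g] += 1
    finally:
        af.close()
    return CountResult(
        exon=pd.Series(exon_c, name="exon").loc[genes],
        intron=pd.Series(intron_c, name="intron").loc[genes],
        library_size=libsize,
    )


def to_expression_units(counts: pd.DataFrame, lengths: pd.Series,
                        library_sizes: pd.Series, unit: str,
                        feature_class: str = "exon") -> ExpressionTable:
    """Convert raw counts to counts/RPKM/TPM/FPKM.

    RPKM_i = count_i / ((length_i/1e3) * (libsize/1e6)); TPM scales the
    per-kilobase read rates to sum to 1e6 per sample; FPKM applies the
    RPKM formula to fragment counts.  Zero-length features are excluded
    with a warning.
    """
    if unit not in ("counts", "RPKM", "TPM", "FPKM"):
        raise ValueError(f"unknown unit {unit!r}")
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    zero_len = lengths <= 0
    if zero_len.any():
        warnings.warn(
            f"excluding {int(zero_len.sum())} zero-length features from "
            f"{feature_class} table"
        )
        counts = counts.loc[~zero_len]
        lengths = lengths.loc[~zero_len]
    if unit == "counts":
        mat = counts
    elif unit in ("RPKM", "FPKM"):
        mat = counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)
    else:  # TPM
        rate = counts.div(lengths, axis=0)
        tot = rate.sum(axis=0)
        tot[tot == 0] = 1.0
        mat = rate.div(tot, axis=1) * 1e6
    return ExpressionTable(matrix=mat, unit=unit, library_sizes=library_sizes,
                           feature_class=feature_class)


def build_timecourse(total_bams, labeled_bams, times, tL: float,
                     annotation: dict[str, GeneAnnotation],
                     unit: str = "RPKM", **count_kwargs) -> TimeCourseExpression:
    """Quantify the time course: P = intron signal of the total
    libraries, T = exon signal of the total libraries, TL = exon signal
    of the labeled libraries.

    Genes without introns cannot supply a pre-mRNA signal; their P rows
    are NaN and they are flagged un-fittable.
    """
    total_bams = list(total_bams)
    labeled_bams = list(labeled_bams)
    times = np.asarray(times, dtype=float)
    if not (len(total_bams) == len(labeled_bams) == times.size):
        raise ValueError("total_bams, labeled_bams and times must have equal length")
    grid = TimeGrid(times=times, tL=tL)  # validates ordering
    genes = sorted(annotation)
    exon_len = pd.Series({g: annotation[g].exonic_length for g in genes})
    intron_len = pd.Series({g: annotation[g].intronic_length for g in genes})

    frag = "fragments" if unit == "FPKM" else "reads"
    cols = list(times)

    def quantify_set(bams, feature):
        cnt = pd.DataFrame(index=genes, columns=cols, dtype=float)
        libs = pd.Series(index=cols, dtype=float)
        for t, bam in zip(cols, bams):
            res = count_reads(bam, annotation, count_units=frag, **count_kwargs)
            cnt[t] = res.exon if feature == "exon" else res.intron
            libs[t] = res.library_size
        lengths = exon_len if feature == "exon" else intron_len
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = to_expression_units(cnt, lengths, libs, unit, feature_class=feature)
        return tab.matrix.reindex(genes), libs

    T, lib_tot = quantify_set(total_bams, "exon")
    P, _ = quantify_set(total_bams, "intron")
    TL, lib_lab = quantify_set(labeled_bams, "exon")

    flags = {}
    no_intron = intron_len[intron_len == 0].index
    for g in no_intron:
        flags[g] = ["unfittable_no_introns"]
        P.loc[g] = np.nan
    if len(no_intron):
        warnings.warn(
            f"{len(no_intron)} genes without introns flagged un-fittable"
        )
    expr = TimeCourseExpression(P=P, T=T, TL=TL, grid=grid, unit=unit,
                                gene_flags=flags)
    expr.library_sizes = {"total": lib_tot, "labeled": lib_lab}
    return expr
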