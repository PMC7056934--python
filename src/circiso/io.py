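"""Readers and writers for all external formats.

Inputs: GTF gene annotation, SAM paired-end spliced alignments, and
back-splice-junction tables in three upstream dialects (CIRCexplorer2,
CIRI2, UROBORUS).  Outputs: a GTF of assembled circular transcripts and
a TSV expression table.

Everything internal is 0-based half-open; the conversion happens here
and only here.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict

import pysam

from .core import (
    BackSpliceJunction,
    ExpressionRecord,
    FragmentAlignment,
    GeneAnnotation,
    GeneLocus,
    Interval,
    chain_to_str,
)

log = logging.getLogger(__name__)

BSJ_DIALECTS = ("circexplorer2", "ciri2", "uroborus")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    pass


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gene_annotation(path) -> GeneAnnotation:
    """Parse exon features of a GTF file into per-gene loci.

    Exon intervals are deduplicated within each locus; annotated
    transcripts are kept as exon-index chains sorted by genomic
    coordinate.  Records with end < start are dropped with a log entry.
    """
    exons_by_gene: dict[str, set[Interval]] = defaultdict(set)
    tx_by_gene: dict[str, dict[str, list[Interval]]] = defaultdict(lambda: defaultdict(list))
    meta: dict[str, tuple[str, str]] = {}
    n_bad = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GTFParseError(f"{path}: malformed GTF line {lineno}: bad coordinates") from exc
            if end_i < start_i:
                n_bad += 1
                log.warning("%s line %d: exon with end < start rejected", path, lineno)
                continue
            a = _parse_gtf_attributes(attrs)
            gid, tid = a.get("gene_id"), a.get("transcript_id")
            if gid is None or tid is None:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: missing gene_id/transcript_id"
                )
            iv = (start_i - 1, end_i)  # GTF is 1-based inclusive
            exons_by_gene[gid].add(iv)
            tx_by_gene[gid][tid].append(iv)
            meta[gid] = (chrom, strand)

    genes = []
    for gid in sorted(exons_by_gene):
        chrom, strand = meta[gid]
        exons = sorted(exons_by_gene[gid])
        index = {iv: i for i, iv in enumerate(exons)}
        transcripts = {
            tid: [index[iv] for iv in sorted(ivs)]
            for tid, ivs in sorted(tx_by_gene[gid].items())
        }
        genes.append(GeneLocus(gid, chrom, strand, exons, transcripts))
    if n_bad:
        log.warning("%s: rejected %d exon records with end < start", path, n_bad)
    return GeneAnnotation(genes)


def _cigar_blocks(pos: int, cigartuples) -> list[Interval]:
    """Split an alignment into genomic blocks at every N (intron) gap.

    M/=/X and D advance the reference and extend the current block; N
    closes it; I/S/H/P consume no reference.
    """
    blocks: list[Interval] = []
    cur = pos
    start = pos
    open_block = False
    for op, ln in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D
            if not open_block:
                start = cur
                open_block = True
            cur += ln
        elif op == 3:  # N
            if open_block:
                blocks.append((start, cur))
                open_block = False
            cur += ln
        elif op in (1, 4, 5, 6):  # I, S, H, P
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if open_block:
        blocks.append((start, cur))
    return blocks


def read_alignments(path) -> list[FragmentAlignment]:
    """Read a SAM file into paired fragments.

    Mates are paired by query name.  Each record's CIGAR is split into
    genomic blocks at N gaps; a mate represented by several primary
    records with the same name (a read split at a back-splice junction)
    keeps one chain per record.  Unmapped and secondary/supplementary
    records are skipped.
    """
    frags: dict[str, FragmentAlignment] = {}
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                chain = _cigar_blocks(rec.reference_start, rec.cigartuples or [])
            except ValueError:
                n_skipped += 1
                log.warning("record %s skipped: unsupported CIGAR", rec.query_name)
                continue
            if not chain:
                continue
            f = frags.get(rec.query_name)
            if f is None:
                f = FragmentAlignment(rec.query_name, chromosome=rec.reference_name)
                frags[rec.query_name] = f
            target = f.mate2_chains if rec.is_read2 else f.mate1_chains
            target.append(chain)

    out = []
    n_single = 0
    for f in frags.values():
        if len(f.mate1_chains) > 1 or len(f.mate2_chains) > 1:
            f.is_bsj_spanning = True
        if not f.mate1_chains or not f.mate2_chains:
            n_single += 1
        out.append(f)
    if n_single:
        log.warning("%d fragments had an unpaired mate", n_single)
    if n_skipped:
        log.warning("%d records skipped for unsupported CIGAR operations", n_skipped)
    return out


def _parse_bsj_row(fields: list[str], dialect: str) -> BackSpliceJunction | None:
    if dialect == "circexplorer2":
        # BED-style: chrom, start (0-based), end, name, score, strand, ...,
        # column 13 = supporting back-spliced read count when present.
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
        support = int(float(fields[12])) if len(fields) > 12 else (
            int(float(fields[4])) if len(fields) > 4 else 0)
    elif dialect == "ciri2":
        # circRNA_ID, chr, start (1-based), end, #junction_reads, SM, ...,
        # strand in column 11.
        chrom = fields[1]
        start, end = int(fields[2]) - 1, int(fields[3])
        support = int(float(fields[4])) if len(fields) > 4 else 0
        strand = fields[10] if len(fields) > 10 and fields[10] in "+-" else "."
    elif dialect == "uroborus":
        # chrom, start (1-based), end, strand, gene, read count.
        chrom = fields[0]
        start, end = int(fields[1]) - 1, int(fields[2])
        strand = fields[3] if len(fields) > 3 and fields[3] in "+-" else "."
        support = int(float(fields[5])) if len(fields) > 5 else 0
    else:
        raise ValueError(
            f"unknown BSJ dialect {dialect!r}; supported: {', '.join(BSJ_DIALECTS)}"
        )
    if start >= end:
        log.warning("rejected BSJ row with start >= end: %s:%s-%s", chrom, start, end)
        return None
    return BackSpliceJunction(chrom, start, end, strand, support)


def read_bsj_list(path, dialect: str) -> list[BackSpliceJunction]:
    """Read a back-splice-junction table in one upstream tool's dialect,
    normalizing all coordinates to 0-based half-open."""
    if dialect not in BSJ_DIALECTS:
        raise ValueError(
            f"unknown BSJ dialect {dialect!r}; supported: {', '.join(BSJ_DIALECTS)}"
        )
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("circrna_id"):
                continue
            bsj = _parse_bsj_row(line.split("\t"), dialect)
            if bsj is not None:
                out.append(bsj)
    return out


def filter_bsj_by_support(
    bsjs: list[BackSpliceJunction], min_support: int
) -> list[BackSpliceJunction]:
    """Keep junctions with at least ``min_support`` back-spliced reads
    (inclusive threshold)."""
    if min_support < 0:
        raise ValueError("min_support must be >= 0")
    return [b for b in bsjs if b.support >= min_support]


def write_outputs(records: list[ExpressionRecord], out_prefix) -> tuple[str, str]:
    """Write the assembled transcripts as GTF and the expression table
    as TSV; returns the two paths."""
    gtf_path = f"{out_prefix}.gtf"
    tsv_path = f"{out_prefix}.expression.tsv"

    with open(gtf_path, "w") as fh:
        for r in records:
            for s, e in sorted(r.exon_chain):
                attrs = (
                    f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                    f'bsj_start "{r.bsj.start}"; bsj_end "{r.bsj.end}";'
                )
                fh.write(
                    f"{r.bsj.chromosome}\tcirciso\texon\t{s + 1}\t{e}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )

    header = [
        "transcript_id", "chrom", "bsj_start", "bsj_end", "strand",
        "exon_chain", "length", "read_count", "FPKM", "TPM", "RI",
    ]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.transcript_id, r.bsj.chromosome, r.bsj.start, r.bsj.end,
                        r.strand, chain_to_str(r.exon_chain), r.length,
                        f"{r.read_count:.2f}", f"{r.fpkm:.4f}", f"{r.tpm:.4f}",
                        r.relation_index,
                    )
                )
                + "\n"
            )
    return gtf_path, tsv_path


def read_transcript_gtf(path) -> dict[str, list[Interval]]:
    """Re-read a transcript GTF written by :func:`write_outputs`;
    returns transcript_id -> genomic-sorted exon chain."""
    return {tid: chain for tid, (_, _, chain) in read_transcript_gtf_full(path).items()}


def read_transcript_gtf_full(
    path,
) -> dict[str, tuple[str, BackSpliceJunction, list[Interval]]]:
    """Like :func:`read_transcript_gtf` but keeps chromosome and the
    back-splice junction recorded in the attributes."""
    chains: dict[str, list[Interval]] = defaultdict(list)
    meta: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[2] != "exon":
                continue
            a = _parse_gtf_attributes(fields[8])
            tid = a["transcript_id"]
            chains[tid].append((int(fields[3]) - 1, int(fields[4])))
            meta[tid] = (fields[0], int(a["bsj_start"]), int(a["bsj_end"]), fields[6])
    out = {}
    for tid, ivs in chains.items():
        chrom, bs, be, strand = meta[tid]
        out[tid] = (chrom, BackSpliceJunction(chrom, bs, be, strand), sorted(ivs))
    return out
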