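"""Synthetic circular-transcriptome generator with known ground truth.

Emulates a back-splice-anchored simulation: gene loci with an exon
ladder are laid out on one chromosome; each locus carries one or more
back-splice events (overlapping events share a central anchor exon so
their spans overlap); exons between the back-splice sites are randomly
selected as skipped exons to generate multiple isoforms; each isoform is
assigned a random log-uniform expression level.  Paired-end fragments
are sampled uniformly around each circle (any rotation, including across
the junction) with normally distributed lengths, and emitted pre-aligned
as SAM with correct N-gap CIGARs — reads straddling the junction are
split into two records sharing the query name and mate flag.

The generator emits coordinates (and optional synthetic sequence for
FASTQ); no reference genome is involved.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BackSpliceJunction, CircularTranscript, GeneAnnotation, GeneLocus, Interval, chain_to_str
from .quant import TranscriptLayout


@dataclass
class SimConfig:
    n_loci: int = 20
    exons_per_locus: tuple[int, int] = (5, 10)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (200, 1500)
    n_bsjs_per_locus: tuple[int, int] = (2, 3)
    circle_exons: tuple[int, int] = (2, 6)
    isoforms_per_bsj: tuple[int, int] = (1, 2)
    read_length: int = 100
    n_read_pairs: int = 50_000
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    overlap_fraction: float = 0.3
    expression_range: tuple[float, float] = (1.0, 1000.0)
    locus_spacing: int = 10_000
    chromosome: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        for name in ("n_loci", "read_length", "locus_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")


@dataclass
class TruthTranscript:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    bsj: BackSpliceJunction
    exon_chain: list[Interval]  # genomic-sorted
    expression: float
    theta: float = 0.0
    fragment_count: int = 0

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exon_chain)

    @property
    def chain_key(self) -> tuple:
        return (self.bsj.chromosome, self.bsj.start, self.bsj.end,
                tuple(sorted(self.exon_chain)))

    def as_circular_transcript(self) -> CircularTranscript:
        chain = sorted(self.exon_chain, reverse=self.strand == "-")
        return CircularTranscript(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            bsj=self.bsj,
            exon_chain=chain,
            strand=self.strand,
        )


@dataclass
class SimTruth:
    config: SimConfig
    annotation: GeneAnnotation
    transcripts: list[TruthTranscript]
    bsjs: list[BackSpliceJunction] = field(default_factory=list)
    chrom_length: int = 0

    def by_locus(self) -> dict[str, list[TruthTranscript]]:
        out: dict[str, list[TruthTranscript]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out


def _distinct_subsets(rng, internal: list[int], n: int) -> list[frozenset[int]]:
    """The full chain plus up to n-1 distinct random skip sets."""
    chosen = [frozenset()]
    n_max = 2 ** len(internal)
    tries = 0
    while len(chosen) < min(n, n_max) and tries < 200:
        tries += 1
        size = int(rng.integers(1, max(len(internal), 1) + 1))
        skip = frozenset(rng.choice(internal, size=size, replace=False).tolist())
        if skip not in chosen:
            chosen.append(skip)
    return chosen


def _assign_expression(rng, transcripts: list[TruthTranscript], lo: float, hi: float) -> None:
    levels = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(transcripts)))
    for t, lv in zip(transcripts, levels):
        t.expression = float(lv)
    by_gene: dict[str, float] = {}
    for t in transcripts:
        by_gene[t.gene_id] = by_gene.get(t.gene_id, 0.0) + t.expression
    for t in transcripts:
        t.theta = t.expression / by_gene[t.gene_id]


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Generate annotation, back-splice junctions and truth isoforms.

    Deterministic given ``cfg.seed``.  With probability
    ``overlap_fraction`` a locus receives several back-splice events that
    all span a shared anchor exon, so their genomic spans overlap."""
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneLocus] = []
    transcripts: list[TruthTranscript] = []
    bsjs: list[BackSpliceJunction] = []
    cursor = 1000

    for li in range(cfg.n_loci):
        gid = f"G{li + 1:04d}"
        strand = "+" if li % 2 == 0 else "-"
        n_ex = int(rng.integers(cfg.exons_per_locus[0], cfg.exons_per_locus[1] + 1))
        n_ex = max(n_ex, 3)
        exons: list[Interval] = []
        pos = cursor
        for _ in range(n_ex):
            ln = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        cursor = pos + cfg.locus_spacing

        locus = GeneLocus(
            gid, cfg.chromosome, strand, exons,
            {f"{gid}.L1": list(range(n_ex))},
        )
        genes.append(locus)

        if rng.random() < cfg.overlap_fraction and n_ex >= 4:
            lo = max(2, cfg.n_bsjs_per_locus[0])
            hi = max(lo, cfg.n_bsjs_per_locus[1])
            n_bsj = int(rng.integers(lo, hi + 1))
        else:
            n_bsj = 1

        # circles span a realistic number of exons; clustered events all
        # cross a shared anchor exon so their genomic spans overlap
        anchor = n_ex // 2
        pairs: list[tuple[int, int]] = []
        tries = 0
        while len(pairs) < n_bsj and tries < 100:
            tries += 1
            span = int(rng.integers(cfg.circle_exons[0],
                                    min(cfg.circle_exons[1], n_ex) + 1))
            lo_a = max(0, anchor - span + 1)
            hi_a = min(anchor, n_ex - span)
            if hi_a < lo_a:
                continue
            a = int(rng.integers(lo_a, hi_a + 1))
            b = a + span - 1
            if (a, b) not in pairs:
                pairs.append((a, b))
        pairs.sort()

        for bi, (a, b) in enumerate(pairs, 1):
            bsj = BackSpliceJunction(
                cfg.chromosome, exons[a][0], exons[b][1], strand, 0
            )
            bsjs.append(bsj)
            internal = list(range(a + 1, b))
            n_iso = int(rng.integers(cfg.isoforms_per_bsj[0], cfg.isoforms_per_bsj[1] + 1))
            for ii, skip in enumerate(_distinct_subsets(rng, internal, n_iso), 1):
                chain = [exons[j] for j in range(a, b + 1) if j not in skip]
                transcripts.append(
                    TruthTranscript(
                        transcript_id=f"circ{gid}-{bi}-{ii}",
                        gene_id=gid,
                        chromosome=cfg.chromosome,
                        strand=strand,
                        bsj=bsj,
                        exon_chain=chain,
                        expression=0.0,
                    )
                )

    _assign_expression(rng, transcripts, *cfg.expression_range)
    return SimTruth(cfg, GeneAnnotation(genes), transcripts, bsjs, chrom_length=cursor)


def reassign_expression(truth: SimTruth, seed: int) -> SimTruth:
    """New random expression levels on the same truth structure — one
    'condition' of a multi-condition design."""
    rng = np.random.default_rng(seed)
    new = replace(
        truth,
        transcripts=[replace(t, fragment_count=0) for t in truth.transcripts],
        bsjs=[replace(b, support=0) for b in truth.bsjs],
    )
    _assign_expression(rng, new.transcripts, *truth.config.expression_range)
    return new


def _tx_interval_to_chains(
    layout: TranscriptLayout, t0: int, t1: int
) -> list[list[Interval]]:
    """Genomic block chains of a transcript interval; wraps past the
    junction split into two chains."""
    L = layout.length
    pieces = [(t0, t1)] if t1 <= L else [(t0, L), (0, t1 - L)]
    chains = []
    offs = layout.offsets
    for p0, p1 in pieces:
        blocks = []
        ei = int(np.searchsorted(offs, p0, side="right")) - 1
        while p0 < p1:
            s, e = layout.exons[ei]
            off = offs[ei]
            seg1 = min(p1, offs[ei + 1])
            if layout.minus:
                blocks.append((e - (seg1 - off), e - (p0 - off)))
            else:
                blocks.append((s + (p0 - off), s + (seg1 - off)))
            p0 = seg1
            ei += 1
        blocks.sort()
        chains.append(blocks)
    return chains


def _cigar(blocks: list[Interval]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_reads(
    truth: SimTruth,
    cfg: SimConfig,
    sam_path,
    fastq_prefix=None,
    reads_seed_offset: int = 1,
) -> SimTruth:
    """Sample paired-end fragments and write them as aligned SAM.

    Fragment counts per transcript are multinomial with probability
    proportional to expression x length; fragment starts are uniform on
    the circle and lengths normal, truncated to [read_length, l(t)].
    Junction supports and per-transcript fragment counts are recorded
    back into the returned truth."""
    rng = np.random.default_rng((cfg.seed + reads_seed_offset) % (2**31 - 1))
    rl = cfg.read_length
    weights = np.array([t.expression * t.length for t in truth.transcripts])
    support: dict[tuple, int] = {b.key: 0 for b in truth.bsjs}

    fq1 = open(f"{fastq_prefix}_1.fastq", "w") if fastq_prefix else None
    fq2 = open(f"{fastq_prefix}_2.fastq", "w") if fastq_prefix else None

    counts = (
        rng.multinomial(cfg.n_read_pairs, weights / weights.sum())
        if cfg.n_read_pairs > 0 and weights.sum() > 0
        else np.zeros(len(weights), dtype=int)
    )

    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        sam.write(f"@SQ\tSN:{cfg.chromosome}\tLN:{truth.chrom_length}\n")
        sam.write("@PG\tID:circiso-sim\tPN:circiso-sim\n")
        frag_no = 0
        for t, m in zip(truth.transcripts, counts):
            if m == 0:
                continue
            ct = t.as_circular_transcript()
            layout = TranscriptLayout(ct)
            L = layout.length
            if L < rl:
                continue
            t.fragment_count = int(m)
            seq = None
            if fq1:
                seq_rng = np.random.default_rng(
                    (cfg.seed * 1_000_003 + zlib.crc32(t.transcript_id.encode()))
                    % (2**31 - 1)
                )
                seq = "".join(seq_rng.choice(list("ACGT"), size=L))
            starts = rng.integers(0, L, size=m)
            flens = np.clip(
                np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=m)),
                rl, L,
            ).astype(int)
            for s0, fl in zip(starts, flens):
                frag_no += 1
                qname = f"frag{frag_no:09d}"
                m1 = (int(s0), int(s0) + rl)
                m2 = (int(s0) + int(fl) - rl, int(s0) + int(fl))
                mate_chains = []
                for a, b in (m1, m2):
                    a_ = a % L
                    mate_chains.append(_tx_interval_to_chains(layout, a_, a_ + (b - a)))
                if any(len(c) > 1 for c in mate_chains):
                    support[t.bsj.key] += 1
                for mate_no, chains in enumerate(mate_chains, 1):
                    flag = 99 if mate_no == 1 else 147
                    mpos = mate_chains[2 - mate_no][0][0][0] + 1
                    for chain in chains:
                        sam.write(
                            f"{qname}\t{flag}\t{cfg.chromosome}\t{chain[0][0] + 1}\t50\t"
                            f"{_cigar(chain)}\t=\t{mpos}\t0\t*\t*\n"
                        )
                    if fq1 and seq:
                        a, b = (m1, m2)[mate_no - 1]
                        a_ = a % L
                        b_ = a_ + (b - a)
                        read = seq[a_:b_] if b_ <= L else seq[a_:] + seq[: b_ - L]
                        if mate_no == 2:
                            read = read.translate(_COMP)[::-1]
                        fh = fq1 if mate_no == 1 else fq2
                        fh.write(f"@{qname}/{mate_no}\n{read}\n+\n{'I' * len(read)}\n")
    if fq1:
        fq1.close()
        fq2.close()

    truth.bsjs = [replace(b, support=support[b.key]) for b in truth.bsjs]
    # keep transcript records pointing at the supported junction objects
    by_key = {b.key: b for b in truth.bsjs}
    for t in truth.transcripts:
        t.bsj = by_key[t.bsj.key]
    return truth


def write_annotation_gtf(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        for g in truth.annotation:
            for tid, idxs in g.transcripts.items():
                for i in idxs:
                    s, e = g.exons[i]
                    fh.write(
                        f"{g.chromosome}\tcirciso-sim\texon\t{s + 1}\t{e}\t.\t"
                        f'{g.strand}\t.\tgene_id "{g.gene_id}"; transcript_id "{tid}";\n'
                    )


def write_bsj_list(truth: SimTruth, path) -> None:
    """CIRCexplorer2-style table: BED6 plus filler, support in column 13."""
    with open(path, "w") as fh:
        for b in truth.bsjs:
            fields = [
                b.chromosome, str(b.start), str(b.end),
                f"circ/{b.support}", "0", b.strand,
                str(b.start), str(b.end), "0,0,0", "1",
                str(b.end - b.start), "0", str(b.support),
            ]
            fh.write("\t".join(fields) + "\n")


def write_truth_table(truth: SimTruth, path) -> None:
    cols = [
        "transcript_id", "gene_id", "chrom", "strand", "bsj_start", "bsj_end",
        "exon_chain", "length", "expression", "theta", "fragment_count",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth.transcripts:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.transcript_id, t.gene_id, t.chromosome, t.strand,
                        t.bsj.start, t.bsj.end, chain_to_str(t.exon_chain),
                        t.length, f"{t.expression:.6g}", f"{t.theta:.6g}",
                        t.fragment_count,
                    )
                )
                + "\n"
            )


def run_simulation(cfg: SimConfig, out_prefix, with_fastq: bool = False) -> dict[str, str]:
    """Generate a full dataset: annotation GTF, aligned SAM, junction
    list, truth table (and FASTQ on request).  Returns the paths."""
    truth = simulate_truth(cfg)
    paths = {
        "annotation": f"{out_prefix}.annotation.gtf",
        "sam": f"{out_prefix}.alignments.sam",
        "bsj": f"{out_prefix}.bsj.tsv",
        "truth": f"{out_prefix}.truth.tsv",
    }
    fq_prefix = f"{out_prefix}.reads" if with_fastq else None
    truth = simulate_reads(truth, cfg, paths["sam"], fastq_prefix=fq_prefix)
    if with_fastq:
        paths["fastq1"] = f"{fq_prefix}_1.fastq"
        paths["fastq2"] = f"{fq_prefix}_2.fastq"
    write_annotation_gtf(truth, paths["annotation"])
    write_bsj_list(truth, paths["bsj"])
    write_truth_table(truth, paths["truth"])
    return paths
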