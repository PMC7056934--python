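"""Model/Results interface over the full assembly + quantification pipeline.

``CircIsoformModel`` holds the inputs — gene annotation, paired-end
spliced alignments, and a back-splice-junction list — and configuration.
``fit()`` runs the stages in order (filter junctions, assign to loci,
build splice graphs, extract subpath evidence, minimum path cover,
EM abundance estimation, low-abundance filter, expression metrics,
relation index) and returns a ``CircIsoformResults`` carrying the
assembled isoforms, their expression estimates, per-stage diagnostics
and a summary table.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd

from . import io
from .core import BackSpliceJunction, CircularTranscript, ExpressionRecord, FragmentAlignment, GeneAnnotation, chain_to_str
from .empc import InfeasibleCover, assemble_locus
from .graph import (
    MultipleSpliceGraphs,
    UnassembledBSJ,
    assign_bsjs_to_loci,
    build_splice_graph,
    extract_subpaths,
)
from .quant import (
    FragmentLengthModel,
    QuantConfig,
    compute_expression_metrics,
    estimate_fragment_length_model,
    filter_low_abundance,
    em_estimate,
)
from .relation import relation_index_map

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_support: int = 10
    boundary_tolerance: int = 0
    k_effective: int = 3
    filter_ratio: float = 1e-3
    max_em_iters: int = 1000
    loglik_tol: float = 1e-6
    fragment_mean: float | None = None  # None: self-calibrated
    fragment_sd: float | None = None

    def quant(self) -> QuantConfig:
        return QuantConfig(
            k_effective=self.k_effective,
            filter_ratio=self.filter_ratio,
            max_em_iters=self.max_em_iters,
            loglik_tol=self.loglik_tol,
        )


class CircIsoformModel:
    """Circular-isoform assembly and abundance model.

    Parameters
    ----------
    annotation : GeneAnnotation
    fragments : list of FragmentAlignment
        Paired-end spliced alignments (gapped reads define splice edges).
    junctions : list of BackSpliceJunction
        Back-splice events from an upstream detector.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        annotation: GeneAnnotation,
        fragments: list[FragmentAlignment],
        junctions: list[BackSpliceJunction],
        config: PipelineConfig | None = None,
    ):
        self.annotation = annotation
        self.fragments = fragments
        self.junctions = junctions
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(
        cls,
        annotation_path,
        sam_path,
        bsj_path,
        dialect: str = "circexplorer2",
        config: PipelineConfig | None = None,
    ) -> "CircIsoformModel":
        annotation = io.read_gene_annotation(annotation_path)
        fragments = io.read_alignments(sam_path)
        junctions = io.read_bsj_list(bsj_path, dialect)
        return cls(annotation, fragments, junctions, config)

    # ------------------------------------------------------------------

    def fit(self) -> "CircIsoformResults":
        cfg = self.config
        diag: dict[str, int | float] = {}

        bsjs = io.filter_bsj_by_support(self.junctions, cfg.min_support)
        diag["junctions_in"] = len(self.junctions)
        diag["junctions_after_support_filter"] = len(bsjs)

        # resolve '.' strands from the annotation where possible
        bsjs = [self._resolve_strand(b) for b in bsjs]

        assigned, unassigned = assign_bsjs_to_loci(
            bsjs, self.annotation, cfg.boundary_tolerance
        )
        diag["junctions_unassigned"] = len(unassigned)

        # fragments indexed by chromosome and sorted by span start so each
        # locus extracts its fragments by bisection
        frags_by_chrom: dict[str, tuple[list[int], list[tuple[int, FragmentAlignment]]]] = {}
        tmp: dict[str, list[tuple[int, int, FragmentAlignment]]] = {}
        for f in self.fragments:
            s, e = f.span
            tmp.setdefault(f.chromosome, []).append((s, e, f))
        for chrom, items in tmp.items():
            items.sort(key=lambda x: (x[0], x[1]))
            frags_by_chrom[chrom] = (
                [s for s, _, _ in items],
                [(e, f) for _, e, f in items],
            )
        diag["fragments_total"] = len(self.fragments)

        groups: list[tuple[list[CircularTranscript], list[FragmentAlignment]]] = []
        n_unassembled = 0
        for gid in sorted(assigned):
            locus = self.annotation.get(gid)
            span_lo = min(b.start for b in assigned[gid])
            span_hi = max(b.end for b in assigned[gid])
            locus_frags = self._locus_fragments(
                frags_by_chrom.get(locus.chromosome), span_lo, span_hi
            )
            msg = MultipleSpliceGraphs(gid)
            families = []
            for bsj in sorted(assigned[gid], key=lambda b: (b.start, b.end)):
                try:
                    g = build_splice_graph(
                        locus, bsj, locus_frags, cfg.boundary_tolerance
                    )
                except UnassembledBSJ as exc:
                    log.info("unassembled: %s", exc)
                    n_unassembled += 1
                    continue
                families.append(extract_subpaths(g, locus_frags))
                msg.graphs.append(g)
            if not msg.graphs:
                continue
            try:
                transcripts = assemble_locus(msg, families)
            except InfeasibleCover as exc:
                log.warning("locus %s: %s", gid, exc)
                n_unassembled += len(msg.graphs)
                continue
            groups.append((transcripts, locus_frags))
        diag["junctions_unassembled"] = n_unassembled
        diag["transcripts_assembled"] = sum(len(t) for t, _ in groups)

        # fragment-length model: explicit override or self-calibration on
        # single-isoform loci
        if cfg.fragment_mean is not None and cfg.fragment_sd is not None:
            F = FragmentLengthModel(cfg.fragment_mean, cfg.fragment_sd)
        else:
            F = estimate_fragment_length_model(groups, cfg.k_effective)
        diag["fragment_length_mean"] = round(F.mean, 2)
        diag["fragment_length_sd"] = round(F.sd, 2)

        qcfg = cfg.quant()
        final: list[CircularTranscript] = []
        n_orphan = 0
        for transcripts, locus_frags in groups:
            try:
                res = em_estimate(transcripts, locus_frags, F, qcfg)
            except ValueError:
                n_orphan += len(transcripts)
                continue
            kept, dropped = filter_low_abundance(transcripts, qcfg)
            if dropped and kept:
                one = QuantConfig(qcfg.k_effective, qcfg.filter_ratio, 1, qcfg.loglik_tol)
                try:
                    em_estimate(kept, locus_frags, F, one)
                except ValueError:
                    pass
            final.extend(kept)
        diag["transcripts_filtered_out"] = diag["transcripts_assembled"] - len(final)
        diag["transcripts_out"] = len(final)

        ri = relation_index_map(bsjs)
        records = (
            compute_expression_metrics(final, max(len(self.fragments), 1), ri)
            if final
            else []
        )
        return CircIsoformResults(
            model=self,
            transcripts=final,
            expression=records,
            fragment_length_model=F,
            relation_index=ri,
            diagnostics=diag,
            unassigned_junctions=unassigned,
        )

    # ------------------------------------------------------------------

    def _resolve_strand(self, bsj: BackSpliceJunction) -> BackSpliceJunction:
        if bsj.strand != ".":
            return bsj
        for g in self.annotation:
            if (
                g.chromosome == bsj.chromosome
                and bsj.start in g.exon_starts()
                and bsj.end in g.exon_ends()
            ):
                return BackSpliceJunction(
                    bsj.chromosome, bsj.start, bsj.end, g.strand, bsj.support
                )
        return bsj

    @staticmethod
    def _locus_fragments(index, lo: int, hi: int) -> list[FragmentAlignment]:
        if index is None:
            return []
        starts, rest = index
        i = bisect_left(starts, lo)
        out = []
        while i < len(starts) and starts[i] < hi:
            e, f = rest[i]
            if e <= hi:
                out.append(f)
            i += 1
        return out


@dataclass
class CircIsoformResults:
    """Fitted results: assembled isoforms with abundance estimates."""

    model: CircIsoformModel
    transcripts: list[CircularTranscript]
    expression: list[ExpressionRecord]
    fragment_length_model: FragmentLengthModel
    relation_index: dict
    diagnostics: dict = field(default_factory=dict)
    unassigned_junctions: list = field(default_factory=list)

    def expression_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "chrom": r.bsj.chromosome,
                "bsj_start": r.bsj.start,
                "bsj_end": r.bsj.end,
                "strand": r.strand,
                "exon_chain": chain_to_str(r.exon_chain),
                "length": r.length,
                "read_count": r.read_count,
                "FPKM": r.fpkm,
                "TPM": r.tpm,
                "RI": r.relation_index,
            }
            for r in self.expression
        ]
        return pd.DataFrame(rows)

    def save(self, out_prefix) -> tuple[str, str]:
        return io.write_outputs(self.expression, out_prefix)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Circular isoform assembly & quantification",
            "=" * 46,
            f"junctions in                  {d.get('junctions_in', 0):>8}",
            f"  after support filter        {d.get('junctions_after_support_filter', 0):>8}",
            f"  unassigned to any locus     {d.get('junctions_unassigned', 0):>8}",
            f"  unassembled                 {d.get('junctions_unassembled', 0):>8}",
            f"fragments (mapped pairs)      {d.get('fragments_total', 0):>8}",
            f"fragment length model         N({self.fragment_length_model.mean:.1f}, "
            f"{self.fragment_length_model.sd:.1f}^2)",
            f"transcripts assembled         {d.get('transcripts_assembled', 0):>8}",
            f"  below 1/1000 abundance      {d.get('transcripts_filtered_out', 0):>8}",
            f"  reported                    {d.get('transcripts_out', 0):>8}",
        ]
        return "\n".join(lines)
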