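"""Scoring of assembly and quantification against a known truth.

A predicted isoform is a true positive when its full exon chain exactly
matches a truth isoform of the same back-splice junction.  Sensitivity,
precision and F1 follow the usual definitions; quantification accuracy
is Pearson and Spearman correlation between truth and estimated
abundances, either absolute (all matched transcripts) or relative
(within-locus proportions).  Scores can be stratified by the junctions'
relation index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CircularTranscript, ExpressionRecord
from .simulate import TruthTranscript


@dataclass
class AssemblyScore:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def sensitivity(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * s * p / (s + p) if (s + p) else 0.0


def _truth_keys(truth: list[TruthTranscript], expressed_only: bool = True) -> set:
    return {
        t.chain_key
        for t in truth
        if not expressed_only or t.fragment_count > 0
    }


def _pred_keys(predicted) -> set:
    return {p.chain_key for p in predicted}


def score_assembly(
    truth: list[TruthTranscript],
    predicted: list[CircularTranscript] | list[ExpressionRecord],
    expressed_only: bool = True,
) -> AssemblyScore:
    """Exact exon-chain matching of predictions against truth.

    The sensitivity denominator counts truth isoforms with at least one
    emitted fragment (an unexpressed isoform leaves no evidence to
    assemble from)."""
    t_keys = _truth_keys(truth, expressed_only)
    p_keys = {
        (r.bsj.chromosome, r.bsj.start, r.bsj.end, tuple(sorted(r.exon_chain)))
        for r in predicted
    }
    tp = len(t_keys & p_keys)
    return AssemblyScore(tp, len(p_keys - t_keys), len(t_keys - p_keys))


def score_quantification(
    truth: list[TruthTranscript],
    predicted: list[ExpressionRecord],
    mode: str = "absolute",
) -> tuple[float, float]:
    """(PCC, SCC) between truth and estimated abundance over matched
    transcripts.

    ``absolute``: truth fragment counts vs estimated read counts.
    ``relative-per-locus``: within-locus abundance proportions,
    restricted to loci with >=2 matched isoforms."""
    pred_by_key = {
        (r.bsj.chromosome, r.bsj.start, r.bsj.end, tuple(sorted(r.exon_chain))): r
        for r in predicted
    }
    pairs: list[tuple[float, float, str]] = []
    for t in truth:
        r = pred_by_key.get(t.chain_key)
        if r is None:
            continue
        pairs.append((float(t.fragment_count), r.read_count, t.gene_id))
    if mode == "relative-per-locus":
        by_gene: dict[str, list[tuple[float, float]]] = {}
        for x, y, g in pairs:
            by_gene.setdefault(g, []).append((x, y))
        rel = []
        for g, vals in by_gene.items():
            if len(vals) < 2:
                continue
            sx = sum(v[0] for v in vals) or 1.0
            sy = sum(v[1] for v in vals) or 1.0
            rel.extend((x / sx, y / sy) for x, y in vals)
        xs = np.array([v[0] for v in rel])
        ys = np.array([v[1] for v in rel])
    else:
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
    if len(xs) < 3:
        raise ValueError("need at least 3 matched transcript pairs")
    pcc = float(stats.pearsonr(xs, ys).statistic)
    scc = float(stats.spearmanr(xs, ys).statistic)
    return pcc, scc


RI_BINS = (1, 2, 3, 4)


def stratify_by_ri(
    truth: list[TruthTranscript],
    predicted: list[CircularTranscript] | list[ExpressionRecord],
    ri_map: dict[tuple[str, int, int], int],
    expressed_only: bool = True,
) -> dict[str, AssemblyScore]:
    """Assembly scores recomputed within relation-index bins
    {1, 2, 3, 4, '>4'}; empty bins are omitted."""
    out: dict[str, AssemblyScore] = {}
    def bin_of(key) -> str:
        ri = ri_map.get(key, 1)
        return str(ri) if ri in RI_BINS else ">4"
    bins = sorted({bin_of(t.bsj.key) for t in truth})
    for b in bins:
        t_sub = [t for t in truth if bin_of(t.bsj.key) == b]
        p_sub = [p for p in predicted if bin_of(p.bsj.key) == b]
        score = score_assembly(t_sub, p_sub, expressed_only)
        if score.true_positives + score.false_positives + score.false_negatives:
            out[b] = score
    return out


def pooled_score(scores: list[AssemblyScore]) -> AssemblyScore:
    return AssemblyScore(
        sum(s.true_positives for s in scores),
        sum(s.false_positives for s in scores),
        sum(s.false_negatives for s in scores),
    )
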