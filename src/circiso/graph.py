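"""Per-back-splice-event splice graphs.

For every back-splice junction assigned to a gene locus we build one
directed acyclic graph whose nodes are the annotated exons inside the
circle's span and whose edges are forward splice junctions witnessed by
gapped reads.  The two back-spliced exons are the single source and sink;
a source->sink path is a candidate circular isoform.  Reads spanning at
least three consecutive exons additionally yield subpath evidence that
the assembler must honour.

All ordering is by ``node_index`` in transcription (5'->3') order, so
minus-strand loci share a single code path with plus-strand ones.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .core import BackSpliceJunction, FragmentAlignment, GeneAnnotation, GeneLocus, Interval

log = logging.getLogger(__name__)


class UnassembledBSJ(Exception):
    """Raised when no splice graph can be built for a junction
    (no matching annotated exon, or insufficient forward-spliced reads
    to connect source and sink)."""


@dataclass(frozen=True)
class ExonNode:
    interval: Interval
    node_index: int

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise ValueError("exon node must have end > start")


@dataclass
class SpliceGraph:
    bsj: BackSpliceJunction
    strand: str
    nodes: list[ExonNode]
    edges: set[tuple[int, int]]
    source: int
    sink: int
    gene_id: str = ""

    def successors(self, i: int) -> list[int]:
        return sorted(v for u, v in self.edges if u == i)

    def predecessors(self, i: int) -> list[int]:
        return sorted(u for u, v in self.edges if v == i)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def exon_chain_for(self, path: list[int]) -> list[Interval]:
        """Exon intervals of a node-index path, in transcription order."""
        return [self.nodes[i].interval for i in path]


@dataclass
class SubpathEvidence:
    node_run: tuple[int, ...]
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if len(self.node_run) < 3:
            raise ValueError("a subpath constraint spans at least 3 nodes")


@dataclass
class MultipleSpliceGraphs:
    locus: str
    graphs: list[SpliceGraph] = field(default_factory=list)


def assign_bsjs_to_loci(
    bsjs: list[BackSpliceJunction],
    annotation: GeneAnnotation,
    tolerance: int = 0,
) -> tuple[dict[str, list[BackSpliceJunction]], list[BackSpliceJunction]]:
    """Assign each junction to the loci whose annotated exon boundaries
    match both of its coordinates (within ``tolerance`` bp).

    Returns (gene_id -> junctions, unassigned junctions).  A junction
    matching two overlapping genes appears under both, with a warning.
    """
    by_chrom: dict[str, list[GeneLocus]] = defaultdict(list)
    for g in annotation:
        by_chrom[g.chromosome].append(g)

    assigned: dict[str, list[BackSpliceJunction]] = defaultdict(list)
    unassigned: list[BackSpliceJunction] = []
    for bsj in bsjs:
        hits = []
        for g in by_chrom.get(bsj.chromosome, []):
            if bsj.strand != "." and g.strand in "+-" and bsj.strand != g.strand:
                continue
            starts, ends = g.exon_starts(), g.exon_ends()
            ok_start = any(abs(bsj.start - s) <= tolerance for s in starts)
            ok_end = any(abs(bsj.end - e) <= tolerance for e in ends)
            if ok_start and ok_end:
                hits.append(g.gene_id)
        if not hits:
            unassigned.append(bsj)
        else:
            if len(hits) > 1:
                log.warning(
                    "junction %s:%d-%d matches exon boundaries in %d genes",
                    bsj.chromosome, bsj.start, bsj.end, len(hits),
                )
            for gid in hits:
                assigned[gid].append(bsj)
    return dict(assigned), unassigned


def fragments_in_span(
    fragments: list[FragmentAlignment], start: int, end: int
) -> list[FragmentAlignment]:
    """Fragments whose every mapped segment lies within [start, end);
    fragments in regions where circles overlap are thereby shared among
    the overlapping graphs."""
    out = []
    for f in fragments:
        s, e = f.span
        if s >= start and e <= end:
            out.append(f)
    return out


def _snap(coord: int, candidates: set[int], tolerance: int) -> int | None:
    if coord in candidates:
        return coord
    if tolerance:
        near = [c for c in candidates if abs(c - coord) <= tolerance]
        if near:
            return min(near, key=lambda c: (abs(c - coord), c))
    return None


def _chain_junctions(chain: list[Interval]):
    for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
        yield (s1, e1), (s2, e2)


def build_splice_graph(
    locus: GeneLocus,
    bsj: BackSpliceJunction,
    fragments: list[FragmentAlignment],
    tolerance: int = 0,
) -> SpliceGraph:
    """Construct the splice graph of one back-splice event.

    Nodes are annotated exon variants fully inside the junction span;
    the exon starting at the junction's acceptor boundary and the exon
    ending at its donor boundary are source and sink (strand-adjusted).
    An edge (u, v) requires a gapped read whose gap boundaries coincide
    with u's 3' end and v's 5' start.  The sink->source circular
    junction itself is never an edge.

    Raises :class:`UnassembledBSJ` when no matching exon exists or the
    sink is unreachable from the source.
    """
    s = _snap(bsj.start, locus.exon_starts(), tolerance)
    e = _snap(bsj.end, locus.exon_ends(), tolerance)
    if s is None or e is None:
        raise UnassembledBSJ(
            f"{bsj.chromosome}:{bsj.start}-{bsj.end}: no annotated exon boundary match"
        )

    candidates = [iv for iv in locus.exons if iv[0] >= s and iv[1] <= e]
    minus = locus.strand == "-"
    ordered = sorted(candidates, reverse=minus)  # transcription order
    idx_of = {iv: i for i, iv in enumerate(ordered)}

    frags = fragments_in_span(fragments, s, e)

    # Read-evidence per exon interval (any overlapping segment).
    evidence: Counter = Counter()
    for f in frags:
        for a, b in f.all_segments():
            for iv in candidates:
                if a < iv[1] and b > iv[0]:
                    evidence[iv] += 1

    def pick(variants: list[Interval], what: str) -> Interval:
        if not variants:
            raise UnassembledBSJ(
                f"{bsj.chromosome}:{bsj.start}-{bsj.end}: no {what} exon inside span"
            )
        return max(variants, key=lambda iv: (evidence[iv], iv[1] - iv[0]))

    src_iv = pick([iv for iv in candidates if iv[0] == s] if not minus
                  else [iv for iv in candidates if iv[1] == e], "source")
    snk_iv = pick([iv for iv in candidates if iv[1] == e] if not minus
                  else [iv for iv in candidates if iv[0] == s], "sink")

    # Splice edges from within-chain gaps.
    by_end = defaultdict(list)
    by_start = defaultdict(list)
    for iv in candidates:
        by_start[iv[0]].append(iv)
        by_end[iv[1]].append(iv)
    edges: set[tuple[int, int]] = set()
    for f in frags:
        for chains in (f.mate1_chains, f.mate2_chains):
            for chain in chains:
                for (a1, a2), (b1, b2) in _chain_junctions(chain):
                    for u in by_end.get(a2, []):
                        if a1 < u[0]:
                            continue
                        for v in by_start.get(b1, []):
                            if b2 > v[1]:
                                continue
                            tu, tv = idx_of[u], idx_of[v]
                            if tu != tv:
                                edges.add((min(tu, tv), max(tu, tv)))

    src, snk = idx_of[src_iv], idx_of[snk_iv]
    if src == snk:
        keep = {src}
        edges = set()
    else:
        # Drop unsupported nodes, then restrict to nodes on some
        # source->sink path.
        supported = {
            idx_of[iv]
            for iv in candidates
            if evidence[iv] > 0 or iv in (src_iv, snk_iv)
        }
        edges = {(u, v) for u, v in edges if u in supported and v in supported}
        fwd = defaultdict(set)
        rev = defaultdict(set)
        for u, v in edges:
            fwd[u].add(v)
            rev[v].add(u)

        def closure(start: int, adj) -> set[int]:
            seen = {start}
            stack = [start]
            while stack:
                for w in adj[stack.pop()]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            return seen

        keep = closure(src, fwd) & closure(snk, rev)
        if snk not in keep or src not in keep:
            raise UnassembledBSJ(
                f"{bsj.chromosome}:{bsj.start}-{bsj.end}: sink unreachable from source "
                "(insufficient forward-spliced reads)"
            )
        edges = {(u, v) for u, v in edges if u in keep and v in keep}

    kept_ivs = [iv for iv in ordered if idx_of[iv] in keep]
    remap = {idx_of[iv]: i for i, iv in enumerate(kept_ivs)}
    nodes = [ExonNode(iv, i) for i, iv in enumerate(kept_ivs)]
    return SpliceGraph(
        bsj=bsj,
        strand=locus.strand,
        nodes=nodes,
        edges={(remap[u], remap[v]) for u, v in edges},
        source=remap[src],
        sink=remap[snk],
        gene_id=locus.gene_id,
    )


def _chain_to_run(graph: SpliceGraph, chain: list[Interval]) -> tuple[int, ...] | None:
    """Map one gapless-block chain to its node-index run, or None when
    the chain is inconsistent with (or ambiguous within) the graph."""
    ivs = [n.interval for n in graph.nodes]
    idx_of = {iv: i for i, iv in enumerate(ivs)}
    if len(chain) == 1:
        a, b = chain[0]
        hits = [i for i, iv in enumerate(ivs) if a >= iv[0] and b <= iv[1]]
        return (hits[0],) if len(hits) == 1 else None
    genomic: list[int] = []
    for pos, (a, b) in enumerate(chain):
        if pos == 0:
            hits = [idx_of[iv] for iv in ivs if iv[1] == b and a >= iv[0] and iv in idx_of]
        elif pos == len(chain) - 1:
            hits = [idx_of[iv] for iv in ivs if iv[0] == a and b <= iv[1]]
        else:
            hits = [idx_of[chain[pos]]] if (a, b) in idx_of else []
        if len(hits) != 1:
            return None
        genomic.append(hits[0])
    run = tuple(sorted(genomic))  # node_index is transcription order
    for u, v in zip(run, run[1:]):
        if (u, v) not in graph.edges:
            return None
    return run


def _bridgeable(graph: SpliceGraph, u: int, v: int) -> bool:
    """Two mate runs may be joined across the unobserved fragment gap
    only when u->v is an edge and no one-node detour u->w->v exists —
    otherwise the gap could hide a skipped exon and the joined run would
    assert an adjacency the fragment does not prove."""
    if (u, v) not in graph.edges:
        return False
    for w in graph.successors(u):
        if w != v and (w, v) in graph.edges:
            return False
    return True


def extract_subpaths(
    graph: SpliceGraph, fragments: list[FragmentAlignment]
) -> list[SubpathEvidence]:
    """Collect subpath constraints: runs of >=3 consecutive nodes
    jointly witnessed by one fragment.

    Chains of a junction-split read are kept as separate runs (the
    circular jump is not forward-splice evidence); runs of the two mates
    are joined when the join is unambiguous.  Duplicate runs are merged
    with their multiplicity incremented.
    """
    counts: Counter = Counter()
    n_inconsistent = 0
    lo, hi = graph.bsj.start, graph.bsj.end
    for f in fragments:
        s, e = f.span
        if s < lo or e > hi:
            continue
        runs: list[tuple[int, ...]] = []
        bad = False
        for chains in (f.mate1_chains, f.mate2_chains):
            for chain in chains:
                run = _chain_to_run(graph, chain)
                if run is None:
                    if len(chain) > 1:
                        bad = True
                elif run:
                    runs.append(run)
        if bad:
            n_inconsistent += 1
            continue
        runs.sort()
        merged: list[tuple[int, ...]] = []
        for run in runs:
            if not merged:
                merged.append(run)
                continue
            prev = merged[-1]
            if run[0] <= prev[-1]:
                # overlapping runs must agree on the shared stretch
                joined = tuple(sorted(set(prev) | set(run)))
                ok = all((u, v) in graph.edges for u, v in zip(joined, joined[1:]))
                if ok and set(prev) | set(run) == set(joined):
                    merged[-1] = joined
                else:
                    merged.append(run)
            elif _bridgeable(graph, prev[-1], run[0]):
                merged[-1] = prev + run
            else:
                merged.append(run)
        for run in merged:
            if len(run) >= 3:
                counts[run] += 1
    if n_inconsistent:
        log.debug(
            "%s:%d-%d: %d fragments with evidence inconsistent with the graph",
            graph.bsj.chromosome, lo, hi, n_inconsistent,
        )
    return [SubpathEvidence(run, m) for run, m in sorted(counts.items())]
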