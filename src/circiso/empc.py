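"""Extended minimum path cover on splice graphs.

Classic minimum path cover asks for the fewest paths covering every node
of a DAG.  Transcript assembly needs more: every observed splice edge
and every multi-exon evidence run must also appear in some path, and
every path must run from the back-spliced source exon to the back-spliced
sink exon.  ``solve_empc`` finds a minimum such cover.

Splice graphs of single circles are small (rarely more than a dozen
exons), so the solver enumerates all source->sink paths and runs an
iterative-deepening exact search over them, seeded with a combinatorial
lower bound.  Graphs whose path count exceeds ``PATH_CAP`` fall back to
a deterministic greedy cover.  A brute-force subset enumerator is
provided as an independent oracle for testing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .core import BackSpliceJunction, CircularTranscript
from .graph import MultipleSpliceGraphs, SpliceGraph, SubpathEvidence

log = logging.getLogger(__name__)

PATH_CAP = 2000


class InfeasibleCover(Exception):
    pass


@dataclass
class PathCoverSolution:
    paths: list[tuple[int, ...]]
    dropped_subpaths: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.paths)


def _nx_graph(graph: SpliceGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges)
    return g


def _all_paths(graph: SpliceGraph, cap: int = PATH_CAP) -> list[tuple[int, ...]] | None:
    if graph.source == graph.sink:
        return [(graph.source,)]
    g = _nx_graph(graph)
    out: list[tuple[int, ...]] = []
    for p in nx.all_simple_paths(g, graph.source, graph.sink):
        out.append(tuple(p))
        if len(out) > cap:
            return None
    out.sort()
    return out


def _contains_run(path: tuple[int, ...], run: tuple[int, ...]) -> bool:
    n, m = len(path), len(run)
    return any(path[i:i + m] == run for i in range(n - m + 1))


def _coverage(path: tuple[int, ...], elements: list) -> frozenset[int]:
    """Indices of required elements covered by one path.  Elements are
    node ints, edge pairs, or longer runs."""
    covered = set()
    pset = set(path)
    pedges = set(zip(path, path[1:]))
    for i, el in enumerate(elements):
        if isinstance(el, int):
            if el in pset:
                covered.add(i)
        elif len(el) == 2:
            if el in pedges:
                covered.add(i)
        elif _contains_run(path, el):
            covered.add(i)
    return frozenset(covered)


def _check_conditions(
    graph: SpliceGraph,
    subpaths: list[tuple[int, ...]],
    paths: list[tuple[int, ...]],
) -> bool:
    """Literal check of the four cover conditions: all nodes covered (a),
    all edges covered (b), all subpaths contained contiguously (c), and
    every path running source->sink (d)."""
    nodes = set().union(*(set(p) for p in paths)) if paths else set()
    edges = set().union(*(set(zip(p, p[1:])) for p in paths)) if paths else set()
    if not nodes >= set(range(graph.n_nodes)):
        return False
    if not edges >= graph.edges:
        return False
    for run in subpaths:
        if not any(_contains_run(p, run) for p in paths):
            return False
    for p in paths:
        if p[0] != graph.source or p[-1] != graph.sink:
            return False
        if any((u, v) not in graph.edges for u, v in zip(p, p[1:])):
            return False
    return True


def _lower_bound(graph: SpliceGraph) -> int:
    """Every path through a node uses one in-edge and one out-edge, so
    covering all edges needs at least max(indeg, outdeg) paths at the
    busiest node."""
    lb = 1
    indeg: dict[int, int] = {}
    outdeg: dict[int, int] = {}
    for u, v in graph.edges:
        outdeg[u] = outdeg.get(u, 0) + 1
        indeg[v] = indeg.get(v, 0) + 1
    for d in itertools.chain(indeg.values(), outdeg.values()):
        lb = max(lb, d)
    return lb


def _exact_cover(
    paths: list[tuple[int, ...]],
    elements: list,
    k_start: int,
    k_max: int,
) -> list[tuple[int, ...]] | None:
    cover = [_coverage(p, elements) for p in paths]
    all_el = frozenset(range(len(elements)))
    feasible_el = frozenset().union(*cover) if cover else frozenset()
    if feasible_el != all_el:
        return None
    by_element: list[list[int]] = [[] for _ in elements]
    for pi, cov in enumerate(cover):
        for ei in cov:
            by_element[ei].append(pi)

    for k in range(k_start, k_max + 1):
        seen: set[frozenset[int]] = set()

        def dfs(chosen: tuple[int, ...], covered: frozenset[int]):
            if covered == all_el:
                return chosen
            if len(chosen) == k:
                return None
            key = frozenset(chosen)
            if key in seen:
                return None
            seen.add(key)
            # branch on the uncovered element with fewest covering paths
            ei = min(
                (i for i in range(len(elements)) if i not in covered),
                key=lambda i: (len(by_element[i]), i),
            )
            for pi in by_element[ei]:
                res = dfs(chosen + (pi,), covered | cover[pi])
                if res is not None:
                    return res
            return None

        res = dfs((), frozenset())
        if res is not None:
            return sorted(paths[i] for i in res)
    return None


def _greedy_cover(
    paths: list[tuple[int, ...]], elements: list
) -> list[tuple[int, ...]] | None:
    cover = [_coverage(p, elements) for p in paths]
    all_el = set(range(len(elements)))
    if not cover or set().union(*cover) != all_el:
        return None
    uncovered = set(all_el)
    chosen: list[int] = []
    while uncovered:
        best = max(
            range(len(paths)),
            key=lambda i: (len(cover[i] & uncovered), [-x for x in paths[i]]),
        )
        if not cover[best] & uncovered:
            return None
        chosen.append(best)
        uncovered -= cover[best]
    # drop paths made redundant by later picks
    pruned = list(chosen)
    for i in list(pruned):
        rest = [j for j in pruned if j != i]
        if rest and frozenset().union(*(cover[j] for j in rest)) >= all_el:
            pruned = rest
    return sorted(paths[i] for i in pruned)


def solve_empc(
    graph: SpliceGraph, subpaths: list[SubpathEvidence] | None = None
) -> PathCoverSolution:
    """Minimum set of source->sink paths covering every node, every edge,
    and every evidence subpath of one splice graph.

    Subpaths contained in no source->sink path are dropped (lowest
    multiplicity first) with a warning and the solve retried.
    Deterministic for identical inputs.
    """
    subpaths = sorted(subpaths or [], key=lambda sp: (-sp.multiplicity, sp.node_run))
    paths = _all_paths(graph)
    if paths is None:
        return _solve_large(graph, subpaths)
    if not paths:
        raise InfeasibleCover("sink unreachable from source")

    runs = [sp.node_run for sp in subpaths]
    dropped: list[tuple[int, ...]] = []
    # discard runs no path can contain (inconsistent evidence)
    kept_runs = []
    for run in runs:
        if any(_contains_run(p, run) for p in paths):
            kept_runs.append(run)
        else:
            dropped.append(run)
            log.warning("dropping subpath %s: contained in no source->sink path", run)

    elements: list = (
        list(range(graph.n_nodes)) + sorted(graph.edges) + kept_runs
    )
    k_lb = _lower_bound(graph)
    sol = _exact_cover(paths, elements, k_lb, len(paths))
    while sol is None and kept_runs:
        # mutually unsatisfiable subpaths: drop weakest evidence first
        run = kept_runs.pop()
        dropped.append(run)
        log.warning("dropping conflicting subpath %s", run)
        elements = list(range(graph.n_nodes)) + sorted(graph.edges) + kept_runs
        sol = _exact_cover(paths, elements, k_lb, len(paths))
    if sol is None:
        raise InfeasibleCover("no feasible path cover")
    return PathCoverSolution(sol, dropped)


def _solve_large(
    graph: SpliceGraph, subpaths: list[SubpathEvidence]
) -> PathCoverSolution:
    """Greedy fallback for graphs with too many source->sink paths to
    enumerate exhaustively: grow a path pool from shortest paths through
    every node/edge/subpath, then greedily cover."""
    g = _nx_graph(graph)
    pool: set[tuple[int, ...]] = set()

    def via(prefix_target, suffix_source, middle=()):
        try:
            pre = nx.shortest_path(g, graph.source, prefix_target)
            suf = nx.shortest_path(g, suffix_source, graph.sink)
        except nx.NetworkXNoPath:
            return
        pool.add(tuple(pre) + tuple(middle) + tuple(suf[1:]) if middle
                 else tuple(pre) + tuple(suf[1:]))

    for n in range(graph.n_nodes):
        via(n, n)
    for u, v in sorted(graph.edges):
        via(u, v)
    runs = [sp.node_run for sp in subpaths]
    for run in runs:
        via(run[0], run[-1], run[1:-1])
    paths = sorted(pool)
    elements: list = list(range(graph.n_nodes)) + sorted(graph.edges) + runs
    dropped: list[tuple[int, ...]] = []
    sol = _greedy_cover(paths, elements)
    while sol is None and runs:
        dropped.append(runs.pop())
        elements = list(range(graph.n_nodes)) + sorted(graph.edges) + runs
        sol = _greedy_cover(paths, elements)
    if sol is None:
        raise InfeasibleCover("no feasible path cover (greedy)")
    return PathCoverSolution(sol, dropped)


def enumerate_all_covers_bruteforce(
    graph: SpliceGraph,
    subpaths: list[SubpathEvidence] | None = None,
    max_nodes: int = 10,
) -> PathCoverSolution:
    """Test oracle: enumerate every subset of source->sink paths in
    increasing size and return the first (lexicographically smallest)
    feasible cover.  Provably minimum; refuses graphs over ``max_nodes``."""
    if graph.n_nodes > max_nodes:
        raise ValueError(f"brute force refuses graphs with more than {max_nodes} nodes")
    paths = _all_paths(graph, cap=10_000)
    if not paths:
        raise InfeasibleCover("sink unreachable from source")
    runs = [sp.node_run for sp in (subpaths or [])]
    for k in range(1, len(paths) + 1):
        for combo in itertools.combinations(paths, k):
            if _check_conditions(graph, runs, list(combo)):
                return PathCoverSolution(sorted(combo))
    raise InfeasibleCover("no feasible path cover")


def assemble_locus(
    graphs: MultipleSpliceGraphs,
    subpath_families: list[list[SubpathEvidence]],
) -> list[CircularTranscript]:
    """Run the path-cover solver on every splice graph of a locus and
    convert the paths to circular transcripts.

    Transcript IDs encode gene, junction ordinal (genomic order of the
    junction within the locus) and isoform ordinal: ``circGENE-2-1`` is
    the first isoform of the locus's second back-splice event.
    """
    order = sorted(
        range(len(graphs.graphs)),
        key=lambda i: (graphs.graphs[i].bsj.start, graphs.graphs[i].bsj.end),
    )
    out: list[CircularTranscript] = []
    for ordinal, gi in enumerate(order, 1):
        graph = graphs.graphs[gi]
        sol = solve_empc(graph, subpath_families[gi])
        for iso, path in enumerate(sol.paths, 1):
            out.append(
                CircularTranscript(
                    transcript_id=f"circ{graphs.locus}-{ordinal}-{iso}",
                    gene_id=graphs.locus,
                    bsj=graph.bsj,
                    exon_chain=graph.exon_chain_for(list(path)),
                    strand=graph.strand,
                )
            )
    return out
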