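"""Splice-graph construction and subpath-evidence extraction."""

import pytest

from circiso.core import BackSpliceJunction, FragmentAlignment, GeneAnnotation, GeneLocus
from circiso.graph import (
    UnassembledBSJ,
    assign_bsjs_to_loci,
    build_splice_graph,
    extract_subpaths,
)

# three-exon locus: E0=[100,200) E1=[400,500) E2=[800,900)
EXONS = [(100, 200), (400, 500), (800, 900)]


def locus(strand="+", exons=EXONS, gid="g1"):
    return GeneLocus(gid, "chr1", strand, list(exons), {"t1": list(range(len(exons)))})


def frag(fid, m1_chains, m2_chains):
    return FragmentAlignment(fid, m1_chains, m2_chains, "chr1")


def spliced(fid, *junction_pairs):
    """Fragment whose mate1 is one chain with blocks; mate2 empty stub
    replaced by a one-block chain inside the first exon touched."""
    chains = [list(junction_pairs)]
    return frag(fid, chains, [[junction_pairs[0]]])


BSJ = BackSpliceJunction("chr1", 100, 900, "+", 5)


class TestAssignment:
    def test_exact_boundary_match(self):
        anno = GeneAnnotation([locus()])
        assigned, unassigned = assign_bsjs_to_loci([BSJ], anno)
        assert assigned == {"g1": [BSJ]}
        assert unassigned == []

    def test_no_matching_boundary_reported(self):
        anno = GeneAnnotation([locus()])
        stray = BackSpliceJunction("chr1", 123, 900, "+")
        assigned, unassigned = assign_bsjs_to_loci([stray], anno)
        assert not assigned
        assert unassigned == [stray]

    def test_overlapping_genes_get_shared_bsj(self):
        g2 = locus(gid="g2")
        anno = GeneAnnotation([locus(), g2])
        assigned, _ = assign_bsjs_to_loci([BSJ], anno)
        assert set(assigned) == {"g1", "g2"}

    def test_strand_mismatch_not_assigned(self):
        anno = GeneAnnotation([locus("-")])
        assigned, unassigned = assign_bsjs_to_loci([BSJ], anno)
        assert not assigned and len(unassigned) == 1

    def test_boundary_tolerance(self):
        anno = GeneAnnotation([locus()])
        off = BackSpliceJunction("chr1", 99, 901, "+")
        assigned, _ = assign_bsjs_to_loci([off], anno, tolerance=2)
        assert "g1" in assigned


class TestBuild:
    def test_chain_graph(self):
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
        ]
        g = build_splice_graph(locus(), BSJ, frags)
        assert g.n_nodes == 3
        assert g.edges == {(0, 1), (1, 2)}
        assert (g.source, g.sink) == (0, 2)

    def test_skip_evidence_adds_edge(self):
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
            frag("c", [[(150, 200), (800, 850)]], [[(810, 880)]]),
        ]
        g = build_splice_graph(locus(), BSJ, frags)
        assert g.edges == {(0, 1), (1, 2), (0, 2)}

    def test_gapless_fragment_adds_no_edge(self):
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
            frag("c", [[(410, 450)]], [[(420, 470)]]),
        ]
        g = build_splice_graph(locus(), BSJ, frags)
        assert g.edges == {(0, 1), (1, 2)}

    def test_no_boundary_match_unassembled(self):
        bad = BackSpliceJunction("chr1", 150, 900, "+")
        with pytest.raises(UnassembledBSJ):
            build_splice_graph(locus(), bad, [])

    def test_sink_unreachable_unassembled(self):
        frags = [frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]])]
        with pytest.raises(UnassembledBSJ, match="unreachable"):
            build_splice_graph(locus(), BSJ, frags)

    def test_single_exon_circle(self):
        one = BackSpliceJunction("chr1", 100, 200, "+")
        g = build_splice_graph(locus(), one, [frag("a", [[(120, 180)]], [[(130, 190)]])])
        assert g.n_nodes == 1 and g.source == g.sink == 0
        assert g.edges == set()

    def test_minus_strand_indices_follow_transcription(self):
        mlocus = locus("-")
        mbsj = BackSpliceJunction("chr1", 100, 900, "-", 5)
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
        ]
        g = build_splice_graph(mlocus, mbsj, frags)
        # transcription order: E2, E1, E0
        assert g.nodes[0].interval == (800, 900)
        assert g.nodes[2].interval == (100, 200)
        assert g.edges == {(0, 1), (1, 2)}
        assert (g.source, g.sink) == (0, 2)

    def test_deterministic_rebuild(self):
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
        ]
        g1 = build_splice_graph(locus(), BSJ, frags)
        g2 = build_splice_graph(locus(), BSJ, list(frags))
        assert [n.interval for n in g1.nodes] == [n.interval for n in g2.nodes]
        assert g1.edges == g2.edges


class TestSubpaths:
    def _graph(self):
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
        ]
        return build_splice_graph(locus(), BSJ, frags), frags

    def test_three_node_run_emitted(self):
        g, _ = self._graph()
        f = frag("c", [[(150, 200), (400, 500), (800, 850)]], [[(810, 880)]])
        sps = extract_subpaths(g, [f])
        assert [sp.node_run for sp in sps] == [(0, 1, 2)]

    def test_duplicate_runs_merge_multiplicity(self):
        g, _ = self._graph()
        f1 = frag("c", [[(150, 200), (400, 500), (800, 850)]], [[(810, 880)]])
        f2 = frag("d", [[(150, 200), (400, 500), (800, 850)]], [[(810, 880)]])
        sps = extract_subpaths(g, [f1, f2])
        assert len(sps) == 1 and sps[0].multiplicity == 2

    def test_junction_split_mate_runs_split_at_circle(self):
        # read crosses the back-splice junction: one chain ends at the
        # sink exon's 3' end, the next re-enters at the source exon and
        # splices into E1 — only the post-junction part is a (2-node) run,
        # which is edge evidence, not a subpath
        g, _ = self._graph()
        f = FragmentAlignment(
            "w", [[(850, 900)], [(100, 130), (400, 420)]], [[(410, 480)]], "chr1",
            is_bsj_spanning=True,
        )
        sps = extract_subpaths(g, [f])
        assert sps == []

    def test_mate_pair_bridged_when_unambiguous(self):
        # no alternative route from E1 to E2, so joining mate runs (0,1)
        # and (2,) across the unobserved inner gap is safe
        g, _ = self._graph()
        f = frag("d", [[(150, 200), (400, 450)]], [[(800, 880)]])
        assert [sp.node_run for sp in extract_subpaths(g, [f])] == [(0, 1, 2)]

    def test_mate_pair_not_bridged_when_gap_could_hide_exon(self):
        # four-exon locus with both 1->2->3 and the direct 1->3 skip:
        # mate runs (0,1) and (3,) must not be joined — the gap could
        # contain E2 or not
        exons4 = EXONS + [(1200, 1300)]
        bsj4 = BackSpliceJunction("chr1", 100, 1300, "+", 5)
        frags = [
            frag("a", [[(150, 200), (400, 450)]], [[(410, 480)]]),
            frag("b", [[(450, 500), (800, 850)]], [[(810, 880)]]),
            frag("c", [[(450, 500), (1200, 1250)]], [[(1210, 1280)]]),
            frag("e", [[(850, 900), (1200, 1250)]], [[(1210, 1280)]]),
        ]
        g = build_splice_graph(locus(exons=exons4), bsj4, frags)
        assert g.edges == {(0, 1), (1, 2), (2, 3), (1, 3)}
        f = frag("d", [[(150, 200), (400, 450)]], [[(1200, 1280)]])
        assert extract_subpaths(g, [f]) == []

    def test_every_run_is_a_walk(self):
        g, frags = self._graph()
        f = frag("c", [[(150, 200), (400, 500), (800, 850)]], [[(810, 880)]])
        for sp in extract_subpaths(g, frags + [f]):
            for u, v in zip(sp.node_run, sp.node_run[1:]):
                assert (u, v) in g.edges
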