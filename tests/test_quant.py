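"""Quantification: compatibility, circular implied lengths, EM, metrics."""

import math

import numpy as np
import pytest

from circiso.core import BackSpliceJunction, CircularTranscript, FragmentAlignment
from circiso.quant import (
    FragmentLengthModel,
    QuantConfig,
    compute_expression_metrics,
    em_estimate,
    filter_low_abundance,
    fragment_compatibility,
    implied_fragment_length,
    selection_positions,
)

BSJ = BackSpliceJunction("chr1", 100, 1500, "+")


def transcript(chain, tid="t1", strand="+", bsj=BSJ):
    return CircularTranscript(tid, "g", bsj, chain, strand)


# exon chain E0=[100,500) E1=[700,1000) E2=[1200,1500); L = 1000
T3 = transcript([(100, 500), (700, 1000), (1200, 1500)])


def frag(m1, m2, fid="f"):
    return FragmentAlignment(fid, [m1], [m2], "chr1")


class TestCompatibility:
    def test_fragment_inside_single_exon(self):
        f = frag([(150, 250)], [(300, 400)])
        assert fragment_compatibility(f, T3)

    def test_junction_mismatch_incompatible(self):
        # splice E0 -> E2 against a transcript where E1 intervenes
        f = frag([(400, 500), (1200, 1250)], [(1250, 1350)])
        assert not fragment_compatibility(f, T3)

    def test_skip_transcript_accepts_skip_junction(self):
        t_skip = transcript([(100, 500), (1200, 1500)])
        f = frag([(400, 500), (1200, 1250)], [(1250, 1350)])
        assert fragment_compatibility(f, t_skip)

    def test_wrap_across_bsj_compatible(self):
        # mate1 at the 3' end of the sink exon, split across the
        # junction into the source exon; mate2 inside the source exon
        f = FragmentAlignment(
            "w", [[(1400, 1500)], [(100, 160)]], [[(200, 300)]], "chr1",
            is_bsj_spanning=True,
        )
        assert fragment_compatibility(f, T3)

    def test_sub_k_terminal_overhang_ignored(self):
        # 2-bp overhang into E1 would mismatch the chain, but ends
        # shorter than k=3 are trimmed before matching
        f = frag([(400, 500), (700, 702)], [(200, 300)])
        assert fragment_compatibility(f, T3, k=3)

    def test_segment_outside_exons_incompatible(self):
        f = frag([(550, 650)], [(700, 800)])
        assert not fragment_compatibility(f, T3)


class TestImpliedLength:
    def test_linear_case(self):
        # transcript coords: mate1 [0,100) mate2 [300,400) -> lt 400
        f = frag([(100, 200)], [(400, 500)])
        assert implied_fragment_length(f, T3) == 400

    def test_span_across_splice_junction(self):
        # mate2 inside E1: transcript position 400..500 -> lt 500
        f = frag([(100, 200)], [(700, 800)])
        assert implied_fragment_length(f, T3) == 500

    def test_mate2_upstream_wraps(self):
        # mate1 near the transcript 3' end, mate2 near the 5' start:
        # linear span is negative, so one full length is added
        f = frag([(1300, 1400)], [(150, 250)])
        # mate1 at [800,900), mate2 at [50,150): lt = 150 + 1000 - 800
        assert implied_fragment_length(f, T3) == 350

    def test_forced_extra_wrap_adds_full_length(self):
        f = frag([(100, 200)], [(400, 500)])
        assert implied_fragment_length(f, T3, wrap=True) == 400 + 1000

    def test_short_circle_termini_same_region(self):
        # circle of 250 bp; mates at transcript [0,100) and [150,250);
        # rolling-circle layout with an extra turn gives 250 + 250
        t = transcript([(100, 350)], bsj=BackSpliceJunction("chr1", 100, 350, "+"))
        f = frag([(100, 200)], [(250, 350)])
        assert implied_fragment_length(f, t) == 250
        assert implied_fragment_length(f, t, wrap=True) == 500

    def test_minus_strand_orientation(self):
        tm = transcript([(1200, 1500), (700, 1000), (100, 500)], strand="-")
        # 5' mate at the genomic right (transcription start)
        f = frag([(1400, 1500)], [(1200, 1300)])
        assert implied_fragment_length(f, tm) == 300

    def test_selection_positions(self):
        assert selection_positions(500, 3) == 496


class TestEM:
    F = FragmentLengthModel(300.0, 50.0)

    def test_single_transcript_forced(self):
        frags = [frag([(100, 200)], [(300, 400)], f"f{i}") for i in range(5)]
        res = em_estimate([T3], frags, self.F)
        assert res.theta[0] == pytest.approx(1.0)
        assert res.expected_counts[0] == pytest.approx(5.0)

    def test_unique_assignment_recovers_count_proportions(self):
        """Two equal-length transcripts with only uniquely compatible
        fragments, 30 vs 70 -> theta (0.3, 0.7)."""
        tA = transcript([(100, 500), (700, 1000), (1200, 1500)], "A")
        tB = transcript([(2100, 2500), (2700, 3000), (3200, 3500)], "B",
                        bsj=BackSpliceJunction("chr1", 2100, 3500, "+"))
        frags = [frag([(150, 250)], [(300, 400)], f"a{i}") for i in range(30)]
        frags += [frag([(2150, 2250)], [(2300, 2400)], f"b{i}") for i in range(70)]
        res = em_estimate([tA, tB], frags, self.F)
        assert res.theta == pytest.approx([0.3, 0.7], abs=1e-6)
        assert res.expected_counts.sum() == pytest.approx(100.0)

    def test_loglik_monotone_nondecreasing(self):
        tA = transcript([(100, 500), (700, 1000), (1200, 1500)], "A")
        tB = transcript([(100, 500), (1200, 1500)], "B")
        rng = np.random.default_rng(3)
        frags = []
        for i in range(60):
            s = int(rng.integers(100, 380))
            frags.append(frag([(s, s + 100)], [(s + 20, s + 120)], f"f{i}"))
        frags.append(frag([(400, 500), (700, 800)], [(750, 850)], "ej1"))
        frags.append(frag([(400, 500), (1200, 1300)], [(1250, 1350)], "ej2"))
        res = em_estimate([tA, tB], frags, self.F)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_conservation_after_em(self):
        tA = transcript([(100, 500), (700, 1000), (1200, 1500)], "A")
        tB = transcript([(100, 500), (1200, 1500)], "B")
        frags = [frag([(150, 250)], [(300, 400)], f"f{i}") for i in range(20)]
        frags.append(frag([(400, 500), (700, 800)], [(750, 850)], "ej"))
        res = em_estimate([tA, tB], frags, self.F)
        assert res.theta.sum() == pytest.approx(1.0)
        assert res.expected_counts.sum() == pytest.approx(res.n_used_fragments)

    def test_no_compatible_fragment_errors(self):
        with pytest.raises(ValueError):
            em_estimate([T3], [frag([(5000, 5100)], [(5200, 5300)])], self.F)

    def test_em_matches_grid_search_of_likelihood(self):
        """EM equals direct maximization of the printed likelihood on a
        2-isoform toy, to 3 decimals."""
        tA = transcript([(100, 500), (700, 1000), (1200, 1500)], "A")  # L=1000
        tB = transcript([(100, 500), (1200, 1500)], "B")               # L=700
        rng = np.random.default_rng(5)
        frags = []
        # shared fragments inside E0 plus a few junction-informative ones
        for i in range(40):
            s = int(rng.integers(100, 350))
            frags.append(frag([(s, s + 80)], [(s + 60, s + 140)], f"s{i}"))
        for i in range(6):
            frags.append(frag([(400, 500), (700, 800)], [(760, 860)], f"a{i}"))
        for i in range(3):
            frags.append(frag([(400, 500), (1200, 1300)], [(1260, 1360)], f"b{i}"))
        res = em_estimate([tA, tB], frags, self.F,
                          QuantConfig(loglik_tol=1e-12, max_em_iters=20000))

        # independent oracle: grid search over theta directly in the
        # likelihood  prod_f sum_t [theta_t l_t / sum theta l] * F[lt]/(l_t-2k+2)
        lts = []
        for f in frags:
            row = []
            for t in (tA, tB):
                lt = implied_fragment_length(f, t)
                row.append(lt)
            lts.append(row)
        lens = np.array([1000.0, 700.0])
        denom = lens - 2 * 3 + 2

        def loglik(theta_a):
            th = np.array([theta_a, 1 - theta_a])
            w = th * lens
            w = w / w.sum()
            total = 0.0
            for row in lts:
                p = 0.0
                for ti, lt in enumerate(row):
                    if lt is not None:
                        p += w[ti] * self.F.pdf(lt) / denom[ti]
                total += math.log(p)
            return total

        grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        best = grid[int(np.argmax([loglik(x) for x in grid]))]
        assert res.theta[0] == pytest.approx(best, abs=1e-3)


class TestFilterAndMetrics:
    def _with_theta(self, thetas):
        out = []
        for i, th in enumerate(thetas):
            t = transcript([(100, 500)], f"t{i}",
                           bsj=BackSpliceJunction("chr1", 100, 500, "+"))
            t.theta = th
            out.append(t)
        return out

    def test_low_abundance_dropped(self):
        kept, dropped = filter_low_abundance(self._with_theta([0.999, 0.0005]))
        assert [t.transcript_id for t in dropped] == ["t1"]
        assert kept[0].theta == pytest.approx(1.0)

    def test_balanced_pair_retained(self):
        kept, dropped = filter_low_abundance(self._with_theta([0.5, 0.5]))
        assert len(kept) == 2 and not dropped

    def test_singleton_always_retained(self):
        kept, dropped = filter_low_abundance(self._with_theta([1.0]))
        assert len(kept) == 1 and not dropped

    def test_fpkm_unit_arithmetic(self):
        t = transcript([(0, 1000)], bsj=BackSpliceJunction("chr1", 0, 1000, "+"))
        t.expected_count = 100.0
        rec = compute_expression_metrics([t], 10**6)[0]
        assert rec.fpkm == pytest.approx(100.0)
        assert rec.tpm == pytest.approx(1e6)

    def test_tpm_normalization_two_transcripts(self):
        t1 = transcript([(0, 1000)], "a", bsj=BackSpliceJunction("chr1", 0, 1000, "+"))
        t2 = transcript([(2000, 4000)], "b", bsj=BackSpliceJunction("chr1", 2000, 4000, "+"))
        t1.expected_count = t2.expected_count = 100.0
        recs = compute_expression_metrics([t1, t2], 10**6)
        assert recs[0].tpm == pytest.approx(666666.67, abs=0.01)
        assert recs[1].tpm == pytest.approx(333333.33, abs=0.01)
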