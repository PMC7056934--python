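"""Synthetic-data generator: determinism, geometry, sampling laws."""

import numpy as np
import pytest

from circiso.io import read_alignments, read_bsj_list, read_gene_annotation
from circiso.simulate import (
    SimConfig,
    run_simulation,
    simulate_reads,
    simulate_truth,
)


def small_cfg(**kw):
    defaults = dict(n_loci=6, n_read_pairs=4000, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestTruth:
    def test_single_isoform_config(self):
        truth = simulate_truth(small_cfg(isoforms_per_bsj=(1, 1)))
        per_bsj = {}
        for t in truth.transcripts:
            per_bsj.setdefault(t.bsj.key, []).append(t)
        assert all(len(v) == 1 for v in per_bsj.values())

    def test_same_seed_identical_files(self, tmp_path):
        p1 = run_simulation(small_cfg(), tmp_path / "a")
        p2 = run_simulation(small_cfg(), tmp_path / "b")
        for k in p1:
            assert open(p1[k]).read() == open(p2[k]).read()

    def test_overlap_fraction_yields_clustered_loci(self):
        truth = simulate_truth(small_cfg(n_loci=100, overlap_fraction=0.3, seed=9))
        by_gene = {}
        for t in truth.transcripts:
            by_gene.setdefault(t.gene_id, set()).add(t.bsj.key)
        n_multi = sum(1 for v in by_gene.values() if len(v) >= 2)
        # binomial(100, ~0.3) within 4 sd
        assert 10 <= n_multi <= 50

    def test_theta_sums_to_one_per_locus(self):
        truth = simulate_truth(small_cfg())
        sums = {}
        for t in truth.transcripts:
            sums[t.gene_id] = sums.get(t.gene_id, 0.0) + t.theta
        assert all(s == pytest.approx(1.0) for s in sums.values())

    def test_isoforms_share_source_and_sink(self):
        truth = simulate_truth(small_cfg(isoforms_per_bsj=(2, 3), circle_exons=(4, 6)))
        for t in truth.transcripts:
            chain = sorted(t.exon_chain)
            assert chain[0][0] == t.bsj.start
            assert chain[-1][1] == t.bsj.end


class TestReads:
    def test_outputs_parse_with_own_readers(self, tmp_path):
        paths = run_simulation(small_cfg(), tmp_path / "sim")
        anno = read_gene_annotation(paths["annotation"])
        frags = read_alignments(paths["sam"])
        bsjs = read_bsj_list(paths["bsj"], "circexplorer2")
        assert len(anno) == 6
        assert len(bsjs) >= 6
        assert sum(f.is_bsj_spanning for f in frags) > 0
        assert len(frags) <= 4000

    def test_zero_read_pairs(self, tmp_path):
        cfg = small_cfg(n_read_pairs=0)
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "z.sam")
        body = [l for l in open(tmp_path / "z.sam") if not l.startswith("@")]
        assert body == []

    def test_wrap_exists_on_short_circle(self, tmp_path):
        """Fragments longer than half the circle must sometimes wrap the
        junction (split SAM records)."""
        cfg = small_cfg(
            n_loci=1, circle_exons=(3, 3), exon_length=(100, 120),
            n_read_pairs=1500, fragment_mean=250.0, fragment_sd=30.0,
            isoforms_per_bsj=(1, 1), overlap_fraction=0.0,
        )
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "w.sam")
        assert any(b.support > 0 for b in truth.bsjs)

    def test_single_exon_circle_records_gapless_unless_split(self, tmp_path):
        cfg = small_cfg(
            n_loci=1, circle_exons=(2, 2), exon_length=(300, 400),
            n_read_pairs=500, isoforms_per_bsj=(1, 1), overlap_fraction=0.0,
        )
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "s.sam")
        # every CIGAR gap must sit at an annotated intron
        import re
        for line in open(tmp_path / "s.sam"):
            if line.startswith("@"):
                continue
            cigar = line.split("\t")[5]
            ops = re.findall(r"(\d+)([MN])", cigar)
            assert sum(int(n) for n, op in ops if op == "M") == cfg.read_length or \
                sum(int(n) for n, op in ops if op == "M") < cfg.read_length

    def test_fragment_count_recorded_matches_sam(self, tmp_path):
        cfg = small_cfg()
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "c.sam")
        frags = read_alignments(tmp_path / "c.sam")
        assert sum(t.fragment_count for t in truth.transcripts) == len(frags)

    def test_empirical_fragment_length_mean(self, tmp_path):
        cfg = small_cfg(n_loci=4, n_read_pairs=20_000, circle_exons=(4, 6),
                        exons_per_locus=(6, 10), seed=3,
                        isoforms_per_bsj=(1, 1), overlap_fraction=0.0)
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "m.sam")
        from circiso.quant import implied_fragment_length, TranscriptLayout
        frags = read_alignments(tmp_path / "m.sam")
        by_t = {t.chain_key: TranscriptLayout(t.as_circular_transcript())
                for t in truth.transcripts}
        cts = {t.chain_key: t.as_circular_transcript() for t in truth.transcripts}
        lts = []
        for f in frags[:4000]:
            for key, ct in cts.items():
                lt = implied_fragment_length(f, ct, layout=by_t[key])
                if lt is not None:
                    lts.append(lt)
                    break
        lts = np.array(lts)
        # truncation at read length biases the mean only slightly
        assert abs(lts.mean() - cfg.fragment_mean) < 3 * cfg.fragment_sd / np.sqrt(len(lts)) + 5

    def test_fragment_shares_follow_theta_times_length(self, tmp_path):
        """Law of large numbers: realized per-transcript fragment shares
        approach expression x length weighted probabilities."""
        cfg = small_cfg(n_loci=10, n_read_pairs=100_000, seed=11)
        truth = simulate_truth(cfg)
        truth = simulate_reads(truth, cfg, tmp_path / "lln.sam")
        w = np.array([t.expression * t.length for t in truth.transcripts])
        expected = w / w.sum()
        observed = np.array([t.fragment_count for t in truth.transcripts]) / cfg.n_read_pairs
        assert np.abs(observed - expected).max() < 0.03


class TestFastq:
    def test_fastq_written_and_paired(self, tmp_path):
        paths = run_simulation(small_cfg(n_read_pairs=200), tmp_path / "fq",
                               with_fastq=True)
        r1 = open(paths["fastq1"]).read().splitlines()
        r2 = open(paths["fastq2"]).read().splitlines()
        assert len(r1) % 4 == 0 and len(r1) == len(r2)
        assert r1[0].startswith("@frag") and set(r1[1]) <= set("ACGT")
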