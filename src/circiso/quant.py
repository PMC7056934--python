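"""Isoform abundance estimation on circular transcripts.

Given the assembled isoforms of a locus and the fragments mapped there,
the model treats each fragment as drawn from a mixture over isoforms:
the probability that a fragment originates from transcript ``t`` is
proportional to its abundance times its length, theta_t * l(t), and,
given the transcript, the fragment's implied length lt(f) follows a
normal fragment-length distribution F while its start is uniform over
the l(t) - 2k + 2 effective positions of the circle (k = effective
mapping threshold, 3 bp by default).  The log-likelihood is concave and
is maximized by EM.

Because the transcript is a circle, a fragment may wrap across the
back-splice junction: its implied length is measured along the circle
and a full transcript length is added when the footprint wraps past its
own start.  No effective-length correction is applied: circles have no
ends, so l(t) enters the likelihood uncorrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import CircularTranscript, ExpressionRecord, FragmentAlignment, Interval

log = logging.getLogger(__name__)


@dataclass
class FragmentLengthModel:
    """Normal fragment-length distribution F."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("fragment-length sd must be positive")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sd
        return np.exp(-0.5 * z * z) / (self.sd * math.sqrt(2.0 * math.pi))


@dataclass
class QuantConfig:
    k_effective: int = 3
    filter_ratio: float = 1e-3
    max_em_iters: int = 1000
    loglik_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k_effective < 1:
            raise ValueError("k_effective must be >= 1")
        if not 0 <= self.filter_ratio < 1:
            raise ValueError("filter_ratio must be in [0, 1)")


def selection_positions(length: int, k: int) -> int:
    """Number of effective start positions for a fragment on a circle of
    the given length: l(t) - 2k + 2."""
    return length - 2 * k + 2


class TranscriptLayout:
    """Coordinate map between the genome and one circular transcript.

    Transcript coordinates run 0..L in transcription (5'->3') order; on
    minus-strand transcripts genomic order is reversed, and positions
    within an exon run against the genomic axis.
    """

    def __init__(self, transcript: CircularTranscript):
        self.transcript = transcript
        self.minus = transcript.strand == "-"
        self.exons: list[Interval] = list(transcript.exon_chain)
        if self.minus:
            assert all(a[0] >= b[1] for a, b in zip(self.exons, self.exons[1:])) or \
                len(self.exons) == 1 or self.exons == sorted(self.exons, reverse=True)
        self.offsets = [0]
        for s, e in self.exons:
            self.offsets.append(self.offsets[-1] + (e - s))
        self.length = self.offsets[-1]

    def _block_to_tx(self, ei: int, a: int, b: int) -> tuple[int, int]:
        s, e = self.exons[ei]
        off = self.offsets[ei]
        if self.minus:
            return (off + (e - b), off + (e - a))
        return (off + (a - s), off + (b - s))

    def match_chain(self, chain: list[Interval]) -> tuple[int, int] | None:
        """Map one gapless-block chain onto the transcript.  Interior
        blocks must equal exons exactly and splice boundaries must be
        flush; returns the transcript interval or None if inconsistent."""
        blocks = list(reversed(chain)) if self.minus else list(chain)
        n = len(blocks)

        def flush3(block: Interval, exon: Interval) -> bool:
            # block reaches the exon's transcription-3' boundary
            return block[0] == exon[0] if self.minus else block[1] == exon[1]

        def flush5(block: Interval, exon: Interval) -> bool:
            return block[1] == exon[1] if self.minus else block[0] == exon[0]

        def contained(block: Interval, exon: Interval) -> bool:
            return block[0] >= exon[0] and block[1] <= exon[1]

        for i0 in range(len(self.exons)):
            if not contained(blocks[0], self.exons[i0]):
                continue
            if n > 1 and not flush3(blocks[0], self.exons[i0]):
                continue
            ok = True
            for j in range(1, n):
                ei = i0 + j
                if ei >= len(self.exons):
                    ok = False
                    break
                exon = self.exons[ei]
                if j < n - 1:
                    if blocks[j] != exon:
                        ok = False
                        break
                else:
                    if not (flush5(blocks[j], exon) and contained(blocks[j], exon)):
                        ok = False
                        break
            if not ok:
                continue
            ts, _ = self._block_to_tx(i0, *blocks[0])
            _, te = self._block_to_tx(i0 + n - 1, *blocks[-1])
            if n == 1:
                ts, te = self._block_to_tx(i0, *blocks[0])
            return (ts, te)
        return None


def _trim_chain(chain: list[Interval], k: int) -> list[Interval]:
    """Drop terminal blocks shorter than the effective-mapping threshold."""
    out = list(chain)
    while out and out[0][1] - out[0][0] < k:
        out.pop(0)
    while out and out[-1][1] - out[-1][0] < k:
        out.pop()
    return out


def _map_mate(
    layout: TranscriptLayout, chains: list[list[Interval]], k: int
) -> tuple[int, int] | None:
    """Map a mate (one or two chains) to an unrolled transcript interval
    [start, end) with start in [0, L); a junction-split mate wraps, so
    its end may exceed L."""
    trimmed = [c for c in (_trim_chain(ch, k) for ch in chains) if c]
    if not trimmed:
        return None
    ivs = []
    for ch in trimmed:
        m = layout.match_chain(ch)
        if m is None:
            return None
        ivs.append(m)
    if len(ivs) == 1:
        return ivs[0]
    if len(ivs) == 2:
        L = layout.length
        (s1, e1), (s2, e2) = ivs
        # the two pieces must abut the circular junction
        if e1 == L and s2 == 0:
            return (s1, e2 + L)
        if e2 == L and s1 == 0:
            return (s2, e1 + L)
    return None


def _mates_of(fragment: FragmentAlignment):
    m1 = fragment.mate1_chains or None
    m2 = fragment.mate2_chains or None
    return m1, m2


def map_fragment(
    fragment: FragmentAlignment, transcript: CircularTranscript, k: int = 3,
    layout: TranscriptLayout | None = None,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None] | None:
    """Transcript intervals of the two mates, or None if incompatible."""
    layout = layout or TranscriptLayout(transcript)
    m1, m2 = _mates_of(fragment)
    out = []
    for chains in (m1, m2):
        if chains is None:
            out.append(None)
            continue
        iv = _map_mate(layout, chains, k)
        if iv is None:
            return None
        out.append(iv)
    if out[0] is None and out[1] is None:
        return None
    return (out[0], out[1])


def fragment_compatibility(
    fragment: FragmentAlignment, transcript: CircularTranscript, k: int = 3
) -> bool:
    """True iff every mapped segment fits the transcript's exon chain
    with matching splice boundaries, allowing wrap across the
    back-splice junction; terminal overhangs shorter than ``k`` bp are
    ignored."""
    return map_fragment(fragment, transcript, k) is not None


def implied_fragment_length(
    fragment: FragmentAlignment,
    transcript: CircularTranscript,
    k: int = 3,
    wrap: bool | None = None,
    layout: TranscriptLayout | None = None,
) -> int | None:
    """Implied length lt(f) of a fragment on a circular transcript.

    Measured from the 5' mate's start to the 3' mate's end along the
    circle.  When the 3' mate lies upstream of the 5' mate on the
    linearized circle the footprint wraps and one full transcript length
    is added; ``wrap=True`` forces an extra turn (used when external
    evidence shows the fragment wraps past its own start, which
    coordinates alone cannot reveal)."""
    layout = layout or TranscriptLayout(transcript)
    mapped = map_fragment(fragment, transcript, k, layout)
    if mapped is None:
        return None
    iv1, iv2 = mapped
    L = layout.length
    if iv1 is None or iv2 is None:
        iv = iv1 or iv2
        lt = iv[1] - iv[0]
        return lt + L if wrap else lt
    a1, b1 = iv1
    a2, b2 = iv2
    # unroll the 3' mate forward from the 5' mate's start
    while a2 < a1:
        a2 += L
        b2 += L
    lt = b2 - a1
    if b2 < b1:  # 3' mate nested before the 5' mate's end: must wrap
        lt += L
    if wrap:
        lt += L
    return lt


@dataclass
class EMResult:
    theta: np.ndarray
    expected_counts: np.ndarray
    loglik_trace: list[float]
    n_used_fragments: int
    n_excluded_fragments: int
    converged: bool = True


def _compat_weights(
    transcripts: list[CircularTranscript],
    fragments: list[FragmentAlignment],
    F: FragmentLengthModel,
    cfg: QuantConfig,
):
    """Sparse compatibility weights c_ft = F[lt(f)] / (l(t) - 2k + 2)."""
    layouts = [TranscriptLayout(t) for t in transcripts]
    denom = np.array(
        [max(selection_positions(t.length, cfg.k_effective), 1) for t in transcripts],
        dtype=float,
    )
    rows, cols, lts = [], [], []
    n_excluded = 0
    for fi, f in enumerate(fragments):
        hit = False
        for ti, (t, lay) in enumerate(zip(transcripts, layouts)):
            lt = implied_fragment_length(f, t, cfg.k_effective, layout=lay)
            if lt is not None:
                rows.append(fi)
                cols.append(ti)
                lts.append(lt)
                hit = True
        if not hit:
            n_excluded += 1
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    c = F.pdf(np.asarray(lts, dtype=float)) / denom[cols] if len(cols) else np.array([])
    return rows, cols, c, n_excluded


def em_estimate(
    transcripts: list[CircularTranscript],
    fragments: list[FragmentAlignment],
    F: FragmentLengthModel,
    cfg: QuantConfig | None = None,
) -> EMResult:
    """Maximum-likelihood abundances for one group of transcripts.

    EM runs on the fragment-origin simplex phi_t (proportional to
    theta_t * l(t)); the reported theta are mapped back by dividing by
    length and renormalizing.  The per-iteration log-likelihood is
    non-decreasing; expected counts sum to the number of usable
    fragments."""
    cfg = cfg or QuantConfig()
    T = len(transcripts)
    if T == 0:
        raise ValueError("no transcripts to quantify")
    rows, cols, c, n_excluded = _compat_weights(transcripts, fragments, F, cfg)

    # fragments whose every weight underflowed are unusable
    if len(rows):
        sums = np.zeros(len(fragments))
        np.add.at(sums, rows, c)
        usable = sums > 0.0
        keep = usable[rows]
        rows, cols, c = rows[keep], cols[keep], c[keep]
        frag_ids = np.unique(rows)
        remap = {old: new for new, old in enumerate(frag_ids)}
        rows = np.array([remap[r] for r in rows], dtype=np.intp)
        N = len(frag_ids)
        n_excluded = len(fragments) - N
    else:
        N = 0
        n_excluded = len(fragments)
    if N == 0:
        raise ValueError("no fragment is compatible with any transcript")

    phi = np.full(T, 1.0 / T)
    trace: list[float] = []
    converged = False
    for _ in range(cfg.max_em_iters):
        w = phi[cols] * c
        den = np.zeros(N)
        np.add.at(den, rows, w)
        ll = float(np.log(den).sum())
        gamma = w / den[rows]
        new_phi = np.zeros(T)
        np.add.at(new_phi, cols, gamma)
        new_phi /= N
        if trace and abs(ll - trace[-1]) <= cfg.loglik_tol * max(1.0, abs(ll)):
            trace.append(ll)
            phi = new_phi
            converged = True
            break
        trace.append(ll)
        phi = new_phi
    if not converged and cfg.max_em_iters > 1:
        log.warning("EM did not converge within %d iterations", cfg.max_em_iters)

    counts = np.zeros(T)
    w = phi[cols] * c
    den = np.zeros(N)
    np.add.at(den, rows, w)
    np.add.at(counts, cols, w / den[rows])

    lengths = np.array([t.length for t in transcripts], dtype=float)
    theta = phi / lengths
    theta /= theta.sum()
    for t, th, cnt in zip(transcripts, theta, counts):
        t.theta = float(th)
        t.expected_count = float(cnt)
    return EMResult(theta, counts, trace, N, n_excluded, converged)


def filter_low_abundance(
    transcripts: list[CircularTranscript], cfg: QuantConfig | None = None
) -> tuple[list[CircularTranscript], list[CircularTranscript]]:
    """Drop isoforms below ``filter_ratio`` (default 1/1000) of the most
    abundant isoform in the group and renormalize theta over survivors."""
    cfg = cfg or QuantConfig()
    if not transcripts:
        return [], []
    top = max(t.theta for t in transcripts)
    kept = [t for t in transcripts if t.theta >= cfg.filter_ratio * top]
    dropped = [t for t in transcripts if t.theta < cfg.filter_ratio * top]
    total = sum(t.theta for t in kept)
    if total > 0:
        for t in kept:
            t.theta /= total
    return kept, dropped


def quantify_group(
    transcripts: list[CircularTranscript],
    fragments: list[FragmentAlignment],
    F: FragmentLengthModel,
    cfg: QuantConfig | None = None,
) -> tuple[list[CircularTranscript], EMResult]:
    """EM, low-abundance filter, then one EM pass on the survivors."""
    cfg = cfg or QuantConfig()
    res = em_estimate(transcripts, fragments, F, cfg)
    kept, dropped = filter_low_abundance(transcripts, cfg)
    if dropped and kept:
        one_pass = QuantConfig(
            k_effective=cfg.k_effective,
            filter_ratio=cfg.filter_ratio,
            max_em_iters=1,
            loglik_tol=cfg.loglik_tol,
        )
        res = em_estimate(kept, fragments, F, one_pass)
    return kept, res


def estimate_fragment_length_model(
    groups: list[tuple[list[CircularTranscript], list[FragmentAlignment]]],
    k: int = 3,
    default: tuple[float, float] = (300.0, 50.0),
    min_fragments: int = 30,
) -> FragmentLengthModel:
    """Self-calibrate the fragment-length distribution from implied
    lengths in single-isoform groups, where lt(f) is unambiguous."""
    lts: list[int] = []
    for transcripts, fragments in groups:
        if len(transcripts) != 1:
            continue
        t = transcripts[0]
        lay = TranscriptLayout(t)
        for f in fragments:
            lt = implied_fragment_length(f, t, k, layout=lay)
            if lt is not None:
                lts.append(lt)
    if len(lts) < min_fragments:
        log.warning(
            "only %d fragments available for fragment-length calibration; "
            "using default mean=%.0f sd=%.0f", len(lts), *default,
        )
        return FragmentLengthModel(*default)
    arr = np.asarray(lts, dtype=float)
    sd = float(arr.std(ddof=1))
    return FragmentLengthModel(float(arr.mean()), max(sd, 1.0))


def compute_expression_metrics(
    transcripts: list[CircularTranscript],
    total_mapped_fragments: int,
    ri_map: dict | None = None,
) -> list[ExpressionRecord]:
    """FPKM, TPM and read counts from EM expected counts.

    FPKM_t = count_t / (l(t)/1e3) / (total/1e6);
    TPM_t  = 1e6 * (count_t/l(t)) / sum_u(count_u/l(u)).
    Raw transcript length is used throughout — circles have no edge
    effects, so no effective-length correction applies."""
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    dens = [t.expected_count / t.length for t in transcripts]
    dens_sum = sum(dens)
    records = []
    for t, d in zip(transcripts, dens):
        fpkm = t.expected_count / (t.length / 1e3) / (total_mapped_fragments / 1e6)
        tpm = 1e6 * d / dens_sum if dens_sum > 0 else 0.0
        records.append(
            ExpressionRecord(
                transcript_id=t.transcript_id,
                bsj=t.bsj,
                exon_chain=sorted(t.exon_chain),
                strand=t.strand,
                length=t.length,
                read_count=t.expected_count,
                fpkm=fpkm,
                tpm=tpm,
                gene_id=t.gene_id,
                relation_index=(ri_map or {}).get(t.bsj.key, 1),
            )
        )
    return records
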