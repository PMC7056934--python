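"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open intervals ``[start, end)``.
GTF and SAM inputs (1-based) are converted on read and converted back on
write; nothing outside the I/O layer ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


@dataclass(frozen=True)
class BackSpliceJunction:
    """One back-splice event: the downstream 5' donor joined to the
    upstream 3' acceptor, anchoring a circular RNA.

    ``start`` is the left boundary of the upstream acceptor exon and
    ``end`` the right boundary of the downstream donor exon, so the
    circle's genomic span is ``[start, end)``.
    """

    chromosome: str
    start: int
    end: int
    strand: str = "."
    support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"back-splice junction must have start < end, got "
                f"{self.chromosome}:{self.start}-{self.end}"
            )
        if self.support < 0:
            raise ValueError("support must be >= 0")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


@dataclass
class GeneLocus:
    """A gene with its deduplicated exon catalogue and annotated
    (linear) transcript structures."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval] = field(default_factory=list)  # sorted, unique
    transcripts: dict[str, list[int]] = field(default_factory=dict)  # tid -> exon indices

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], max(e for _, e in self.exons))

    def exon_starts(self) -> set[int]:
        return {s for s, _ in self.exons}

    def exon_ends(self) -> set[int]:
        return {e for _, e in self.exons}


@dataclass
class GeneAnnotation:
    genes: list[GeneLocus]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]


@dataclass
class FragmentAlignment:
    """One paired-end fragment's mapped footprint.

    Each mate is stored as a list of *chains*; a chain is the
    coordinate-sorted block list of one SAM record (blocks split at N
    gaps).  A mate usually has one chain; a read split at the back-splice
    junction contributes two chains to the same mate.  Splice-junction
    evidence is only ever extracted *within* a chain — the jump between
    two chains of a split mate is the circular junction itself.
    """

    fragment_id: str
    mate1_chains: list[list[Interval]] = field(default_factory=list)
    mate2_chains: list[list[Interval]] = field(default_factory=list)
    chromosome: str = ""
    is_bsj_spanning: bool = False

    @property
    def mate1_segments(self) -> list[Interval]:
        return sorted(seg for chain in self.mate1_chains for seg in chain)

    @property
    def mate2_segments(self) -> list[Interval]:
        return sorted(seg for chain in self.mate2_chains for seg in chain)

    def all_segments(self) -> list[Interval]:
        return sorted(
            seg
            for chains in (self.mate1_chains, self.mate2_chains)
            for chain in chains
            for seg in chain
        )

    @property
    def span(self) -> Interval:
        segs = self.all_segments()
        return (segs[0][0], max(e for _, e in segs))


@dataclass
class CircularTranscript:
    """An assembled circular isoform: an ordered exon chain from the
    back-spliced source exon to the back-spliced sink exon.

    ``exon_chain`` is in transcription (5'->3') order; on minus-strand
    loci this is descending genomic order.
    """

    transcript_id: str
    gene_id: str
    bsj: BackSpliceJunction
    exon_chain: list[Interval]
    strand: str = "+"
    theta: float = 0.0
    expected_count: float = 0.0

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exon_chain)

    @property
    def chain_key(self) -> tuple:
        return (self.bsj.chromosome, self.bsj.start, self.bsj.end,
                tuple(sorted(self.exon_chain)))


@dataclass
class ExpressionRecord:
    transcript_id: str
    bsj: BackSpliceJunction
    exon_chain: list[Interval]
    strand: str
    length: int
    read_count: float
    fpkm: float
    tpm: float
    gene_id: str = ""
    relation_index: int = 1

    def __post_init__(self) -> None:
        if self.fpkm < 0 or self.tpm < 0 or self.read_count < 0:
            raise ValueError("expression values must be non-negative")


def chain_to_str(chain: list[Interval]) -> str:
    """Serialize an exon chain as ``start-end,start-end`` in genomic order."""
    return ",".join(f"{s}-{e}" for s, e in sorted(chain))


def chain_from_str(text: str) -> list[Interval]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out
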