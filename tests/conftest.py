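import textwrap

import pytest

from circiso.core import BackSpliceJunction
from circiso.graph import ExonNode, SpliceGraph


@pytest.fixture
def tmp_gtf(tmp_path):
    """Write GTF text (dedented) to a temp file and return the path."""

    def _write(text: str, name: str = "anno.gtf"):
        p = tmp_path / name
        p.write_text(textwrap.dedent(text).lstrip())
        return p

    return _write


@pytest.fixture
def tmp_sam(tmp_path):
    """Write a SAM file with a minimal header and the given body lines."""

    def _write(lines: list[str], name: str = "aln.sam", chrom: str = "chr1",
               length: int = 1_000_000):
        p = tmp_path / name
        header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{chrom}\tLN:{length}\n"
        p.write_text(header + "".join(line + "\n" for line in lines))
        return p

    return _write


def make_graph(edges, n=None, source=0, sink=None, strand="+"):
    """Small splice graph on node indices with synthetic exon intervals."""
    if n is None:
        n = max(max(e) for e in edges) + 1 if edges else 1
    if sink is None:
        sink = n - 1
    nodes = [ExonNode((i * 1000, i * 1000 + 100), i) for i in range(n)]
    bsj = BackSpliceJunction("chr1", 0, n * 1000 + 100, strand)
    return SpliceGraph(bsj, strand, nodes, set(edges), source, sink)


def sam_line(qname, flag, pos, cigar, chrom="chr1", mpos=1, mapq=50):
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t=\t{mpos}\t0\t*\t*"
    )
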