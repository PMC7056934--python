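# File formats

Internally all coordinates are 0-based half-open; GTF and SAM (1-based)
are converted on read and write.

## Inputs

**Gene annotation (GTF).** Only `exon` features are used; each must
carry `gene_id` and `transcript_id` attributes. Exon intervals are
deduplicated per gene; alternative boundary variants of the same exon
are kept as distinct intervals.

**Alignments (SAM).** Paired-end records from a spliced aligner; CIGARs
may contain M/I/D/N/S operations and are split into genomic blocks at
every N gap. Secondary and supplementary records are ignored. A read
split at a back-splice junction may be represented as two primary
records sharing the query name and mate flag (as the bundled simulator
writes them); the reader merges them into one mate with two block
chains.

**Back-splice junction lists.** The dialect is chosen explicitly with
`--dialect` (columns are too ambiguous to sniff). One example line each:

* `circexplorer2` — BED-style, 0-based half-open, back-spliced read
  count in column 13:

  ```
  chr1	1000	2000	circ/7	0	+	1000	2000	0,0,0	1	1000	0	7
  ```

* `ciri2` — header line, 1-based inclusive coordinates, junction reads
  in column 5, strand in column 11:

  ```
  c1	chr1	1001	2000	7	MS	0	0.5	exon	geneA	+	ids
  ```

* `uroborus` — 1-based start, strand may be `.` (then resolved from the
  annotation), read count in column 6:

  ```
  chr1	1001	2000	+	geneA	7
  ```

## Outputs

**`<prefix>.gtf`** — one `exon` feature per exon of each assembled
circular transcript, with `gene_id`, `transcript_id`, `bsj_start`,
`bsj_end` attributes. Transcript IDs are `circGENE-j-i` (junction
ordinal `j` in genomic order within the locus, isoform ordinal `i`).

**`<prefix>.expression.tsv`** — columns `transcript_id, chrom,
bsj_start, bsj_end, strand, exon_chain, length, read_count, FPKM, TPM,
RI`.

**`<prefix>.manifest.json`** — per-stage diagnostic counts of the run.
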