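# Methods

## Model overview

`circiso` treats each back-splice junction (BSJ) as anchoring one
directed acyclic splice graph. Nodes are the annotated exon variants
lying fully inside the junction span `[start, end)`; the exon beginning
at the acceptor boundary is the source and the exon ending at the donor
boundary is the sink (roles swap on the minus strand, where node order
follows transcription rather than the genomic axis — all graph logic
operates on transcription-ordered node indices, giving one code path for
both strands). Edges are forward splice junctions witnessed by gapped
reads whose gap boundaries coincide with annotated splice sites. The
sink-to-source back-splice is implicit in circularity and never an edge.
Reads split at the junction are kept as separate block chains per SAM
record; junction evidence is extracted only within a chain, so the
circular jump can never masquerade as a forward splice.

Assumptions: circle boundaries coincide with annotated exon boundaries
(an optional ±2 bp tolerance absorbs off-by-one dialect errors);
isoforms differ by exon skipping or annotated boundary variants within
the span; fragments derive from mature (intron-free) circles.

## Assembly: extended minimum path cover

A feasible assembly is a set of source→sink paths covering all nodes
(a), all edges (b) and all evidence subpaths (c), with every path
running source→sink (d); the assembly is a minimum such set. Evidence
subpaths are runs of ≥3 nodes jointly witnessed by one fragment: runs
within one read chain are certain; the two mates' runs are joined across
the unsequenced inner gap only when the join is unambiguous — the
junction between the runs' end nodes must be an edge with no one-node
detour, otherwise the gap could hide a skipped exon and the runs are
kept separate. Length-2 runs are edge constraints, not subpaths.

Because a single circle rarely spans more than a dozen exons, the solver
enumerates all source→sink paths (cap 2000) and runs an
iterative-deepening exact search: starting from the combinatorial lower
bound `max_v max(indeg v, outdeg v)`, it branches on the uncovered
element with the fewest covering paths. The solution is provably minimal
for the enumerated path set and is validated in the test suite against
an independent brute-force subset enumerator on hundreds of random DAGs
of ≤10 nodes, with random satisfiable subpath constraints. Graphs
exceeding the path cap fall back to a documented deterministic greedy
cover (shortest-path pool through every element, largest-gain selection,
redundancy pruning); in the bundled simulations this path is never
taken. Determinism: paths are enumerated and selected in lexicographic
node-index order. Subpaths contained in no source→sink path are dropped
with a warning (inconsistent evidence); mutually unsatisfiable subpath
sets are relaxed by dropping the lowest-multiplicity subpath first,
multiplicity being evidence strength.

Exon variants with no overlapping read evidence are dropped before
solving (they cannot satisfy coverage); nodes that cannot lie on any
source→sink path are likewise pruned. If several exon variants share the
anchoring boundary, the variant with the most read evidence (ties:
longest) anchors the graph. A junction whose sink is unreachable from
its source — too few forward-spliced reads — is reported unassembled.

## Quantification

Fragments are assigned to isoforms by EM on

```
L(θ|R) = ∏_f Σ_t  [θ_t l(t) / Σ_α θ_α l(α)] · F[l_t(f)] / (l(t) − 2k + 2)
```

The first factor is the probability that a random fragment originates
from circle `t` (proportional to abundance × length); the second is the
probability of the observed implied length under the normal
fragment-length law `F`, over the `l(t) − 2k + 2` effective start
positions of the circle. EM runs on the fragment-origin simplex
`φ_t ∝ θ_t l(t)`; the reported `θ` divides out length and renormalizes.

* **Compatibility.** Every fragment block must fit the isoform's exon
  chain with flush splice boundaries; wrap across the back-splice
  junction is allowed. Terminal blocks shorter than `k` (default 3 bp)
  are trimmed before matching — sub-`k` overhangs carry no reliable
  junction information.
* **Implied length.** `l_t(f)` runs from the 5' mate's start to the 3'
  mate's end along the circle; the 3' mate is unrolled forward, adding
  one full `l(t)` when it lies upstream on the linearized circle or is
  nested before the 5' mate's end. A fragment wrapping a full extra turn
  is indistinguishable from its one-turn image by coordinates alone;
  the minimal unrolling is used (an explicit `wrap=True` override exists
  for callers with outside knowledge). With the default fragment law
  (mean 300 bp) and typical circle sizes the ambiguity is rare.
* **No effective-length correction.** Circles have no ends, hence no
  edge effects; raw `l(t)` is used everywhere.
* **Fragment-length law.** `F` is normal; mean and sd are
  self-calibrated from implied lengths in single-isoform loci (where
  `l_t(f)` is unambiguous), falling back to N(300, 50²) when fewer than
  30 such fragments exist. Both parameters can be overridden.
* **EM numerics.** Uniform initialization over a locus's isoforms (the
  log-likelihood is concave, so initialization affects only speed);
  convergence when the relative log-likelihood change is below 1e-6, cap
  1000 iterations; the per-iteration log-likelihood is asserted
  non-decreasing in the tests, and expected counts always sum to the
  number of usable fragments. Fragments compatible with no assembled
  isoform are excluded and reported as a diagnostic count.
* **Abundance filter.** Isoforms below 1/1000 of the most abundant
  isoform are dropped, θ is renormalized over the survivors, and one EM
  pass refreshes the counts. The filter group is the gene locus (the
  unit the assembler operates on); the alternative per-junction scope
  differs only for loci with several junctions of very unequal
  expression.

FPKM = count / (l/10³) / (total mapped fragments/10⁶);
TPM = 10⁶ · (count/l) / Σ(count/l).

## Relation index

Junction spans on the same chromosome that intersect by ≥1 bp (half
open; strand-agnostic by default, strand-aware by flag) are related;
transitive closure partitions the junction set, and a junction's RI is
its class size. Computed by a union-find sweep over start-sorted
intervals; the tests check it against an explicit quadratic
transitive-closure oracle. RI is a reported diagnostic only — it never
alters assembly.

## Synthetic data generator

The simulator emulates a back-splice-anchored simulation protocol: gene
loci (default 5–10 exons of 100–400 bp, introns 200–1500 bp, alternating
strands, 10 kb spacing) carry 1 or more BSJs; with probability
`overlap_fraction` a locus receives 2+ junctions that all span a shared
anchor exon, so their spans overlap and populate higher relation-index
classes. Circles span 2–6 exons (`circle_exons`), matching the typical
exonic circRNA size range of a few hundred bp to ~1.5 kb; exons between
the back-splice sites are randomly skipped to create up to
`isoforms_per_bsj` distinct isoforms per junction (the full chain is
always isoform 1, reflecting the dominance of all-exon circles).
Expression is log-uniform on [1, 1000] arbitrary units — a declared
stand-in for a biological expression range, not an inferred one; θ is
the within-locus share.

Fragments are multinomial across transcripts with probability ∝
expression × length; starts are uniform on the circle (any rotation),
lengths normal (default mean 300, sd 50) truncated to
[read length, l(t)]. Reads are emitted pre-aligned as SAM with exact
N-gap CIGARs; a read straddling the junction is split into two primary
records sharing query name and mate flag. Emitting alignments directly
removes any aligner dependency from the tests; optional FASTQ with
synthetic sequence is available. The junction list is written in the
CIRCexplorer2 dialect with support = realized junction-crossing
fragments.

Not emulated: sequencing errors or quality decay, alignment artifacts
(soft-clipping, multimapping), linear mRNA contamination, rolling-circle
concatemers, intronic/intergenic circles, GC or positional bias.
Passing tests therefore demonstrate correctness of the graph/cover/EM
machinery under clean alignments, not robustness to noisy real-world
mapping.

## Simulation studies and their sizes

The bundled studies (driven by `scripts/acceptance.py` and the
acceptance tests) are desk-scale versions of the reference protocol:

* **Assembly accuracy**: 200 loci (~350–650 truth isoforms across
  seeds), 110k fragment pairs of 100 bp — about 250 pairs per isoform,
  the median of a 7-step depth ladder; scored by exact exon-chain
  matching. The same protocol at 8× pairs probes precision at depth.
* **Relative quantification**: 4 loci with 2–3 isoforms each, expression
  redrawn over 8 conditions at 20k pairs each; per isoform, the Pearson
  correlation between theoretical abundance (expected fragment count:
  expression × length / transcriptome total × depth) and EM-assigned
  read counts across conditions. Correlating against raw expression
  alone is confounded in a 4-locus miniature by the strongly varying
  normalizing total; on the count scale EM assignment tracks truth at
  r ≥ 0.99.
* **RI stratification**: 150 loci with `overlap_fraction` 0.6 and 2–4
  junctions per clustered locus, 460k pairs, so RI classes 1–4 each hold
  ≥30 junctions; sensitivity is pooled over RI ≤ 4.

Simulation runs set the junction support filter to 1 — the simulated
junction list plays the role of the upstream detector's output. The
real-data default is 10 supporting back-spliced reads.

Sensitivity in these studies is computed over truth isoforms with at
least one emitted fragment; an isoform that left no evidence cannot be
assembled by any method and would only measure the expression
distribution, not the assembler.

## Known limitations

* Only annotated exons participate: unannotated exons, intronic and
  intergenic circles are out of reach by construction.
* Exact minimality is guaranteed only for the enumerated-path regime;
  pathological graphs beyond the cap get a greedy heuristic.
* When several boundary-variant exons share the junction boundary, a
  single variant is chosen as source/sink; isoforms mixing both variants
  of the anchor exon are not separated.
* The double-wrap ambiguity in implied fragment length is resolved
  minimally, slightly biasing `F` for circles shorter than the fragment
  length.
* Multi-sample joint quantification, bias correction and differential
  expression are out of scope.
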