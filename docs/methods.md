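# Methods

## Problem and model

Genome-guided transcriptome assembly reconstructs the set of expressed
transcript isoforms of each gene from spliced short-read alignments.
`isoweave` additionally *borrows* evidence from the transcript assemblies
of two or more upstream assemblers (e.g. StringTie-like, Scallop-like,
Cufflinks-like tools run on the same alignments): where several
independent assemblers agree on a stretch of transcript structure, that
stretch is treated as trustworthy and used to steer the assembly.

The pipeline runs in five stages.

### 1. Splicing graphs

Read alignments are converted to genomic block chains (CIGAR `M/=/X/D`
extend a block, `N` splits, `I/S/H/P` consume no reference), mates are
paired by name, and fragment pairs are clustered into loci by
single-linkage proximity (gap ≤ `max_locus_gap`, default 50 bp; strands
kept apart when known, unknown-strand fragments join either). Per locus a
weighted DAG *G* is built: the locus is cut at every junction boundary
spelled by spliced reads, maximal read-covered runs between cuts become
exon-segment nodes, and edges are splice junctions (weight = number of
reads spelling the intron) or adjacencies between abutting segments
(weight = number of reads crossing the boundary). Adjacency edges are
first-class so alternative transcript ends and retained introns are
representable as paths. When a junction boundary and a coverage boundary
coincide, the junction wins — boundaries from spliced reads are
authoritative. Transcript assembly is then the search for an edge-path
cover of *G*.

### 2. Paired subpaths

A read pair whose mates span node paths *P₁* (length *p*) and *P₂*
(length *q*) is connected through the paths from the end of *P₁* to the
start of *P₂*: if exactly one connecting path exists (with *s* interior
nodes) and *p + s + q ≥ 3*, the pair spells the paired subpath
*P₁ → interior → P₂*. Overlapping mates merge directly under the same
length rule; zero or several connectors mean the pair is uninformative.
Connector enumeration is capped (64 paths / depth 32); hitting the cap
counts as ambiguous. Identical subpaths aggregate, their count being the
subpath's coverage. Every length-*k* window (*k* = 2 … longest) of every
paired subpath is a paired *k*-subpath whose coverage sums over all
containing subpaths; windows with coverage ≥ 2 are **reliable**. The
canonical decomposition starts at *k* = 3; we also produce 2-subpaths by
the same window/threshold scheme because the extension rule consults
length-2 witnesses (configurable via `min_k`).

### 3. Colored graphs

Transcripts parsed from each assembler's GTF are clustered into loci by
exonic overlap; per locus, exons with identical coordinates collapse into
nodes of the colored graph *G꜀* and each transcript becomes a path
labelled by its assembler ("color"). Windows of these paths are assembly
*k*-subpaths; a window's **depth** is the number of *distinct* colors
whose paths contain it (two predictions from one tool corroborate
nothing), and depth ≥ 2 makes it reliable. Exon identity is exact by
default; `boundary_slack` > 0 first snaps boundaries within that many bp
to the locally most frequent coordinate, a pragmatic answer to assemblers
that disagree slightly on terminal exon ends.

### 4. Anchoring and merging evidence

A hash index maps every splicing-graph junction (chromosome, strand,
donor, acceptor) to its graph and edge. An assembly subpath anchors to a
splicing graph when all of its junctions hit the index in the same graph
and the induced edge sequence is connected there (colored exons spanning
several segments are bridged with adjacency edges; terminal exons extend
through adjacencies only while staying inside the exon interval).
Subpaths whose junctions never entered *G* — unseen in the reads — are
dropped and counted. Mono-exon transcripts, which carry no junction,
match single-node graphs by ≥ 50 % reciprocal overlap instead.

Read- and assembly-derived reliable sets are merged per graph. Coverage
(read pairs) and depth (assemblers) are incommensurable, so scores are
first replaced by normalized rank positions within each length class;
duplicated node sequences keep one copy tagged `merged` with the larger
normalized score. Seeding later uses only length, provenance preference
(assembly before read at equal length — it aggregates more evidence) and
score, so the exact normalization matters little.

### 5. Line graph, connection program, path extension

The line graph *L(G)* has a node per edge of *G* (weight = that edge's
coverage) and an edge per incident pair. At each branching node of *G*
with in-weights *wᵢ* and out-weights *wⱼ* we solve

    min  Σᵢ (Σⱼ f_ij − wᵢ)² + Σⱼ (Σᵢ f_ij − wⱼ)²
    s.t. f_ij ≥ 0,  and  f_ij ≥ ε·min(wᵢ, wⱼ) for pairs (i, j) witnessed
         by a reliable 3-subpath through the node (ε = 0.05),

by non-negative least squares after shifting out the lower bounds. NNLS's
active-set pivoting is deterministic for our fixed row-major variable
order, so output is bit-reproducible. An L-edge is kept (weight 1) when
its flow reaches θ·(node's maximum flow) with θ = 0.1, when it carries
its in-edge's largest positive flow, or when the pair is witnessed;
non-branching incidences are always 1. The row-argmax clause is ours: a
pure node-max threshold can strand an expressed low-coverage in-edge with
no weight-1 continuation, breaking the cover guarantee; the only L-nodes
left exit-less are those whose entire flow row is exactly zero.

Assembly then repeats: **seed** the longest reliable subpath (projected
onto *L*: a length-*n* *G*-path is the unique length-(*n*−1) *L*-path)
not yet contained in a predicted path — ties broken assembly-first, then
score, then lexicographically — or, when all are covered, the unused
L-node with the largest weight; **extend** both ways, preferring weight-1
edges (falling back to all neighbors rather than truncating, so no
downstream node is stranded; `--strict-binary` stops instead), filtering
multiple candidates by reliable 2-, then 3-, then longer witness subpaths
matching the current path's suffix/prefix, then by largest current node
weight, then lexicographically; **commit**: the path's minimum node
weight c_min is recorded as its abundance proxy and subtracted from every
on-path node. The loop ends when every reliable subpath and every L-node
is covered; each round covers at least one new subpath or node, so
termination is guaranteed (an iteration cap of 10·|L| guards against
regressions). Isolated *G*-nodes become mono-exon transcripts with c_min
= mean base coverage. Paths with c_min < `min_cov` (default 1.5) are
dropped — the post-assembly expression filter that trades precision
against sensitivity — and surviving paths are written as GTF (1-based
inclusive; abutting segments merged into exons; `cov` attribute carries
c_min).

## Parameters

| name | default | unit | role |
|---|---|---|---|
| `min_mapq` | 1 | phred | drop sub-quality alignments |
| `max_locus_gap` | 50 | bp | locus clustering linkage distance |
| `min_junction_reads` | 1 | reads | junction support threshold |
| coverage threshold | 2 | read pairs | reliable paired subpath |
| depth threshold | 2 | assemblers | reliable assembly subpath |
| `eps_support` | 0.05 | fraction | witnessed-pair flow floor |
| `theta` | 0.1 | fraction | L-edge binarization threshold |
| `min_cov` | 1.5 | coverage | expression filter on c_min |
| `boundary_slack` | 0 | bp | exon-boundary snapping in G꜀ |

All are CLI-configurable. The connection program is deliberately isolated
behind one function (`solve_connection_qp`) so an alternative formulation
can replace it without touching the rest of the pipeline.

## Synthetic data

The generator emulates a spliced aligner's output and upstream assembler
GTFs for a small gene panel. Its defaults (`default_spec`) are the test
conditions: three genes on one toy chromosome — a 5-exon gene with three
isoforms whose phasings only paired-end or assembly evidence can
disambiguate, a 3-exon skipped-exon gene whose minor isoform is invisible
to paired subpaths (mate merges are too short) and must be borrowed from
the assemblies, and a mono-exon gene; 75 bp paired reads, 250 ± 25 bp
fragments, 120–200 fragments per isoform (the depth a moderately
expressed gene receives in a real library, keeping junction support and
the residual c_min of minor isoforms clear of the thresholds). Mock
assembler profiles control a true-positive rate, a spurious
exon-recombination rate, and terminal-boundary jitter. Fragment sampling
draws from one NumPy generator seeded with `spec.seed`; GTF generation
uses its own stream (`seed + 1`), so each output is independently
byte-reproducible.

What the generator does *not* emulate: base-level sequencing errors,
mapping ambiguity, coverage bias (GC, positional), intra-assembler
boundary noise on internal exons, or anti-sense transcription. Passing
tests therefore demonstrate the graph algorithms and evidence logic, not
robustness to alignment artifacts on real libraries.

## Numerical choices

- Flows below 1e−9 (absolute) count as zero; flow-sanity checks use 1e−6.
- Ties everywhere break lexicographically by node index so output is
  bit-reproducible; within reliable-set classes, by score descending then
  lexicographic.
- Degenerate all-zero-weight branching nodes get uniform flow over
  witnessed pairs (over all pairs if none).
- Duplicate alignments of one mate keep the highest summed MAPQ pairing.

## Known limitations

- Short-read only; no chimeric/fusion paths; loci are assembled
  independently.
- Assembler junctions absent from the read-derived graph are dropped, not
  rescued: evidence can only select among read-supported structures.
- c_min is a residual, not an expression estimate: once a dominant
  isoform is committed, shared edges retain only the remainder, so minor
  isoforms of low-coverage genes can fall under `min_cov`. Lowering
  `--min-cov` trades precision for sensitivity.
- The connection program is a concrete reconstruction of the balance
  QP's published intent (its exact printed form is not reproduced here);
  it is isolated so a different formulation can be swapped in.
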