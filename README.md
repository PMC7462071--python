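# isoweave

Genome-guided transcriptome assembly that **borrows** evidence from the
transcript assemblies of several upstream assemblers.

Different genome-guided assemblers (StringTie, Scallop, Cufflinks, …)
make different mistakes on the same RNA-seq library; structure that two
or more of them agree on is far more trustworthy than any single
prediction. `isoweave` merges per-assembler GTFs into a per-locus
**colored graph** G꜀ (nodes = exons, each transcript a path labelled by
its assembler), extracts *reliable assembly subpaths* — path windows seen
by ≥ 2 distinct assemblers — and combines them with *reliable paired
subpaths* — read-pair-phased windows of the read-derived **splicing
graph** G with coverage ≥ 2. Both evidence kinds then seed a greedy path
extension over the weighted **line graph** L(G) (nodes = edges of G,
weighted by junction coverage; edges binarized to 0/1 connection
indicators by a small non-negative least-squares balance program at every
branching node). Each round seeds the longest uncovered reliable subpath,
extends it both ways under a fixed preference hierarchy (weight-1 edges →
witness subpaths of increasing length → largest node weight →
lexicographic), commits the path with its minimum node weight c_min as
abundance proxy, and subtracts c_min along the path. The loop ends when
every reliable subpath and every L-node is covered — a
transcript-representing path cover — and paths with c_min below an
expression threshold are filtered before GTF output.

It is aimed at transcriptomics practitioners who already run several
assemblers on bulk or single-cell short-read libraries and want a
principled consensus that can still recover isoforms no single input
assembler reported. See `docs/methods.md` for the full model,
parameters, and limitations.

## Worked example

The package ships a deterministic synthetic-data generator (a toy
chromosome with three multi-isoform genes, spliced read pairs, and three
mock assembler GTFs), so a complete run needs no external data:

```sh
python -c "from isoweave import default_spec, write_fixture; \
           write_fixture(default_spec(seed=7), 'demo')"
isoweave assemble --bam demo/reads.sam \
    --assemblies demo/asmA.gtf,demo/asmB.gtf,demo/asmC.gtf \
    --colors asmA,asmB,asmC --out demo/out.gtf
```

which logs

```
INFO isoweave.pipeline: graph 0 (chrT:1003-3500): 3 paths, 3 kept
INFO isoweave.pipeline: graph 1 (chrT:10003-11796): 2 paths, 2 kept
INFO isoweave.pipeline: graph 2 (chrT:20005-20881): 1 paths, 1 kept
loci=3 graphs=3 paired_subpaths=7 assembly_subpaths_mapped=21 transcripts=6 filtered=0
```

— three gene loci were found, the 5-exon gene yielded its three isoforms,
the skipped-exon gene both of its (the minor one is invisible to
paired-end evidence alone and is recovered from the borrowed assemblies),
and the mono-exon gene one. `demo/out.gtf` starts with

```
chrT  isoweave  transcript  1004  3500  33.000  +  .  gene_id "ISOW.1"; transcript_id "ISOW.1.1"; cov "33.000";
chrT  isoweave  exon        1004  1300  33.000  +  .  gene_id "ISOW.1"; transcript_id "ISOW.1.1"; cov "33.000"; exon_number "1";
```

where `cov` is the transcript's abundance proxy c_min (the minimum
line-graph node weight along its path at commit time). All six emitted
intron chains match the generator's truth table exactly.

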