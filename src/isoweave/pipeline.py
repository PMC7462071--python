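"""End-to-end orchestration: alignments + assembler GTFs -> transcript GTF.

The stages run in method order: ingest and cluster alignments, build one
splicing graph per locus, extract reliable paired subpaths per graph,
build colored graphs from the merged assemblies and extract reliable
assembly subpaths, anchor those onto the splicing graphs through the
junction index, merge the two evidence sets, weight and binarize each
line graph, then seed-and-extend a transcript-representing path cover
and write the surviving paths as GTF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import (
    alignment,
    colored_graph as cg,
    line_graph as lg,
    paired_subpaths as ps,
    path_extension as px,
    splice_graph as sg,
    subpath_mapping as sm,
)
from .paired_subpaths import ReliableSubpathSet, ScoredPath

log = logging.getLogger(__name__)


@dataclass
class AssemblyStats:
    loci: int = 0
    graphs: int = 0
    paired_subpaths: int = 0
    assembly_subpaths: int = 0
    assembly_subpaths_mapped: int = 0
    paths_emitted: int = 0
    paths_filtered: int = 0


@dataclass
class AssemblyResult:
    gtf_lines: list[str] = field(default_factory=list)
    transcripts: list[tuple[sg.SplicingGraph, px.TranscriptPath]] = field(
        default_factory=list
    )
    stats: AssemblyStats = field(default_factory=AssemblyStats)

    def intron_chains(self) -> set[tuple[tuple[int, int], ...]]:
        """Intron chains of emitted multi-exon transcripts."""
        return {
            t.intron_chain()
            for _, t in self.transcripts
            if len(t.exon_chain) > 1
        }


def assemble(
    bam: str | Path,
    assemblies: Sequence[str | Path],
    colors: Optional[Sequence[str]] = None,
    out_gtf: Optional[str | Path] = None,
    *,
    min_mapq: int = 1,
    max_locus_gap: int = 50,
    min_junction_reads: int = 1,
    theta: float = lg.THETA,
    eps_support: float = lg.EPS_SUPPORT,
    min_cov: float = px.MIN_COV_DEFAULT,
    boundary_slack: int = 0,
    strict_binary: bool = False,
    fasta=None,
) -> AssemblyResult:
    """Run the full assembly and optionally write the output GTF."""
    if len(assemblies) < 2:
        raise ValueError("at least two assembler GTFs are required")
    if colors is None:
        colors = [f"assembler{i + 1}" for i in range(len(assemblies))]

    result = AssemblyResult()

    # 1. reads -> loci -> splicing graphs
    frags = alignment.load_alignments(str(bam), min_mapq=min_mapq, fasta=fasta)
    pairs = alignment.pair_mates(frags)
    loci = alignment.cluster_loci(pairs, max_gap=max_locus_gap)
    result.stats.loci = len(loci)
    graphs: list[sg.SplicingGraph] = []
    graph_locus: list[alignment.Locus] = []
    for locus in loci:
        graph = sg.build_locus_graph(
            locus, min_junction_reads=min_junction_reads, graph_id=len(graphs)
        )
        if graph.nodes:
            graphs.append(graph)
            graph_locus.append(locus)
    result.stats.graphs = len(graphs)

    # 2. reliable paired subpaths per graph
    paired_sets: dict[int, ReliableSubpathSet] = {}
    for graph, locus in zip(graphs, graph_locus):
        subpaths = ps.collect_paired_subpaths(locus.fragments, graph)
        result.stats.paired_subpaths += len(subpaths)
        paired_sets[graph.graph_id] = ps.decompose_reliable(subpaths)

    # 3. colored graphs over merged assemblies -> reliable assembly subpaths
    transcripts = list(cg.parse_assemblies([str(p) for p in assemblies], list(colors)))
    index = sm.build_junction_index(graphs)
    assembly_sets: dict[int, dict[int, dict[tuple, ScoredPath]]] = {}
    for cluster in cg.cluster_merged_transcripts(transcripts):
        colored = cg.build_colored_graph(cluster, boundary_slack=boundary_slack)
        reliable = cg.extract_reliable_assembly_subpaths(colored)
        result.stats.assembly_subpaths += sum(
            len(v) for v in reliable.by_length.values()
        )
        mapped = sm.map_reliable_assembly_set(reliable, colored, index, graphs)
        for gid, rset in mapped.items():
            acc = assembly_sets.setdefault(gid, {})
            for k, entries in rset.by_length.items():
                bucket = acc.setdefault(k, {})
                for e in entries:
                    old = bucket.get(e.nodes)
                    if old is None or e.score > old.score:
                        bucket[e.nodes] = e

    # 4. per graph: merge evidence, weight line graph, extend, emit
    for graph in graphs:
        aset = ReliableSubpathSet(provenance=ps.ASSEMBLY_DERIVED)
        for k, bucket in assembly_sets.get(graph.graph_id, {}).items():
            aset.by_length[k] = sorted(
                bucket.values(), key=lambda e: (-e.score, e.nodes)
            )
            result.stats.assembly_subpaths_mapped += len(aset.by_length[k])
        merged = sm.merge_reliable(
            paired_sets.get(graph.graph_id, ReliableSubpathSet()), aset
        )
        line = lg.weight_line_graph(
            graph, merged, theta=theta, eps_support=eps_support
        )
        paths = px.assemble_graph(line, merged, strict_binary=strict_binary)
        kept = [t for t in paths if t.c_min >= min_cov]
        result.stats.paths_emitted += len(kept)
        result.stats.paths_filtered += len(paths) - len(kept)
        result.transcripts.extend((graph, t) for t in kept)
        result.gtf_lines.extend(px.paths_to_gtf(paths, graph, min_cov=min_cov))
        log.info(
            "graph %d (%s:%d-%d): %d paths, %d kept",
            graph.graph_id, graph.chrom, graph.span[0], graph.span[1],
            len(paths), len(kept),
        )

    if out_gtf is not None:
        Path(out_gtf).write_text("\n".join(result.gtf_lines) + "\n")
    return result
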