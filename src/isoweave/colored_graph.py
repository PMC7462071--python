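"""Colored graphs: consensus over transcript assemblies from several tools.

Transcripts from two or more assembler GTFs are merged per locus into a
graph whose nodes are exons and whose edges are the junctions/adjacencies
appearing in any merged transcript.  Each transcript is a colored path
(color = assembler).  Windows of those paths seen by >= 2 distinct
assemblers are "reliable assembly subpaths" — the borrowed evidence that
later seeds assembly.  Depth counts distinct assemblers, not transcripts:
two isoform predictions from one tool corroborate nothing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils

from .paired_subpaths import ASSEMBLY_DERIVED, ReliableSubpathSet, ScoredPath

log = logging.getLogger(__name__)


@dataclass
class ColoredTranscript:
    color: str
    chrom: str
    strand: str
    exon_chain: tuple[tuple[int, int], ...]  # 0-based half-open, sorted
    transcript_id: str

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_chain[0][0], self.exon_chain[-1][1]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exon_chain[i][1], self.exon_chain[i + 1][0])
            for i in range(len(self.exon_chain) - 1)
        )


@dataclass
class ColoredGraph:
    """Exon/junction graph over one locus of merged transcripts."""

    chrom: str
    strand: str
    nodes: list[tuple[int, int]]  # unique exon intervals, sorted
    edges: set[tuple[int, int]]   # consecutive-exon links over all paths
    paths: list[tuple[str, tuple[int, ...], str]] = field(default_factory=list)
    # (color, node path, transcript_id)


def parse_assemblies(
    gtf_paths: list[str], colors: list[str]
) -> Iterator[ColoredTranscript]:
    """Read exon features from each assembler's GTF, one color per file.

    Coordinates convert from GTF's 1-based inclusive to internal 0-based
    half-open.  Exons arriving out of order are sorted; transcripts lacking
    a transcript_id are skipped with a warning; a file contributing no exon
    features at all is an error.
    """
    if len(gtf_paths) != len(colors):
        raise ValueError("one color per GTF file required")
    for path, color in zip(gtf_paths, colors):
        chains: dict[str, dict] = {}
        order: list[str] = []
        n_exons = 0
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                feat = gffutils.feature.feature_from_line(line.rstrip("\n"))
                if feat.featuretype != "exon":
                    continue
                n_exons += 1
                try:
                    tid = feat.attributes["transcript_id"][0]
                except KeyError:
                    log.warning("%s: exon without transcript_id skipped", path)
                    continue
                rec = chains.get(tid)
                if rec is None:
                    rec = {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
                    chains[tid] = rec
                    order.append(tid)
                rec["exons"].append((feat.start - 1, feat.end))
        if n_exons == 0:
            raise ValueError(f"{path}: no exon features found")
        for tid in order:
            rec = chains[tid]
            yield ColoredTranscript(
                color=color,
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in "+-" else ".",
                exon_chain=tuple(sorted(rec["exons"])),
                transcript_id=tid,
            )


def cluster_merged_transcripts(
    transcripts: Iterable[ColoredTranscript],
) -> list[list[ColoredTranscript]]:
    """Single-linkage clustering by exonic overlap on the same chrom+strand."""
    groups: dict[tuple[str, str], list[ColoredTranscript]] = {}
    for t in transcripts:
        groups.setdefault((t.chrom, t.strand), []).append(t)

    loci: list[list[ColoredTranscript]] = []
    for key in sorted(groups):
        members = groups[key]
        # sweep over all exons; transcripts whose exons overlap transitively
        # share a cluster
        events = sorted(
            (s, e, i) for i, t in enumerate(members) for s, e in t.exon_chain
        )
        cluster_of = {}
        cur_cluster, cur_end = -1, -1
        for s, e, i in events:
            if s >= cur_end:  # half-open: touching exons do not overlap
                cur_cluster += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
            # a transcript spans all clusters its exons land in; union them
            cluster_of.setdefault(i, set()).add(cur_cluster)
        # union-find over clusters linked by a shared transcript
        parent = list(range(cur_cluster + 1))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for cset in cluster_of.values():
            cs = sorted(cset)
            for a, b in zip(cs, cs[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
        by_root: dict[int, list[ColoredTranscript]] = {}
        for i, t in enumerate(members):
            root = find(min(cluster_of[i]))
            by_root.setdefault(root, []).append(t)
        for root in sorted(by_root):
            locus = by_root[root]
            locus.sort(key=lambda t: (t.span, t.color, t.transcript_id))
            loci.append(locus)
    loci.sort(key=lambda l: (l[0].chrom, l[0].strand, l[0].span))
    return loci


def _snap_boundaries(
    transcripts: list[ColoredTranscript], slack: int
) -> list[ColoredTranscript]:
    """Snap exon boundaries within ``slack`` bp to the majority coordinate."""
    if slack <= 0:
        return transcripts
    coords = Counter(
        c for t in transcripts for exon in t.exon_chain for c in exon
    )
    snap: dict[int, int] = {}
    group: list[int] = []
    for c in sorted(coords):
        if group and c - group[-1] > slack:
            rep = max(group, key=lambda x: (coords[x], -x))
            snap.update({g: rep for g in group})
            group = []
        group.append(c)
    if group:
        rep = max(group, key=lambda x: (coords[x], -x))
        snap.update({g: rep for g in group})
    out = []
    for t in transcripts:
        chain = tuple(
            (snap[s], snap[e]) for s, e in t.exon_chain if snap[s] < snap[e]
        )
        out.append(
            ColoredTranscript(t.color, t.chrom, t.strand, chain, t.transcript_id)
        )
    return out


def build_colored_graph(
    transcripts: list[ColoredTranscript], boundary_slack: int = 0
) -> ColoredGraph:
    """Collapse identical exon intervals to nodes; transcripts become paths.

    Exon-node identity is exact (start, end) equality unless
    ``boundary_slack`` > 0, in which case boundaries within that many bp
    are first snapped to the locally most frequent coordinate.
    """
    transcripts = _snap_boundaries(transcripts, boundary_slack)
    exons = sorted({exon for t in transcripts for exon in t.exon_chain})
    index = {exon: i for i, exon in enumerate(exons)}
    edges: set[tuple[int, int]] = set()
    paths: list[tuple[str, tuple[int, ...], str]] = []
    for t in transcripts:
        node_path = tuple(index[exon] for exon in t.exon_chain)
        paths.append((t.color, node_path, t.transcript_id))
        edges.update(zip(node_path, node_path[1:]))
    return ColoredGraph(
        chrom=transcripts[0].chrom,
        strand=transcripts[0].strand,
        nodes=exons,
        edges=edges,
        paths=paths,
    )


def extract_reliable_assembly_subpaths(
    graph: ColoredGraph, min_depth: int = 2, min_k: int = 2
) -> ReliableSubpathSet:
    """Window decomposition of transcript paths, scored by assembler depth.

    The depth of a k-window is the number of DISTINCT colors whose paths
    contain it; windows with depth >= ``min_depth`` are reliable.  Sorted
    per length class by depth descending, ties lexicographically.
    """
    window_colors: dict[int, dict[tuple[int, ...], set[str]]] = {}
    for color, nodes, _tid in graph.paths:
        n = len(nodes)
        for k in range(min_k, n + 1):
            bucket = window_colors.setdefault(k, {})
            for i in range(n - k + 1):
                w = nodes[i : i + k]
                bucket.setdefault(w, set()).add(color)
    out = ReliableSubpathSet(provenance=ASSEMBLY_DERIVED)
    for k, bucket in window_colors.items():
        entries = [
            ScoredPath(nodes=w, score=float(len(cols)), provenance=ASSEMBLY_DERIVED)
            for w, cols in bucket.items()
            if len(cols) >= min_depth
        ]
        entries.sort(key=lambda e: (-e.score, e.nodes))
        if entries:
            out.by_length[k] = entries
    return out
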