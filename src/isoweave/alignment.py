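"""Ingest spliced paired-end alignments and cluster them into gene loci.

Alignment records are converted to chains of genomic blocks (0-based,
half-open); mates are paired by query name; pairs are clustered into loci by
single-linkage proximity.  Coordinates stay 0-based half-open everywhere
inside the package; GTF I/O converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

log = logging.getLogger(__name__)

#: strand values used throughout the package
FWD, REV, UNKNOWN = "+", "-", "."

# CIGAR operation codes (pysam numeric encoding)
_REF_EXTEND = {0, 2, 7, 8}  # M, D, =, X extend the current block
_REF_SKIP = 3               # N closes the block (intron)
_NO_REF = {1, 4, 5, 6}      # I, S, H, P consume no reference


@dataclass
class AlignedFragment:
    """One aligned mate as a chain of genomic blocks.

    ``blocks`` are sorted, non-overlapping, strictly increasing intervals;
    gaps between consecutive blocks are the introns spelled by N operations.
    """

    query_name: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    mapq: int = 0
    is_first_mate: bool = True
    mate_of: Optional["AlignedFragment"] = None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive blocks: the introns this mate spells."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


@dataclass
class Locus:
    """A cluster of fragment pairs on one chromosome (and strand, if known)."""

    chrom: str
    strand: str
    span: tuple[int, int]
    fragments: list[tuple[AlignedFragment, Optional[AlignedFragment]]] = field(
        default_factory=list
    )

    def mates(self) -> Iterator[AlignedFragment]:
        """Every individual mate in the locus (singletons included once)."""
        for left, right in self.fragments:
            yield left
            if right is not None:
                yield right


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in _REF_EXTEND:
            cur += length
        elif op == _REF_SKIP:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur_start = cur = cur + length
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def _infer_motif_strand(chrom: str, introns, fasta) -> str:
    """GT-AG spells a forward intron, CT-AC a reverse one."""
    votes = {FWD: 0, REV: 0}
    for donor, acceptor in introns:
        motif = (
            str(fasta[chrom][donor:donor + 2]).upper()
            + str(fasta[chrom][acceptor - 2:acceptor]).upper()
        )
        if motif == "GTAG":
            votes[FWD] += 1
        elif motif == "CTAC":
            votes[REV] += 1
    if votes[FWD] > votes[REV]:
        return FWD
    if votes[REV] > votes[FWD]:
        return REV
    return UNKNOWN


def load_alignments(
    path: str,
    min_mapq: int = 1,
    fasta=None,
) -> Iterator[AlignedFragment]:
    """Stream usable alignments from a coordinate-sorted SAM/BAM file.

    Unmapped, secondary, supplementary and sub-``min_mapq`` records are
    dropped.  Strand comes from the aligner's splice-strand tag (XS) when
    present, else from GT-AG/CT-AC intron motifs if ``fasta`` (a pyfaidx
    Fasta or similar mapping) is supplied, else unknown.

    Raises ``ValueError`` for a missing header or input not sorted by
    coordinate.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        header = af.header.to_dict()
        if not header.get("SQ"):
            raise ValueError(f"{path}: missing or empty SAM header")
        so = header.get("HD", {}).get("SO", "unknown")
        if so != "coordinate":
            raise ValueError(f"{path}: input must be coordinate-sorted (SO={so})")
        last = (-1, -1)
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            key = (rec.reference_id, rec.reference_start)
            if key < last:
                raise ValueError(f"{path}: records out of coordinate order")
            last = key
            if rec.cigartuples is None:
                log.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            try:
                blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples)
            except ValueError as exc:
                log.warning("record %s: %s; skipped", rec.query_name, exc)
                continue
            if not blocks:
                continue
            strand = UNKNOWN
            if rec.has_tag("XS"):
                strand = rec.get_tag("XS")
            elif fasta is not None and len(blocks) > 1:
                introns = [
                    (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
                ]
                strand = _infer_motif_strand(rec.reference_name, introns, fasta)
            yield AlignedFragment(
                query_name=rec.query_name,
                chrom=rec.reference_name,
                strand=strand,
                blocks=blocks,
                mapq=rec.mapping_quality,
                is_first_mate=not rec.is_read2,
            )


def pair_mates(
    fragments: Iterable[AlignedFragment],
) -> list[tuple[AlignedFragment, Optional[AlignedFragment]]]:
    """Pair mates by query name; unpaired fragments become singletons.

    Mates on different chromosomes degrade to two singletons.  When more
    than one alignment of a mate survived upstream filters, the pairing
    with the highest summed MAPQ wins.  Each emitted pair is ordered so the
    left mate starts no later than the right mate.
    """
    by_name: dict[str, list[AlignedFragment]] = {}
    order: list[str] = []
    for frag in fragments:
        if frag.query_name not in by_name:
            order.append(frag.query_name)
        by_name.setdefault(frag.query_name, []).append(frag)

    out: list[tuple[AlignedFragment, Optional[AlignedFragment]]] = []
    for name in order:
        group = by_name[name]
        firsts = [f for f in group if f.is_first_mate]
        seconds = [f for f in group if not f.is_first_mate]
        if len(firsts) > 1 or len(seconds) > 1:
            log.warning("query %s has duplicate alignments; keeping best pair", name)
        best: Optional[tuple[AlignedFragment, AlignedFragment]] = None
        for f1 in firsts:
            for f2 in seconds:
                if f1.chrom != f2.chrom:
                    continue
                if best is None or f1.mapq + f2.mapq > best[0].mapq + best[1].mapq:
                    best = (f1, f2)
        if best is not None:
            left, right = sorted(best, key=lambda f: (f.start, f.end))
            left.mate_of, right.mate_of = right, left
            out.append((left, right))
        else:
            # no usable pairing: everything degrades to singletons
            for f in sorted(group, key=lambda f: (f.chrom, f.start)):
                out.append((f, None))
    out.sort(key=lambda p: (p[0].chrom, p[0].start))
    return out


def _pair_hull(pair) -> tuple[int, int]:
    left, right = pair
    end = left.end if right is None else max(left.end, right.end)
    return left.start, end


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == UNKNOWN or b == UNKNOWN


def cluster_loci(
    pairs: Iterable[tuple[AlignedFragment, Optional[AlignedFragment]]],
    max_gap: int = 50,
) -> list[Locus]:
    """Single-linkage clustering of fragment pairs into gene loci.

    A pair joins an open locus when its intron-spanning hull comes within
    ``max_gap`` of the locus span and the strands are compatible (loci on
    the same chromosome and known strand are kept separate; unknown-strand
    pairs join either).
    """
    by_chrom: dict[str, list] = {}
    for pair in pairs:
        by_chrom.setdefault(pair[0].chrom, []).append(pair)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        open_loci: list[Locus] = []
        for pair in sorted(by_chrom[chrom], key=lambda p: _pair_hull(p)):
            start, end = _pair_hull(pair)
            strand = pair[0].strand
            if strand == UNKNOWN and pair[1] is not None:
                strand = pair[1].strand
            # close loci that can no longer be reached
            still_open = []
            for loc in open_loci:
                if loc.span[1] + max_gap < start:
                    loci.append(loc)
                else:
                    still_open.append(loc)
            open_loci = still_open
            target = None
            for loc in open_loci:
                if _strands_compatible(loc.strand, strand):
                    if target is None or loc.span[1] > target.span[1]:
                        target = loc
            if target is None:
                open_loci.append(Locus(chrom, strand, (start, end), [pair]))
            else:
                target.fragments.append(pair)
                target.span = (min(target.span[0], start), max(target.span[1], end))
                if target.strand == UNKNOWN:
                    target.strand = strand
                # the pair may bridge other open loci; fold compatible ones in
                merged = []
                for loc in open_loci:
                    if (
                        loc is not target
                        and _strands_compatible(loc.strand, target.strand)
                        and loc.span[0] <= target.span[1] + max_gap
                        and target.span[0] <= loc.span[1] + max_gap
                    ):
                        target.fragments.extend(loc.fragments)
                        target.span = (
                            min(target.span[0], loc.span[0]),
                            max(target.span[1], loc.span[1]),
                        )
                        if target.strand == UNKNOWN:
                            target.strand = loc.strand
                    else:
                        merged.append(loc)
                open_loci = merged
        loci.extend(open_loci)
    loci.sort(key=lambda l: (l.chrom, l.span))
    return loci
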