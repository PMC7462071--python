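"""Deterministic synthetic data: toy genes, spliced read pairs, mock
assembler GTFs.

Every pipeline stage is testable without downloads.  A ``FixtureSpec``
describes a small multi-isoform gene set; from it the generator emits (a) a
coordinate-sorted SAM of paired-end spliced alignments whose CIGARs spell
the true introns, with a truth table of intron chains and read counts, and
(b) one GTF per mock "assembler", each reporting true isoforms at its
true-positive rate plus controlled error modes (spurious recombined
chains, terminal-boundary jitter).

All sampling for the alignments draws from one NumPy generator seeded with
``spec.seed``; GTF generation uses its own stream seeded with
``spec.seed + 1`` so the two outputs are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Isoform:
    name: str
    exon_indices: tuple[int, ...]  # indices into the gene's exon layout
    abundance: int                 # fragments to simulate


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, sorted
    isoforms: tuple[Isoform, ...]

    def exon_chain(self, iso: Isoform) -> tuple[tuple[int, int], ...]:
        return tuple(self.exons[i] for i in iso.exon_indices)

    def intron_chain(self, iso: Isoform) -> tuple[tuple[int, int], ...]:
        chain = self.exon_chain(iso)
        return tuple((chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1))


@dataclass(frozen=True)
class AssemblerProfile:
    name: str
    tp_rate: float = 1.0
    false_chain_rate: float = 0.0
    jitter: int = 0


@dataclass
class FixtureSpec:
    seed: int
    genes: tuple[GeneModel, ...]
    read_length: int = 75
    fragment_mean: int = 250
    fragment_sd: int = 25
    profiles: tuple[AssemblerProfile, ...] = ()

    def __post_init__(self) -> None:
        for gene in self.genes:
            n = len(gene.exons)
            for iso in gene.isoforms:
                if iso.abundance <= 0:
                    raise ValueError(f"{gene.name}/{iso.name}: abundance must be > 0")
                idx = iso.exon_indices
                if any(i < 0 or i >= n for i in idx) or list(idx) != sorted(set(idx)):
                    raise ValueError(
                        f"{gene.name}/{iso.name}: invalid exon chain {idx}"
                    )


@dataclass
class TruthRecord:
    gene: str
    isoform: str
    chrom: str
    strand: str
    intron_chain: tuple[tuple[int, int], ...]
    fragments: int


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def intron_chains(self) -> set[tuple[tuple[int, int], ...]]:
        """Intron chains of simulated multi-exon isoforms (with fragments)."""
        return {
            r.intron_chain for r in self.records if r.intron_chain and r.fragments
        }

    def to_tsv(self) -> str:
        lines = ["gene\tisoform\tchrom\tstrand\tintron_chain\tfragments"]
        for r in self.records:
            chain = ";".join(f"{d}-{a}" for d, a in r.intron_chain) or "."
            lines.append(
                f"{r.gene}\t{r.isoform}\t{r.chrom}\t{r.strand}\t{chain}\t{r.fragments}"
            )
        return "\n".join(lines) + "\n"


def default_spec(seed: int = 0) -> FixtureSpec:
    """A small but discriminating gene set: the standard test conditions.

    Three genes on one toy chromosome: a 5-exon gene whose three isoforms
    share internal structure (skipped exon, alternative pairing that only
    paired-end evidence can phase), a 3-exon two-isoform gene, and a
    mono-exon gene.  Abundances are one to two hundred fragments per
    isoform — the depth a moderately expressed gene receives in a typical
    short-read RNA-seq library (75 bp reads, 250 +/- 25 bp fragments) —
    so junction support and the residual abundance proxies of minor
    isoforms sit well clear of the reliability and expression thresholds.
    """
    gene_a = GeneModel(
        name="geneA",
        chrom="chrT",
        strand="+",
        exons=((1000, 1300), (1600, 1750), (2100, 2250), (2600, 2800), (3200, 3500)),
        isoforms=(
            Isoform("A1", (0, 1, 2, 3, 4), 200),
            Isoform("A2", (0, 1, 3, 4), 150),
            Isoform("A3", (0, 2, 4), 120),
        ),
    )
    gene_b = GeneModel(
        name="geneB",
        chrom="chrT",
        strand="+",
        exons=((10000, 10400), (10800, 11000), (11400, 11800)),
        isoforms=(
            Isoform("B1", (0, 1, 2), 150),
            Isoform("B2", (0, 2), 120),
        ),
    )
    gene_c = GeneModel(
        name="geneC",
        chrom="chrT",
        strand="+",
        exons=((20000, 20900),),
        isoforms=(Isoform("C1", (0,), 150),),
    )
    profiles = (
        AssemblerProfile("asmA"),
        AssemblerProfile("asmB"),
        AssemblerProfile("asmC"),
    )
    return FixtureSpec(seed=seed, genes=(gene_a, gene_b, gene_c), profiles=profiles)


def _transcript_to_blocks(
    chain: tuple[tuple[int, int], ...], t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic blocks."""
    blocks = []
    offset = 0
    for s, e in chain:
        length = e - s
        lo, hi = max(t_start, offset), min(t_end, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return blocks


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def generate_alignments(
    spec: FixtureSpec, sam_path: str | Path
) -> TruthTable:
    """Write a coordinate-sorted SAM of simulated read pairs; return truth.

    Fragments are placed uniformly along each isoform; lengths are normal
    (``fragment_mean``, ``fragment_sd``) clipped into what the isoform can
    hold.  Isoforms shorter than one read are skipped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    records = []  # (chrom, pos, sam-fields...)
    chrom_len: dict[str, int] = {}

    for gene in spec.genes:
        for iso in gene.isoforms:
            chain = gene.exon_chain(iso)
            tlen = sum(e - s for s, e in chain)
            chrom_len[gene.chrom] = max(
                chrom_len.get(gene.chrom, 0), chain[-1][1] + 1000
            )
            if tlen < spec.read_length:
                log.warning(
                    "%s/%s: transcript (%d bp) shorter than one read; skipped",
                    gene.name, iso.name, tlen,
                )
                truth.records.append(
                    TruthRecord(gene.name, iso.name, gene.chrom, gene.strand,
                                gene.intron_chain(iso), 0)
                )
                continue
            n_written = 0
            for i in range(iso.abundance):
                flen = int(
                    np.clip(
                        round(rng.normal(spec.fragment_mean, spec.fragment_sd)),
                        spec.read_length,
                        tlen,
                    )
                )
                start = int(rng.integers(0, tlen - flen + 1))
                rl = min(spec.read_length, flen)
                b1 = _transcript_to_blocks(chain, start, start + rl)
                b2 = _transcript_to_blocks(chain, start + flen - rl, start + flen)
                name = f"{gene.name}:{iso.name}:{i}"
                records.append((gene.chrom, gene.strand, name, b1, b2, flen))
                n_written += 1
            truth.records.append(
                TruthRecord(gene.name, iso.name, gene.chrom, gene.strand,
                            gene.intron_chain(iso), n_written)
            )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": chrom_len[c]} for c in sorted(chrom_len)
        ],
    }
    sam_records = []
    for chrom, strand, name, b1, b2, flen in records:
        for mate, (blocks, other) in enumerate(((b1, b2), (b2, b1))):
            flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
            flag |= 0x20 if mate == 0 else 0x10
            rl = sum(e - s for s, e in blocks)
            fields = [
                name, str(flag), chrom, str(blocks[0][0] + 1), "60",
                _cigar(blocks), "=", str(other[0][0] + 1),
                str(flen if mate == 0 else -flen), "A" * rl, "*",
            ]
            if len(blocks) > 1:
                fields.append(f"XS:A:{strand}")
            sam_records.append((chrom, blocks[0][0], "\t".join(fields)))
    sam_records.sort(key=lambda r: (r[0], r[1], r[2]))

    sam_path = Path(sam_path)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for chrom, _pos, line in sam_records:
            out.write(pysam.AlignedSegment.fromstring(line, out.header))
    return truth


def _false_chain(
    gene: GeneModel, rng: np.random.Generator
) -> tuple[int, ...] | None:
    """An exon chain valid over the layout but matching no true isoform."""
    true_chains = {iso.exon_indices for iso in gene.isoforms}
    candidates = [
        iso.exon_indices[:i] + iso.exon_indices[i + 1 :]
        for iso in gene.isoforms
        for i in range(1, len(iso.exon_indices) - 1)
    ]
    candidates = sorted({c for c in candidates if c not in true_chains and len(c) >= 2})
    if not candidates:
        return None
    return candidates[int(rng.integers(0, len(candidates)))]


def generate_assembler_gtfs(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[dict[str, Path], dict[str, list[tuple[str, bool]]]]:
    """One GTF per assembler profile, plus truth labels per transcript.

    Each profile reports a true isoform with probability ``tp_rate``, adds
    a spurious recombined chain per gene with probability
    ``false_chain_rate``, and jitters the outer boundaries of terminal
    exons outward by up to ``jitter`` bp.  Shared truths therefore appear
    in several files while independent errors almost never coincide.
    """
    if len(spec.profiles) < 2:
        raise ValueError("at least two assembler profiles are required")
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    labels: dict[str, list[tuple[str, bool]]] = {}

    for profile in spec.profiles:
        lines: list[str] = []
        labels[profile.name] = []
        for gene in spec.genes:
            chains: list[tuple[str, tuple[tuple[int, int], ...], bool]] = []
            for iso in gene.isoforms:
                if rng.random() < profile.tp_rate:
                    chains.append(
                        (f"{gene.name}.{iso.name}", gene.exon_chain(iso), True)
                    )
            if rng.random() < profile.false_chain_rate:
                fc = _false_chain(gene, rng)
                if fc is not None:
                    chains.append(
                        (f"{gene.name}.false",
                         tuple(gene.exons[i] for i in fc), False)
                    )
            for tid, chain, is_true in chains:
                chain = list(chain)
                if profile.jitter > 0:
                    d1 = int(rng.integers(1, profile.jitter + 1))
                    d2 = int(rng.integers(1, profile.jitter + 1))
                    chain[0] = (max(0, chain[0][0] - d1), chain[0][1])
                    chain[-1] = (chain[-1][0], chain[-1][1] + d2)
                labels[profile.name].append((tid, is_true))
                attrs = f'gene_id "{gene.name}"; transcript_id "{tid}";'
                lines.append(
                    f"{gene.chrom}\tsim\ttranscript\t"
                    f"{chain[0][0] + 1}\t{chain[-1][1]}\t.\t{gene.strand}\t.\t{attrs}"
                )
                for s, e in chain:
                    lines.append(
                        f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}"
                    )
        path = out_dir / f"{profile.name}.gtf"
        path.write_text("\n".join(lines) + "\n")
        paths[profile.name] = path
    return paths, labels


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, dict[str, Path], TruthTable]:
    """Convenience: alignments + assembler GTFs + truth TSV in one call."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam = out_dir / "reads.sam"
    truth = generate_alignments(spec, sam)
    gtfs, _ = generate_assembler_gtfs(spec, out_dir)
    (out_dir / "truth.tsv").write_text(truth.to_tsv())
    return sam, gtfs, truth
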