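"""Core genomic value types shared across the pipeline.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open genomic intervals.
GTF output is converted to 1-based inclusive on write; BED stays
0-based half-open. ``TSS``/``TES`` denote the 0-based coordinate of the
first / last transcribed base in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceJunction:
    """An intron, stored as the half-open genomic interval it removes.

    ``donor`` is the intron start and ``acceptor`` the intron end in
    genomic coordinates regardless of strand; transcript-orientation
    roles are resolved through ``strand``.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"degenerate intron [{self.donor}, {self.acceptor})")

    def motif(self, genome: dict[str, str]) -> str:
        """Splice-site dinucleotide pair (e.g. ``"GT-AG"``) on the transcript strand."""
        seq = genome[self.chrom]
        left = seq[self.donor : self.donor + 2]
        right = seq[self.acceptor - 2 : self.acceptor]
        if self.strand == "+":
            return f"{left}-{right}"
        return f"{revcomp(right)}-{revcomp(left)}"


def blocks_to_junctions(
    chrom: str, strand: str, blocks: list[tuple[int, int]]
) -> tuple[SpliceJunction, ...]:
    """Introns implied by a sorted exon-block chain."""
    return tuple(
        SpliceJunction(chrom, blocks[i][1], blocks[i + 1][0], strand)
        for i in range(len(blocks) - 1)
    )


@dataclass
class TranscriptModel:
    """A reference (or assembled) transcript as an exon-block chain."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    biotype: str = "protein_coding"
    gene_biotype: str = "protein_coding"
    gene_name: str | None = None
    utr3: tuple[int, int] | None = None  # genomic interval of the 3'UTR exon part

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exon blocks in {self.transcript_id}")

    @cached_property
    def junctions(self) -> tuple[SpliceJunction, ...]:
        return blocks_to_junctions(self.chrom, self.strand, self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Exonic sequence in transcript (5'->3') orientation."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.blocks)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class AlignmentRecord:
    """One spliced-alignment locus of one (deduplicated) molecule.

    A chimeric molecule contributes several records sharing ``read_id``;
    ``locus_index`` preserves their 5'->3' order along the read.
    ``subs`` maps 0-based genomic positions to the non-reference base the
    molecule carries there.
    """

    read_id: str
    cell_barcode: str
    umi: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    locus_index: int = 0
    subs: dict[int, str] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @cached_property
    def junctions(self) -> tuple[SpliceJunction, ...]:
        return blocks_to_junctions(self.chrom, self.strand, self.blocks)

    def base_at(self, pos: int, genome: dict[str, str]) -> str | None:
        """Base called at genomic ``pos``, or None when not covered."""
        if not any(s <= pos < e for s, e in self.blocks):
            return None
        return self.subs.get(pos, genome[self.chrom][pos])
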