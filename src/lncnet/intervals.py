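"""Core genomic coordinate types.

All coordinates are 0-based, half-open, on named sequences with an explicit
strand. GTF/GFF3 readers and writers convert to/from 1-based inclusive at
the file boundary; nothing else in the package ever does coordinate
arithmetic in file convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Sequence name.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        Either ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True if the intervals share >= 1 bp (optionally same strand only)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (any strand)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the intervals overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class TranscriptModel:
    """An exon-structured transcript with a biotype label.

    Invariants (checked at construction): exons are on the transcript's
    chrom/strand, sorted by start, non-overlapping, and contained in
    ``interval``. ``length`` is the spliced (exon-union) length.
    """

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "candidate"

    VALID_BIOTYPES = ("protein_coding", "candidate", "lncRNA", "miRNA_precursor")

    def __post_init__(self) -> None:
        if self.biotype not in self.VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.id}")
        if not self.exons:
            self.exons = [self.interval]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(f"exon of {self.id} on wrong chrom/strand")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"exon [{exon.start}, {exon.end}) outside transcript "
                    f"bounds of {self.id}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"overlapping exons in {self.id}")
            prev_end = exon.end

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Extract the spliced transcript sequence (5'->3' on its strand)."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[e.start:e.end] for e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def exonic_overlap(self, other: "TranscriptModel", stranded: bool) -> bool:
        """True if any exon of self overlaps any exon of *other* by >= 1 bp."""
        for a in self.exons:
            for b in other.exons:
                if a.overlaps(b, stranded=stranded):
                    return True
        return False


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
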