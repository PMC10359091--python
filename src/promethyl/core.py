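"""Core genomic domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package. Input
conventions (GTF 1-based, BED 0-based, pair/coverage files configurable)
are converted at the parsing boundary in :mod:`promethyl.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: half-width of the Hi-C contact window around the TSS; the window is
#: [tss - CONTACT_FLANK, tss + CONTACT_FLANK + 1): 5 kb on each side plus
#: the TSS base itself, 10,001 bp in total.
CONTACT_FLANK = 5000

#: length of the sequence / prediction window (centered on the TSS by default).
SEQ_WINDOW = 1000


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


class ValidationError(ValueError):
    """A record that parses but violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """A single base coordinate (0-based) with optional strand."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ContactRecord:
    """One Hi-C contact, canonicalized so end_a <= end_b by (chrom, pos)."""

    end_a: GenomicPosition
    end_b: GenomicPosition

    @classmethod
    def make(cls, a: GenomicPosition, b: GenomicPosition) -> "ContactRecord":
        if (b.chrom, b.pos) < (a.chrom, a.pos):
            a, b = b, a
        return cls(a, b)


@dataclass(frozen=True)
class MethylationCall:
    """Read counts at one cytosine (strand-resolved C of a CpG)."""

    site: GenomicPosition
    n_methylated: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(f"n_total must be positive, got {self.n_total}")
        if not 0 <= self.n_methylated <= self.n_total:
            raise ValidationError(
                f"n_methylated {self.n_methylated} outside [0, {self.n_total}]"
            )

    @property
    def level(self) -> float:
        return self.n_methylated / self.n_total


@dataclass
class TargetRegion:
    """A promoter anchored on its TSS.

    seq_window is the 1-kb prediction window; contact_window is the
    10,001-bp window used for Hi-C contact assignment. Both are half-open
    (start, end) tuples in 0-based coordinates, clipped to chromosome
    bounds where necessary (``clipped`` is then set).
    """

    gene_id: str
    tss: GenomicPosition
    strand: str
    seq_window: tuple[int, int]
    contact_window: tuple[int, int]
    clipped: bool = False

    @property
    def chrom(self) -> str:
        return self.tss.chrom

    @classmethod
    def from_tss(
        cls,
        gene_id: str,
        chrom: str,
        tss: int,
        strand: str,
        chrom_length: Optional[int] = None,
        seq_window_length: int = SEQ_WINDOW,
    ) -> "TargetRegion":
        """Build a region with the standard windows around a TSS.

        contact_window = [tss - 5000, tss + 5001); seq_window is centered
        on the TSS with length ``seq_window_length``. Windows extending
        past the chromosome are clipped and the region flagged.
        """
        half = seq_window_length // 2
        cw = [tss - CONTACT_FLANK, tss + CONTACT_FLANK + 1]
        sw = [tss - half, tss + (seq_window_length - half)]
        clipped = False
        for w in (cw, sw):
            if w[0] < 0:
                w[0] = 0
                clipped = True
            if chrom_length is not None and w[1] > chrom_length:
                w[1] = chrom_length
                clipped = True
        return cls(
            gene_id=gene_id,
            tss=GenomicPosition(chrom, tss, strand),
            strand=strand,
            seq_window=(sw[0], sw[1]),
            contact_window=(cw[0], cw[1]),
            clipped=clipped,
        )


@dataclass
class Cell:
    """One cell: its Hi-C contact list and its methylation calls."""

    cell_id: str
    cell_type: Optional[str] = None
    contacts: list[ContactRecord] = field(default_factory=list)
    methylation: list[MethylationCall] = field(default_factory=list)

    def methylation_by_site(self) -> dict[tuple[str, int, str], tuple[int, int]]:
        """Map (chrom, pos, strand) -> (n_methylated, n_total), summing duplicates."""
        out: dict[tuple[str, int, str], tuple[int, int]] = {}
        for call in self.methylation:
            key = (call.site.chrom, call.site.pos, call.site.strand)
            prev = out.get(key, (0, 0))
            out[key] = (prev[0] + call.n_methylated, prev[1] + call.n_total)
        return out
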