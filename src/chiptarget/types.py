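"""Core domain objects shared across the pipeline.

Coordinates are 0-based half-open throughout; strand is ``+`` or ``-``.
BED files on disk share this convention; GFF3 (1-based inclusive) is
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with a single transcript.

    The transcription start site (TSS) is the 5' end of the locus in
    reading direction; the transcription termination site (TTS) the 3'
    end.  These two anchors drive every compartment assignment.
    """

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})")

    @property
    def tss(self) -> int:
        """Coordinate of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Coordinate of the transcription termination site (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class AlignedRead:
    """A single mapped read; ``start`` is the leftmost aligned base."""

    chrom: str
    start: int
    length: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.length - 1


class ReadSet:
    """Column-oriented container for mapped reads on one genome.

    Holds parallel numpy arrays (chromosome code, start, length, strand)
    so that window counting and permutation tests stay vectorized even
    at hundreds of thousands of reads.  Iteration yields
    :class:`AlignedRead` views.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: np.ndarray,
        lengths: np.ndarray,
        strands: np.ndarray,
    ) -> None:
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        # strands stored as boolean: True == '-' (reverse)
        strands = np.asarray(strands)
        if strands.dtype.kind in "US" or strands.dtype == object:
            self.reverse = strands == "-"
        else:
            self.reverse = strands.astype(bool)
        n = len(self.starts)
        if not (len(self.chroms) == len(self.lengths) == len(self.reverse) == n):
            raise ValueError("ReadSet arrays must have equal length")

    @classmethod
    def empty(cls) -> "ReadSet":
        return cls([], np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype=bool))

    @classmethod
    def from_reads(cls, reads: Sequence[AlignedRead]) -> "ReadSet":
        return cls(
            [r.chrom for r in reads],
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.length for r in reads], dtype=np.int64),
            np.array([r.strand == "-" for r in reads], dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[AlignedRead]:
        for c, s, l, rev in zip(self.chroms, self.starts, self.lengths, self.reverse):
            yield AlignedRead(str(c), int(s), int(l), "-" if rev else "+")

    @property
    def strands(self) -> np.ndarray:
        return np.where(self.reverse, "-", "+")

    @property
    def five_prime(self) -> np.ndarray:
        """5' position of every read (start for +, rightmost base for -)."""
        return np.where(self.reverse, self.starts + self.lengths - 1, self.starts)

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.chroms[mask], self.starts[mask], self.lengths[mask], self.reverse[mask])

    def on_chrom(self, chrom: str) -> "ReadSet":
        return self.subset(self.chroms == chrom)


@dataclass
class BindingRegion:
    """A merged run of significant windows, with its three FDR statistics."""

    chrom: str
    start: int
    end: int
    condition: str = ""
    q_peak: float = float("nan")  # min over constituent windows
    q_input: float = float("nan")  # min over constituent windows
    strand_sep_q: float = float("nan")
    strand_sep_bp: float = float("nan")
    support: tuple[bool, bool] = (True, False)  # per-replicate support flags

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionAssignment:
    """A binding region placed in one genomic compartment.

    ``distance`` is the signed bp from the region midpoint to the TSS in
    the gene's reading direction (negative upstream of the TSS);
    ``anchor_distance`` is the signed distance to the compartment anchor
    (TSS for upstream/gene, TTS for downstream) used for profiling.
    """

    region: BindingRegion
    category: str  # upstream | gene | downstream | intergenic
    gene_id: str | None = None
    distance: float | None = None
    anchor_distance: float | None = None


@dataclass
class DEResult:
    """Per-gene differential-expression outcome (overexpressor vs wild type)."""

    gene_id: str
    log2fc: dict[int, float]  # time point (h) -> mean log2(OX) - mean log2(WT)
    p_anova: float
    q: float
    call: str  # up | down | none
    times_passing: tuple[int, ...] = ()


@dataclass
class TargetGene:
    """A candidate bound gene that is also differentially expressed."""

    gene_id: str
    direction: str  # up | down
    regions: list[BindingRegion] = field(default_factory=list)
    tss_distance: float | None = None
    log2fc: dict[int, float] = field(default_factory=dict)
    category: str = "unknown function"
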