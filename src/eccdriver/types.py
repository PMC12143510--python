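"""Core domain types shared across the package.

All genomic coordinates use BED semantics: 0-based, half-open ``[start, end)``.
Transcript annotation read from GTF/GFF3 (1-based, closed) is converted on
load so a single convention holds everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; any non-empty string.
    start : int
        0-based inclusive start (bp). Must be >= 0.
    end : int
        0-based exclusive end (bp). Must be > ``start``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unknown). Enhancers and eccDNA
        circles are unstranded; only transcripts carry a meaningful strand.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must be > start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this span (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least 1 bp on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EccDNARecord:
    """One eccDNA circle, treated as a linear genomic span.

    Elements spanning the circularization junction are not representable;
    the containment procedure operates on linear coordinates only.
    """

    interval: GenomicInterval
    ecc_id: str
    dataset: str = "default"


@dataclass(frozen=True)
class EnhancerRecord:
    """An enhancer with its scored candidate target genes.

    ``targets`` holds ``(gene_id, s_ge)`` pairs ordered by the gene–enhancer
    interaction score S_GE descending, ties broken by gene_id ascending, so
    ``targets[0]`` is always the top-1 candidate.
    """

    interval: GenomicInterval
    enh_id: str
    targets: tuple = ()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"enhancer {self.enh_id} has no targets")
        for gene, score in self.targets:
            if not (score >= 0 and score == score and score != float("inf")):
                raise ValidationError(
                    f"enhancer {self.enh_id}: S_GE for {gene} must be finite and >= 0"
                )

    @property
    def top_target(self) -> str:
        return self.targets[0][0]


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript anchored to a gene, with strand and biotype."""

    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError(
                f"transcript {self.transcript_id} has empty gene_id"
            )


@dataclass(frozen=True)
class EdgCall:
    """A gene's eccDNA-driven status with supporting evidence.

    ``classes`` is a subset of ``{"EEG", "ERG"}``: encoded on a circle,
    regulated by an enhancer on a circle, or both.
    """

    gene_id: str
    classes: frozenset
    supporting_ecc_ids: frozenset
    supporting_element_ids: frozenset
    dataset: str
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValidationError(f"EdgCall for {self.gene_id} has empty classes")
        if not self.classes <= {"EEG", "ERG"}:
            raise ValidationError(f"invalid classes {set(self.classes)}")


@dataclass
class EdgCatalog:
    """Per-dataset EDG calls partitioned by biotype.

    ``coding`` holds protein-coding genes (the general EDGs used for all
    downstream ranking); everything else lands in ``non_coding``.
    """

    dataset: str
    calls: dict = field(default_factory=dict)  # gene_id -> EdgCall

    @property
    def genes(self) -> set:
        return set(self.calls)

    @property
    def coding(self) -> set:
        return {g for g, c in self.calls.items() if c.biotype == "protein_coding"}

    @property
    def non_coding(self) -> set:
        return self.genes - self.coding


@dataclass(frozen=True)
class CentralityRecord:
    """Per-gene centrality trace from the driver-ranking pipeline.

    K is the degree in the full reference PPI; N the count of direct
    differentially-expressed neighbors; Q the summed N over neighbors;
    C_WL = N + alpha*Q the weighted semi-local centrality; and
    EGIS = (K+1)*(C_WL+1) the impact score used for ranking.
    """

    gene_id: str
    K: int
    N: int
    Q: int
    alpha_used: float
    c_wl: float
    egis: float
    rank: int


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion-matrix counts and derived proportions over a gene universe."""

    TP: int
    TN: int
    FP: int
    FN: int
    universe_size: int
    accuracy: float
    precision: float
    recall: float
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass(frozen=True)
class SignatureModel:
    """A fixed linear risk model over z-scored gene expression."""

    genes: tuple
    coefficients: tuple
    name: str = "custom"
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.coefficients):
            raise ValidationError("gene and coefficient counts differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in signature model")


def as_sorted_tuple(items: Sequence) -> tuple:
    return tuple(sorted(items))
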