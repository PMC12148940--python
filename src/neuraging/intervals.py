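"""Genomic coordinate types and transcript element geometry.

Everything downstream (CLIP window annotation, locus binning around
skipped exons, CDS-restricted P-site counting) is interval arithmetic on
one convention: 0-based, half-open, stranded spans.  GTF input is
converted to this convention on ingestion (see :mod:`neuraging.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ELEMENT_LABELS",
    "ELEMENT_PRIORITY",
    "GenomicInterval",
    "BindingWindow",
    "TranscriptModel",
]

# Tie-break priority for window assignment (highest first); `intergenic`
# is the zero-overlap fallback and never competes.
ELEMENT_PRIORITY = ("CDS", "3'UTR", "5'UTR", "noncoding_exon", "intron")
ELEMENT_LABELS = ELEMENT_PRIORITY + ("intergenic",)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open, stranded coordinate span."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Base pairs of overlap; 0 unless chrom and strand both match."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class BindingWindow:
    """One enriched CLIP window (an interval plus bookkeeping)."""

    interval: GenomicInterval
    window_id: str
    condition: str = ""
    score: Optional[float] = None


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``cds_start``/``cds_end`` are genomic (strand-agnostic) bounds of the
    coding span; ``None`` for noncoding transcripts.  Derived elements —
    5'UTR, CDS, 3'UTR, introns — partition the transcript span with no
    gaps or overlaps.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        for ex in exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon chrom/strand mismatch"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.cds_start < self.cds_end):
                raise ValueError(f"{self.transcript_id}: empty CDS span")
            if not self._span_in_exons(self.cds_start, self.cds_end):
                raise ValueError(
                    f"{self.transcript_id}: CDS bounds outside exon union"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def _span_in_exons(self, start: int, end: int) -> bool:
        in_start = any(e.start <= start < e.end for e in self.exons)
        in_end = any(e.start < end <= e.end for e in self.exons)
        return in_start and in_end

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def elements(self) -> list[tuple[str, GenomicInterval]]:
        """(label, interval) pairs partitioning the transcript span.

        Labels follow transcription: on the minus strand the 5'UTR is the
        exonic region genomically *right* of the CDS.
        """
        out: list[tuple[str, GenomicInterval]] = []
        if not self.is_coding:
            out.extend(("noncoding_exon", e) for e in self.exons)
        else:
            left = "5'UTR" if self.strand == "+" else "3'UTR"
            right = "3'UTR" if self.strand == "+" else "5'UTR"
            for e in self.exons:
                # split each exon at the CDS bounds
                cuts = [
                    (e.start, min(e.end, max(e.start, self.cds_start)), left),
                    (
                        min(e.end, max(e.start, self.cds_start)),
                        max(e.start, min(e.end, self.cds_end)),
                        "CDS",
                    ),
                    (max(e.start, min(e.end, self.cds_end)), e.end, right),
                ]
                for s, t, lab in cuts:
                    if t > s:
                        out.append(
                            (lab, GenomicInterval(self.chrom, s, t, self.strand))
                        )
        out.extend(("intron", i) for i in self.introns())
        out.sort(key=lambda p: p[1].start)
        return out

    # -- transcript coordinates (for footprint analysis) ----------------

    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def cds_in_transcript_coords(self) -> Optional[tuple[int, int]]:
        """CDS span as [start, end) in transcript (5'->3') coordinates."""
        if not self.is_coding:
            return None
        bounds = []
        for g in (self.cds_start, self.cds_end):
            pos = 0
            for e in self.exons:
                if e.start <= g <= e.end:
                    pos += g - e.start
                    break
                pos += len(e)
            bounds.append(pos)
        lo, hi = bounds
        if self.strand == "-":
            n = self.transcript_length()
            lo, hi = n - hi, n - lo
        return lo, hi


def validate_models(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Materialize and sanity-check a model collection."""
    out = list(models)
    if not out:
        raise ValueError("empty transcript model set")
    return out
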