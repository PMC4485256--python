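"""Genomic interval and transcript-model containers.

All coordinates are 0-based, half-open (BED convention). GTF inputs are
converted on read so a single convention holds throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: a genomic span plus an ordered exon chain.

    ``biotype`` is ``"coding"`` or ``"lncRNA"``. Exons must be sorted,
    non-overlapping, on the span's chromosome/strand and within the span.
    """

    id: str
    gene_id: str
    biotype: str
    span: GenomicInterval
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.biotype not in {"coding", "lncRNA"}:
            raise ValueError(f"biotype must be 'coding' or 'lncRNA', got {self.biotype!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValueError(f"exon of {self.id} not on transcript chrom/strand")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"exon of {self.id} outside transcript span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.id} overlap or are unsorted")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def mature_length(self) -> int:
        """Summed exon length (the spliced-transcript length)."""
        return sum(len(ex) for ex in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


class GenomeAnnotation:
    """Transcript models (coding + lncRNA) with fast interval lookup.

    Interval trees are built lazily per chromosome: one over coding spans
    (used by the probe-filtering cascade and by positional categorization)
    and one over lncRNA exons (used by probe-to-transcript mapping).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self.transcripts[t.id] = t
        self._coding_span_trees: dict[str, IntervalTree] | None = None
        self._lnc_exon_trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    @property
    def coding(self) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == "coding"]

    @property
    def lncrnas(self) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == "lncRNA"]

    @property
    def chroms(self) -> set[str]:
        return {t.chrom for t in self}

    def coding_span_tree(self, chrom: str) -> IntervalTree:
        if self._coding_span_trees is None:
            trees: dict[str, IntervalTree] = {}
            for t in self.coding:
                trees.setdefault(t.chrom, IntervalTree()).addi(
                    t.span.start, t.span.end, t
                )
            self._coding_span_trees = trees
        return self._coding_span_trees.get(chrom, IntervalTree())

    def lnc_exon_tree(self, chrom: str) -> IntervalTree:
        if self._lnc_exon_trees is None:
            trees: dict[str, IntervalTree] = {}
            for t in self.lncrnas:
                for ex in t.exons:
                    trees.setdefault(t.chrom, IntervalTree()).addi(
                        ex.start, ex.end, t
                    )
            self._lnc_exon_trees = trees
        return self._lnc_exon_trees.get(chrom, IntervalTree())
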