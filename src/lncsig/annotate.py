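"""Probe re-annotation to lncRNAs and positional categorization.

Exon-array probes were designed against coding transcripts; repurposing
them for long non-coding RNAs requires (1) discarding probes that map to
no or multiple genomic locations, (2) discarding probes overlapping any
protein-coding transcript span on either strand, (3) assigning the
survivors to lncRNA transcripts by exonic containment, dropping ambiguous
probes, and (4) averaging probe-level log2 intensities per transcript.

Each lncRNA is also assigned exactly one of five positional categories
relative to protein-coding genes: sense, intronic, antisense, proximity,
intergenic (first matching rule in that fixed precedence wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomeAnnotation, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

CATEGORIES = ("intergenic", "intronic", "sense", "antisense", "proximity")

DEFAULT_PROXIMITY_BP = 10_000
DEFAULT_MIN_PROBES = 4
MIN_LNC_LENGTH = 200  # mature (summed-exon) length a lncRNA must exceed


@dataclass
class FilterReport:
    """Counts discarded per rule, in cascade order."""

    input: int
    zero_hit: int
    multi_hit: int
    coding_overlap: int
    retained: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "zero_hit": self.zero_hit,
            "multi_hit": self.multi_hit,
            "coding_overlap": self.coding_overlap,
            "retained": self.retained,
        }


@dataclass
class ProbeToTranscriptMap:
    """Unique probe -> lncRNA transcript assignment after ambiguity removal."""

    mapping: pd.Series  # index probe_id, value transcript id
    n_ambiguous: int
    n_unmapped: int
    probes_per_transcript: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.probes_per_transcript = self.mapping.value_counts().sort_index()

    @property
    def n_transcripts(self) -> int:
        """Number of lncRNAs with at least one uniquely mapped probe."""
        return int(self.probes_per_transcript.size)


def _validate_probe_table(probes: pd.DataFrame) -> None:
    if probes.empty:
        raise ValueError("empty probe table")
    hits = probes[probes["n_hits"] > 0]
    if ((hits["end"].astype(int) - hits["start"].astype(int)) <= 0).any():
        raise ValueError("probe hit with end <= start: coordinate convention mismatch")


def filter_probes(
    probes: pd.DataFrame, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep probes with exactly one hit not overlapping any coding span.

    The cascade is a pipeline of set differences applied in order:
    zero-hit, multi-hit, coding-overlap (>=1 bp against the full transcript
    span, introns included, on either strand). Returns the retained hits
    plus a :class:`FilterReport` whose counts sum to the input probe count.
    """
    _validate_probe_table(probes)
    n_input = probes["probe_id"].nunique()

    zero = probes.loc[probes["n_hits"] == 0, "probe_id"].unique()
    multi = probes.loc[probes["n_hits"] >= 2, "probe_id"].unique()
    single = probes[probes["n_hits"] == 1]

    overlap_ids = []
    for row in single.itertuples(index=False):
        tree = annotation.coding_span_tree(row.chrom)
        if tree.overlap(int(row.start), int(row.end)):
            overlap_ids.append(row.probe_id)
    retained = single[~single["probe_id"].isin(overlap_ids)].reset_index(drop=True)

    report = FilterReport(
        input=n_input,
        zero_hit=len(zero),
        multi_hit=len(multi),
        coding_overlap=len(overlap_ids),
        retained=retained["probe_id"].nunique(),
    )
    return retained, report


def map_probes_to_lncrnas(
    filtered: pd.DataFrame, annotation: GenomeAnnotation
) -> ProbeToTranscriptMap:
    """Assign each retained probe to the one lncRNA whose exons contain it.

    A probe is kept iff its single hit lies entirely within the exonic
    extent of exactly one lncRNA transcript longer than 200 bp (mature
    length); probes contained in two or more distinct lncRNAs are removed
    as ambiguous, probes contained in none are unmapped.
    """
    assignments: dict[str, str] = {}
    n_ambiguous = 0
    n_unmapped = 0
    for row in filtered.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        tree = annotation.lnc_exon_tree(row.chrom)
        hits = {
            iv.data.id
            for iv in tree.overlap(start, end)
            if iv.begin <= start and end <= iv.end
            and iv.data.mature_length > MIN_LNC_LENGTH
        }
        if len(hits) == 1:
            assignments[row.probe_id] = next(iter(hits))
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_unmapped += 1
    mapping = pd.Series(assignments, name="transcript_id", dtype=object)
    return ProbeToTranscriptMap(mapping=mapping, n_ambiguous=n_ambiguous, n_unmapped=n_unmapped)


def summarize_expression(
    intensities: pd.DataFrame,
    mapping: ProbeToTranscriptMap,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> pd.DataFrame:
    """Average probe log2 intensities per transcript.

    Transcript value per sample is the mean of its probes' log2 values;
    transcripts supported by fewer than ``min_probes`` probes are dropped.
    """
    missing = mapping.mapping.index.difference(intensities.index)
    if len(missing) > 0:
        raise KeyError(
            f"mapped probe(s) absent from intensity matrix: {sorted(missing)[:5]}"
        )
    probes = intensities.loc[mapping.mapping.index]
    grouped = probes.groupby(mapping.mapping).mean()
    counts = mapping.probes_per_transcript
    keep = counts[counts >= min_probes].index
    return grouped.loc[grouped.index.intersection(keep)].sort_index()


def _gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """0 when touching or overlapping, else the bp gap between intervals."""
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def categorize_lncrna(
    lnc: TranscriptModel,
    coding: list[TranscriptModel],
    proximity_bp: int = DEFAULT_PROXIMITY_BP,
) -> str:
    """Assign one of the five positional categories.

    Precedence (first match wins):

    1. ``sense`` — >=1 bp exonic overlap with a coding transcript on the
       same strand;
    2. ``intronic`` — lncRNA span fully inside one intron of a coding
       transcript on the same strand;
    3. ``antisense`` — any span overlap with a coding transcript on the
       opposite strand;
    4. ``proximity`` — no such overlap, but the nearest coding span lies
       within ``proximity_bp``;
    5. ``intergenic`` — otherwise.
    """
    if not lnc.exons:
        raise ValueError(f"lncRNA {lnc.id} has no exons; cannot categorize")
    if proximity_bp <= 0:
        raise ValueError("proximity_bp must be positive")

    same = [c for c in coding if c.chrom == lnc.chrom and c.strand == lnc.strand]
    opposite = [c for c in coding if c.chrom == lnc.chrom and c.strand != lnc.strand]

    for c in same:
        for cex in c.exons:
            for lex in lnc.exons:
                if lex.overlaps(cex):
                    return "sense"
    for c in same:
        for intron in c.introns():
            if intron.contains(lnc.span):
                return "intronic"
    for c in opposite:
        if lnc.span.overlaps(c.span):
            return "antisense"
    dists = [
        _gap_distance(lnc.span, c.span) for c in coding if c.chrom == lnc.chrom
    ]
    if dists and min(dists) <= proximity_bp:
        return "proximity"
    return "intergenic"


def categorize_all(
    annotation: GenomeAnnotation, proximity_bp: int = DEFAULT_PROXIMITY_BP
) -> pd.Series:
    """Category label for every lncRNA in the annotation."""
    coding = annotation.coding
    labels = {
        t.id: categorize_lncrna(t, coding, proximity_bp) for t in annotation.lncrnas
    }
    return pd.Series(labels, name="category", dtype=object).sort_index()
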