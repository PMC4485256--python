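"""Linking ChIP-seq peaks to lncRNA promoters.

A lncRNA counts as bound when some peak midpoint falls within a fixed
window (default 10 kb) upstream of its transcription start site,
strand-aware; the TSS position itself (distance 0) counts as bound.
Distances are reported TSS-relative with upstream positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterConfig:
    window_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def tss_of(transcript: TranscriptModel) -> int:
    """Transcription start site: span start on +, 0-based last base on -."""
    if transcript.strand == "+":
        return transcript.span.start
    if transcript.strand == "-":
        return transcript.span.end - 1
    raise ValueError(f"TSS undefined for unstranded transcript {transcript.id}")


def peak_midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def assign_peaks(
    lncs: list[TranscriptModel],
    peaks: pd.DataFrame,
    config: PromoterConfig = PromoterConfig(),
) -> pd.DataFrame:
    """Bound/unbound flag plus nearest-peak distance for each transcript.

    Bound iff a peak midpoint m on the same chromosome lies in the
    inclusive upstream window: ``TSS - window <= m <= TSS`` on + strand,
    ``TSS <= m <= TSS + window`` on -. ``nearest_peak_distance`` is the
    TSS-relative distance of the closest peak (upstream positive,
    downstream negative; NaN when the chromosome has no peaks).
    """
    known_chroms = {t.chrom for t in lncs}
    mids_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in peaks.groupby("chrom"):
        if chrom not in known_chroms:
            logger.warning("peaks on chromosome %r ignored: not in annotation", chrom)
            continue
        mids_by_chrom[chrom] = np.sort(
            (sub["start"].to_numpy(int) + sub["end"].to_numpy(int)) // 2
        )

    rows = []
    for t in lncs:
        tss = tss_of(t)
        mids = mids_by_chrom.get(t.chrom)
        if mids is None or mids.size == 0:
            rows.append((t.id, tss, t.strand, False, np.nan))
            continue
        # upstream positive regardless of strand
        rel = (tss - mids) if t.strand == "+" else (mids - tss)
        bound = bool(((rel >= 0) & (rel <= config.window_bp)).any())
        nearest = rel[np.argmin(np.abs(rel))]
        rows.append((t.id, tss, t.strand, bound, float(nearest)))
    return pd.DataFrame(
        rows, columns=["transcript_id", "tss", "strand", "bound", "nearest_peak_distance"]
    ).set_index("transcript_id")


def fraction_bound(flags: pd.Series) -> tuple[int, int, float]:
    """(n_bound, n_total, percent bound rounded to 0.1)."""
    if len(flags) == 0:
        raise ValueError("empty feature set")
    n_bound = int(flags.sum())
    n_total = int(len(flags))
    pct = round(100.0 * n_bound / n_total, 1)
    return n_bound, n_total, pct
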