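import numpy as np
import pandas as pd
import pytest

from lncsig import simulate
from lncsig.intervals import GenomicInterval, TranscriptModel


def make_transcript(tid, chrom, start, end, strand, biotype="lncRNA", exons=None):
    """Build a transcript; exons default to one exon spanning the body."""
    if exons is None:
        exons = [(start, end)]
    return TranscriptModel(
        id=tid,
        gene_id=f"g_{tid}",
        biotype=biotype,
        span=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
    )


@pytest.fixture
def small_sim_config():
    """Compact genome: quick to generate, still covers all five categories."""
    return simulate.SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length=1_200_000,
        n_coding=20,
        lnc_counts={
            "intronic": 6,
            "intergenic": 5,
            "antisense": 3,
            "sense": 3,
            "proximity": 3,
        },
        n_probes_per_transcript=6,
        classes={"GF": 4, "RC": 5, "EC": 4, "EC_BSH": 5},
        n_signature_per_class=2,
    )


@pytest.fixture
def two_group_matrix():
    """5 vs 5 pure-noise log2 matrix, 100 features."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        rng.normal(7, 0.3, size=(100, 10)),
        index=[f"f{i:03d}" for i in range(100)],
        columns=[f"t{i}" for i in range(5)] + [f"c{i}" for i in range(5)],
    )
    labels = pd.Series(["trt"] * 5 + ["ctl"] * 5, index=X.columns)
    return X, labels
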