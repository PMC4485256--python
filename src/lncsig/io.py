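"""Readers and writers for the file dialects the pipeline speaks.

Formats: GTF (via :mod:`gffutils`) and BED12 for transcript annotation,
TSV probe-alignment tables, TSV intensity/expression matrices, two-column
sample-label TSVs, and 3+-column BED peak files. All genomic coordinates
are converted to 0-based half-open on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd

from .intervals import GenomeAnnotation, GenomicInterval, TranscriptModel

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "strand", "n_hits"]


# ---------------------------------------------------------------------------
# annotation


def write_gtf(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write transcripts and exons as GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for t in annotation:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                f'biotype "{t.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "lncsig",
                        "transcript",
                        str(t.span.start + 1),
                        str(t.span.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for ex in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "lncsig",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str | os.PathLike) -> GenomeAnnotation:
    """Read a GTF/GFF file of transcript+exon features into an annotation.

    The ``biotype`` (or ``gene_biotype``/``transcript_biotype``) attribute
    decides coding vs lncRNA; unrecognized biotypes raise.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        exons_by_tid.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
    transcripts = []
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        biotype = None
        for key in ("biotype", "transcript_biotype", "gene_biotype"):
            if key in f.attributes:
                biotype = f.attributes[key][0]
                break
        if biotype is None:
            raise ValueError(f"transcript {tid} has no biotype attribute")
        if biotype in {"protein_coding", "coding"}:
            biotype = "coding"
        elif biotype in {"lncRNA", "lincRNA", "lnc_rna"}:
            biotype = "lncRNA"
        else:
            raise ValueError(f"unrecognized biotype {biotype!r} for {tid}")
        exons = sorted(exons_by_tid.get(tid, []), key=lambda e: e.start)
        transcripts.append(
            TranscriptModel(
                id=tid,
                gene_id=gid,
                biotype=biotype,
                span=GenomicInterval(f.seqid, f.start - 1, f.end, f.strand),
                exons=tuple(exons),
            )
        )
    return GenomeAnnotation(transcripts)


def read_bed12(path: str | os.PathLike, default_biotype: str = "lncRNA") -> GenomeAnnotation:
    """Read BED12 transcript models.

    BED carries no biotype, so the name field may encode it as
    ``transcript_id|gene_id|biotype``; otherwise ``default_biotype``
    applies and gene_id equals the transcript id.
    """
    transcripts = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"block count mismatch for {name}")
            fields = name.split("|")
            tid = fields[0]
            gid = fields[1] if len(fields) > 1 else tid
            biotype = fields[2] if len(fields) > 2 else default_biotype
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            )
            transcripts.append(
                TranscriptModel(
                    id=tid,
                    gene_id=gid,
                    biotype=biotype,
                    span=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                )
            )
    return GenomeAnnotation(transcripts)


# ---------------------------------------------------------------------------
# probe alignment tables

def read_probe_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe alignment table: one row per genomic hit.

    Columns: probe_id, chrom, start, end, strand, n_hits. Probes with zero
    hits appear as a single row with empty coordinate fields.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "chrom": str, "strand": str},
    )
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    df["start"] = df["start"].astype("Int64")
    df["end"] = df["end"].astype("Int64")
    df["n_hits"] = df["n_hits"].astype(int)
    return df[PROBE_COLUMNS]


def write_probe_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# matrices, labels, peaks


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Features x samples TSV with a header row of sample IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="feature")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Two-column TSV (sample_id, condition) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs sample_id and condition columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="condition")


def write_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": labels.index, "condition": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def read_bed_peaks(path: str | os.PathLike) -> pd.DataFrame:
    """3+-column BED of peak intervals -> DataFrame (chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {i + 1} has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else f"peak_{i + 1}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed_peaks(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
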