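"""Seeded synthetic data emulating the study's inputs, with planted truth.

The generator lays out a toy genome of protein-coding genes with
exon/intron structure and plants lncRNAs in each of the five positional
categories BY CONSTRUCTION; tiles probes over the clean lncRNAs and
injects zero-hit, multi-hit and coding-overlap decoys; draws a
class-structured log-normal expression matrix over a four-condition
design (germ-free and three re-colonized states by default) with
condition-specific signature lncRNAs of configurable effect size; and
places ChIP-like peaks inside the strand-aware upstream window of a
configurable fraction of lncRNA TSSs.

One root seed fans out to independent per-stage generator streams, so
every output is a deterministic function of (config, seed) and changing
one stage cannot perturb another's draws.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .intervals import GenomeAnnotation, GenomicInterval, TranscriptModel
from .promoter import tss_of

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-shaped generator settings.

    The four default classes mirror the germ-free / re-conventionalized /
    E. coli / E. coli-BSH design with 4-5 biological replicates each.
    Effect sizes are expressed in noise-SD units on the log2 scale.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    n_coding: int = 50
    coding_exon_count: tuple[int, int] = (3, 5)
    coding_exon_len: tuple[int, int] = (150, 300)
    coding_intron_len: tuple[int, int] = (2_000, 6_000)
    lnc_counts: dict[str, int] = field(
        default_factory=lambda: {
            "intronic": 25,
            "intergenic": 20,
            "antisense": 10,
            "sense": 8,
            "proximity": 7,
        }
    )
    lnc_exon_len: tuple[int, int] = (250, 600)
    proximity_bp: int = 10_000
    n_probes_per_transcript: int = 8
    probe_len: int = 25
    decoy_rates: dict[str, float] = field(
        default_factory=lambda: {
            "zero_hit": 0.05,
            "multi_hit": 0.05,
            "coding_overlap": 0.05,
        }
    )
    classes: dict[str, int] = field(
        default_factory=lambda: {"GF": 4, "RC": 5, "EC": 4, "EC_BSH": 5}
    )
    reference: str = "GF"
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    probe_offset_sd: float = 0.25
    noise_sd: float = 0.3
    n_signature_per_class: int = 5
    effect_size: float = 5.0  # noise-SD units; 5 * 0.3 = 1.5 log2 units
    bound_fraction: float = 0.117
    peak_width: int = 200
    n_background_peaks: int = 50

    def validate(self) -> None:
        for name, v in self.lnc_counts.items():
            if v < 0:
                raise ValueError(f"lnc count for {name} must be >= 0")
        for name, v in self.decoy_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"decoy rate {name} must be in [0, 1]")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.reference not in self.classes:
            raise ValueError("reference class missing from classes")


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ["annotation", "probes", "expression", "peaks"]
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, ss.spawn(len(names)))
    }


# ---------------------------------------------------------------------------
# genome layout


def _make_coding_gene(
    idx: int, chrom: str, start: int, rng: np.random.Generator, config: SimConfig
) -> TranscriptModel:
    n_ex = int(rng.integers(config.coding_exon_count[0], config.coding_exon_count[1] + 1))
    exons = []
    pos = start
    strand = rng.choice(["+", "-"])
    for j in range(n_ex):
        ex_len = int(rng.integers(config.coding_exon_len[0], config.coding_exon_len[1] + 1))
        exons.append((pos, pos + ex_len))
        pos += ex_len
        if j < n_ex - 1:
            pos += int(
                rng.integers(config.coding_intron_len[0], config.coding_intron_len[1] + 1)
            )
    span = GenomicInterval(chrom, start, exons[-1][1], strand)
    return TranscriptModel(
        id=f"pc{idx:04d}",
        gene_id=f"pcg{idx:04d}",
        biotype="coding",
        span=span,
        exons=tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
    )


def _single_exon_lnc(
    idx: int, chrom: str, start: int, length: int, strand: str
) -> TranscriptModel:
    iv = GenomicInterval(chrom, start, start + length, strand)
    return TranscriptModel(
        id=f"lnc{idx:04d}", gene_id=f"lncg{idx:04d}", biotype="lncRNA",
        span=iv, exons=(iv,),
    )


def simulate_annotation(config: SimConfig) -> tuple[GenomeAnnotation, pd.Series]:
    """Toy genome with lncRNAs planted into known categories.

    Coding genes are laid out sequentially, separated by gaps exceeding
    the proximity window so that each lncRNA's category is forced by its
    local geometry alone. Returns the annotation plus the planted
    category label per lncRNA.
    """
    config.validate()
    rng = _streams(config)["annotation"]
    counts = {k: config.lnc_counts.get(k, 0) for k in
              ("intronic", "sense", "antisense", "proximity", "intergenic")}
    attached_needed = counts["intronic"] + counts["sense"] + counts["antisense"] + counts["proximity"]
    if attached_needed > config.n_coding:
        raise ValueError(
            f"infeasible geometry: {attached_needed} host-attached lncRNAs "
            f"but only {config.n_coding} coding genes"
        )

    # per-gene attachment plan: one lncRNA per host gene at most
    plan: list[str | None] = (
        ["intronic"] * counts["intronic"]
        + ["sense"] * counts["sense"]
        + ["antisense"] * counts["antisense"]
        + ["proximity"] * counts["proximity"]
    )
    plan += [None] * (config.n_coding - len(plan))
    rng.shuffle(plan)
    n_intergenic = counts["intergenic"]
    # intergenic lncRNAs interleaved before roughly evenly spaced genes
    intergenic_before = set()
    if n_intergenic:
        idxs = np.linspace(0, config.n_coding - 1, n_intergenic).astype(int)
        # guarantee distinct slots
        if len(set(idxs)) < n_intergenic:
            raise ValueError("infeasible geometry: more intergenic lncRNAs than gene gaps")
        intergenic_before = set(int(i) for i in idxs)

    margin = config.proximity_bp + 1_000  # gap that defeats the proximity rule
    transcripts: list[TranscriptModel] = []
    truth: dict[str, str] = {}
    lnc_idx = 0
    chrom_i = 0
    cursor = 1_000

    def lnc_len() -> int:
        return int(rng.integers(config.lnc_exon_len[0], config.lnc_exon_len[1] + 1))

    for gi in range(config.n_coding):
        chrom = f"chr{chrom_i + 1}"
        # worst-case footprint of this unit; jump chromosome if it cannot fit
        worst = (
            (config.coding_exon_count[1] * config.coding_exon_len[1])
            + ((config.coding_exon_count[1] - 1) * config.coding_intron_len[1])
            + 3 * margin
            + 3 * config.lnc_exon_len[1]
            + config.proximity_bp
        )
        if cursor + worst > config.chrom_length:
            chrom_i += 1
            cursor = 1_000
            if chrom_i >= config.n_chroms:
                raise ValueError(
                    "infeasible geometry: genome too short for requested features"
                )
            chrom = f"chr{chrom_i + 1}"

        if gi in intergenic_before:
            length = lnc_len()
            strand = rng.choice(["+", "-"])
            lnc = _single_exon_lnc(lnc_idx, chrom, cursor, length, strand)
            transcripts.append(lnc)
            truth[lnc.id] = "intergenic"
            lnc_idx += 1
            cursor = lnc.span.end + margin

        gene = _make_coding_gene(gi, chrom, cursor, rng, config)
        transcripts.append(gene)
        unit_end = gene.span.end

        attach = plan[gi]
        if attach == "intronic":
            introns = gene.introns()
            length = lnc_len()
            fits = [iv for iv in introns if len(iv) >= length + 200]
            if not fits:
                raise ValueError("infeasible geometry: no intron can host a lncRNA")
            intron = fits[int(rng.integers(len(fits)))]
            off = int(rng.integers(100, len(intron) - length - 100 + 1))
            lnc = _single_exon_lnc(lnc_idx, chrom, intron.start + off, length, gene.strand)
            truth[lnc.id] = "intronic"
        elif attach == "sense":
            # start mid-exon and run past its end: >=1 bp exonic overlap, same strand
            host_ex = gene.exons[int(rng.integers(len(gene.exons)))]
            start = host_ex.start + len(host_ex) // 2
            lnc = _single_exon_lnc(lnc_idx, chrom, start, lnc_len(), gene.strand)
            truth[lnc.id] = "sense"
        elif attach == "antisense":
            opposite = "-" if gene.strand == "+" else "+"
            introns = gene.introns()
            length = lnc_len()
            fits = [iv for iv in introns if len(iv) >= length + 200]
            if not fits:
                raise ValueError("infeasible geometry: no intron can host a lncRNA")
            intron = fits[int(rng.integers(len(fits)))]
            off = int(rng.integers(100, len(intron) - length - 100 + 1))
            lnc = _single_exon_lnc(lnc_idx, chrom, intron.start + off, length, opposite)
            truth[lnc.id] = "antisense"
        elif attach == "proximity":
            length = lnc_len()
            gap = int(rng.integers(500, config.proximity_bp - length - 500))
            strand = rng.choice(["+", "-"])
            lnc = _single_exon_lnc(lnc_idx, chrom, gene.span.end + gap, length, strand)
            truth[lnc.id] = "proximity"
        else:
            lnc = None
        if lnc is not None:
            transcripts.append(lnc)
            lnc_idx += 1
            unit_end = max(unit_end, lnc.span.end)

        cursor = unit_end + margin + int(rng.integers(0, 2_000))

    annotation = GenomeAnnotation(transcripts)
    labels = pd.Series(truth, name="category", dtype=object).sort_index()
    return annotation, labels


# ---------------------------------------------------------------------------
# probes


def probed_lncrnas(annotation: GenomeAnnotation) -> list[TranscriptModel]:
    """LncRNAs whose exons avoid every coding span (probes can survive)."""
    out = []
    for t in annotation.lncrnas:
        tree = annotation.coding_span_tree(t.chrom)
        if not any(tree.overlap(ex.start, ex.end) for ex in t.exons):
            out.append(t)
    return out


def simulate_probes(
    annotation: GenomeAnnotation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile clean probes over probe-able lncRNA exons and inject decoys.

    Returns the probe alignment table (one row per hit) plus a truth table
    with each probe's status (clean / zero_hit / multi_hit /
    coding_overlap) and, for clean probes, the target transcript.
    """
    config.validate()
    rng = _streams(config)["probes"]
    rows = []
    truth_rows = []
    counter = 0

    targets = probed_lncrnas(annotation)
    for t in targets:
        exons = [ex for ex in t.exons if len(ex) >= config.probe_len]
        for j in range(config.n_probes_per_transcript):
            ex = exons[j % len(exons)]
            pos = int(rng.integers(ex.start, ex.end - config.probe_len + 1))
            pid = f"probe{counter:06d}"
            counter += 1
            rows.append((pid, t.chrom, pos, pos + config.probe_len, "+", 1))
            truth_rows.append((pid, "clean", t.id))

    n_clean = len(truth_rows)
    chroms = sorted(annotation.chroms)
    coding = annotation.coding

    for _ in range(round(config.decoy_rates.get("zero_hit", 0) * n_clean)):
        pid = f"probe{counter:06d}"
        counter += 1
        rows.append((pid, pd.NA, pd.NA, pd.NA, pd.NA, 0))
        truth_rows.append((pid, "zero_hit", ""))

    for _ in range(round(config.decoy_rates.get("multi_hit", 0) * n_clean)):
        pid = f"probe{counter:06d}"
        counter += 1
        for _hit in range(2):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, config.chrom_length - config.probe_len))
            rows.append((pid, chrom, pos, pos + config.probe_len, "+", 2))
        truth_rows.append((pid, "multi_hit", ""))

    for _ in range(round(config.decoy_rates.get("coding_overlap", 0) * n_clean)):
        gene = coding[int(rng.integers(len(coding)))]
        pos = int(rng.integers(gene.span.start, gene.span.end - config.probe_len))
        pid = f"probe{counter:06d}"
        counter += 1
        rows.append((pid, gene.chrom, pos, pos + config.probe_len, "+", 1))
        truth_rows.append((pid, "coding_overlap", ""))

    probes = pd.DataFrame(rows, columns=io.PROBE_COLUMNS)
    probes["start"] = probes["start"].astype("Int64")
    probes["end"] = probes["end"].astype("Int64")
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "status", "transcript_id"])
    return probes, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    annotation: GenomeAnnotation,
    probe_truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Probe-level log2 intensity matrix with planted signature lncRNAs.

    log2 intensity = transcript baseline + probe offset + class effect
    (effect_size * noise_sd for that class's signature transcripts) +
    N(0, noise_sd). Decoy probes get probe-specific baselines and noise
    only. Returns (matrix, sample labels, per-class signature truth).
    """
    config.validate()
    rng = _streams(config)["expression"]
    samples = [
        f"{cls}_{i + 1}" for cls, n in config.classes.items() for i in range(n)
    ]
    labels = pd.Series(
        [cls for cls, n in config.classes.items() for _ in range(n)],
        index=samples,
        name="condition",
    )

    clean = probe_truth[probe_truth["status"] == "clean"]
    transcripts = sorted(clean["transcript_id"].unique())
    n_sig_total = config.n_signature_per_class * len(config.classes)
    if n_sig_total > len(transcripts):
        raise ValueError(
            f"cannot plant {n_sig_total} signature lncRNAs among "
            f"{len(transcripts)} probed transcripts"
        )
    chosen = rng.choice(len(transcripts), size=n_sig_total, replace=False)
    signature: dict[str, list[str]] = {}
    it = iter(chosen)
    for cls in config.classes:
        signature[cls] = sorted(
            transcripts[next(it)] for _ in range(config.n_signature_per_class)
        )

    baseline_t = {
        t: rng.normal(config.baseline_mean, config.baseline_sd) for t in transcripts
    }
    effect = config.effect_size * config.noise_sd
    sig_of_class = {
        cls: set(members) for cls, members in signature.items()
    }

    probe_ids = probe_truth["probe_id"].tolist()
    target = dict(zip(probe_truth["probe_id"], probe_truth["transcript_id"]))
    status = dict(zip(probe_truth["probe_id"], probe_truth["status"]))

    values = np.empty((len(probe_ids), len(samples)))
    for i, pid in enumerate(probe_ids):
        if status[pid] == "clean":
            base = baseline_t[target[pid]] + rng.normal(0, config.probe_offset_sd)
        else:
            base = rng.normal(config.baseline_mean, config.baseline_sd)
        row = np.full(len(samples), base)
        if status[pid] == "clean":
            for j, cls in enumerate(labels.values):
                if target[pid] in sig_of_class[cls]:
                    row[j] += effect
        values[i] = row + rng.normal(0, config.noise_sd, size=len(samples))

    matrix = pd.DataFrame(values, index=probe_ids, columns=samples)
    return matrix, labels, signature


def simulate_signature_matrix(
    n_features: int,
    classes: dict[str, int],
    n_signature_per_class: int,
    effect_size: float,
    noise_sd: float = 0.3,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Feature-level class-structured matrix with planted signatures.

    A direct (genome-free) generator for classifier and DE studies:
    log2 value = feature baseline + effect_size * noise_sd for that
    class's signature features + N(0, noise_sd). Signature blocks are
    disjoint across classes. Returns (matrix, labels, signature truth).
    """
    rng = np.random.default_rng(seed)
    n_sig_total = n_signature_per_class * len(classes)
    if n_sig_total > n_features:
        raise ValueError("more signature features requested than features")
    features = [f"f{i:05d}" for i in range(n_features)]
    samples = [f"{cls}_{i + 1}" for cls, n in classes.items() for i in range(n)]
    labels = pd.Series(
        [cls for cls, n in classes.items() for _ in range(n)],
        index=samples, name="condition",
    )
    chosen = rng.choice(n_features, size=n_sig_total, replace=False)
    signature: dict[str, list[str]] = {}
    for j, cls in enumerate(classes):
        block = chosen[j * n_signature_per_class : (j + 1) * n_signature_per_class]
        signature[cls] = sorted(features[i] for i in block)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)
    values = baseline[:, None] + rng.normal(0, noise_sd, size=(n_features, len(samples)))
    effect = effect_size * noise_sd
    feat_index = {f: i for i, f in enumerate(features)}
    for cls, members in signature.items():
        cols = np.flatnonzero((labels == cls).to_numpy())
        for f in members:
            values[feat_index[f]][cols] += effect
    return pd.DataFrame(values, index=features, columns=samples), labels, signature


# ---------------------------------------------------------------------------
# peaks


def _upstream_window(t: TranscriptModel, window_bp: int) -> tuple[int, int]:
    """Inclusive midpoint window [lo, hi] upstream of the TSS."""
    tss = tss_of(t)
    if t.strand == "+":
        return tss - window_bp, tss
    return tss, tss + window_bp


def simulate_peaks(
    annotation: GenomeAnnotation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant peaks upstream of a seeded fraction of lncRNA TSSs.

    A lncRNA is eligible when its full upstream window (plus peak-width
    margin) fits on the chromosome and contains positions outside every
    other lncRNA's window, so planted bound/unbound truth is exact.
    Background peaks are rejection-sampled outside all windows. Returns
    (peaks BED-frame, truth with eligible/bound flags).
    """
    config.validate()
    rng = _streams(config)["peaks"]
    w = config.proximity_bp  # promoter window mirrors the proximity window
    half = config.peak_width // 2

    lncs = [t for t in annotation.lncrnas if t.strand in "+-"]
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for t in lncs:
        lo, hi = _upstream_window(t, w)
        windows.setdefault(t.chrom, []).append((lo, hi, t.id))

    def in_other_window(chrom: str, m: int, own: str) -> bool:
        return any(lo <= m <= hi and tid != own for lo, hi, tid in windows.get(chrom, []))

    def in_any_window(chrom: str, m: int) -> bool:
        return any(lo <= m <= hi for lo, hi, _ in windows.get(chrom, []))

    eligible = []
    for t in lncs:
        lo, hi = _upstream_window(t, w)
        if lo - half < 0 or hi + half > config.chrom_length:
            logger.warning("lncRNA %s upstream window off chromosome edge; excluded", t.id)
            continue
        eligible.append(t)

    n_bound = round(config.bound_fraction * len(eligible))
    order = rng.permutation(len(eligible))
    bound_ids: set[str] = set()
    peaks = []
    pk = 0
    for idx in order:
        if len(bound_ids) >= n_bound:
            break
        t = eligible[idx]
        lo, hi = _upstream_window(t, w)
        placed = False
        for _ in range(200):
            m = int(rng.integers(lo, hi + 1))
            if not in_other_window(t.chrom, m, t.id):
                peaks.append((t.chrom, m - half, m - half + config.peak_width, f"peak{pk:04d}"))
                pk += 1
                placed = True
                break
        if placed:
            bound_ids.add(t.id)
        else:
            logger.warning("no exclusive upstream position for %s; skipped", t.id)

    for _ in range(config.n_background_peaks):
        for _try in range(500):
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            m = int(rng.integers(half, config.chrom_length - half))
            if not in_any_window(chrom, m):
                peaks.append((chrom, m - half, m - half + config.peak_width, f"peak{pk:04d}"))
                pk += 1
                break

    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
    truth = pd.DataFrame(
        {
            "transcript_id": [t.id for t in lncs],
            "eligible": [t.id in {e.id for e in eligible} for t in lncs],
            "bound": [t.id in bound_ids for t in lncs],
        }
    ).set_index("transcript_id").sort_index()
    return peaks_df, truth


# ---------------------------------------------------------------------------
# one-call generation


def simulate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir`` and return the paths.

    Writes the same file dialects the pipeline reads (GTF, TSV, BED) plus
    ``truth/*.tsv`` ground-truth tables.
    """
    out = io.ensure_dir(outdir)
    truth_dir = io.ensure_dir(out / "truth")

    annotation, categories = simulate_annotation(config)
    probes, probe_truth = simulate_probes(annotation, config)
    intensities, labels, signature = simulate_expression(annotation, probe_truth, config)
    peaks, peak_truth = simulate_peaks(annotation, config)

    paths = {
        "annotation": out / "annotation.gtf",
        "probes": out / "probes.tsv",
        "intensities": out / "intensities.tsv",
        "labels": out / "labels.tsv",
        "peaks": out / "peaks.bed",
        "config": out / "sim_config.yaml",
        "truth_categories": truth_dir / "categories.tsv",
        "truth_probes": truth_dir / "probes.tsv",
        "truth_signature": truth_dir / "signature.tsv",
        "truth_peaks": truth_dir / "peaks.tsv",
    }
    io.write_gtf(annotation, paths["annotation"])
    io.write_probe_table(probes, paths["probes"])
    io.write_matrix(intensities, paths["intensities"])
    io.write_labels(labels, paths["labels"])
    io.write_bed_peaks(peaks, paths["peaks"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    categories.rename_axis("transcript_id").to_frame().to_csv(
        paths["truth_categories"], sep="\t"
    )
    probe_truth.to_csv(paths["truth_probes"], sep="\t", index=False)
    sig_rows = [
        {"condition": cls, "transcript_id": tid}
        for cls, members in signature.items()
        for tid in members
    ]
    pd.DataFrame(sig_rows).to_csv(paths["truth_signature"], sep="\t", index=False)
    peak_truth.to_csv(paths["truth_peaks"], sep="\t")
    return paths
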