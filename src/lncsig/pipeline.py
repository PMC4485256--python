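"""Pipeline orchestration: staged runs, manifests, and reporting.

Stages (in dependency order): ``simulate`` -> ``annotate`` -> ``de`` ->
``promoters`` -> ``classify``. Each stage reads the file dialects the
library speaks, writes TSV outputs into the run directory, and records
row counts and SHA-256 checksums in a JSON manifest, so a rerun with the
same config and seed is byte-identical and every report number can be
re-derived from stage output files. Partial outputs of a failing stage
are removed and the error names the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, diffexpr, io, nsc, promoter, simulate

logger = logging.getLogger(__name__)

STAGES = ["simulate", "annotate", "de", "promoters", "classify"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sim_config(cfg: dict, seed: int | None) -> simulate.SimConfig:
    sim_kwargs = dict(cfg.get("simulate", {}))
    for key in ("coding_exon_count", "coding_exon_len", "coding_intron_len", "lnc_exon_len"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    config = simulate.SimConfig(**sim_kwargs)
    if seed is not None:
        config.seed = seed
    return config


def run_experiment(
    cfg: dict,
    outdir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the requested stages in order and write a run manifest.

    ``cfg`` holds per-stage parameter blocks (``simulate``, ``annotate``,
    ``de``, ``promoters``, ``classify``) plus optional ``inputs`` paths
    for runs that start from real files instead of the simulator.
    """
    out = io.ensure_dir(outdir)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    run_seed = seed if seed is not None else int(cfg.get("seed", 0))

    manifest: dict = {"seed": run_seed, "stages": {}, "config": cfg}
    paths: dict[str, Path] = {}

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "checksums": {k: _sha256(Path(v)) for k, v in outputs.items()},
            "counts": counts,
        }
        paths.update(outputs)

    def input_path(key: str, stage: str) -> Path:
        if key in paths:
            return Path(paths[key])
        p = cfg.get("inputs", {}).get(key)
        if p is None:
            raise StageError(stage, f"missing upstream output or input {key!r}")
        p = Path(p)
        if not p.exists():
            raise StageError(stage, f"input file not found: {p}")
        return p

    def stage_simulate() -> None:
        sim_cfg = _sim_config(cfg, run_seed)
        sim_paths = simulate.simulate_all(sim_cfg, out / "simulate")
        counts = {
            "annotation_lines": sum(1 for _ in open(sim_paths["annotation"])),
            "probe_rows": sum(1 for _ in open(sim_paths["probes"])) - 1,
        }
        record("simulate", sim_paths, counts)
        manifest["config"]["simulate_effective"] = dataclasses.asdict(sim_cfg)

    def stage_annotate() -> None:
        ann_dir = io.ensure_dir(out / "annotate")
        params = cfg.get("annotate", {})
        annotation = io.read_gtf(input_path("annotation", "annotate"))
        probes = io.read_probe_table(input_path("probes", "annotate"))
        intensities = io.read_matrix(input_path("intensities", "annotate"))

        filtered, report = annotate.filter_probes(probes, annotation)
        mapping = annotate.map_probes_to_lncrnas(filtered, annotation)
        expr = annotate.summarize_expression(
            intensities, mapping, min_probes=int(params.get("min_probes", 4))
        )
        categories = annotate.categorize_all(
            annotation, proximity_bp=int(params.get("proximity_bp", 10_000))
        )
        outputs = {
            "filtered_probes": ann_dir / "filtered_probes.tsv",
            "filter_report": ann_dir / "filter_report.json",
            "probe_mapping": ann_dir / "probe_mapping.tsv",
            "categories": ann_dir / "categories.tsv",
            "expression": ann_dir / "expression.tsv",
        }
        io.write_probe_table(filtered, outputs["filtered_probes"])
        with open(outputs["filter_report"], "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        mapping.mapping.rename_axis("probe_id").to_frame().to_csv(
            outputs["probe_mapping"], sep="\t"
        )
        cat_table = categories.rename_axis("transcript_id").to_frame()
        cat_table["n_probes"] = (
            mapping.probes_per_transcript.reindex(cat_table.index).fillna(0).astype(int)
        )
        cat_table.to_csv(outputs["categories"], sep="\t")
        io.write_matrix(expr, outputs["expression"])
        record(
            "annotate",
            outputs,
            {
                "probes_retained": report.retained,
                "probes_mapped": int(mapping.mapping.size),
                "lncrnas_with_probes": mapping.n_transcripts,
                "transcripts_expressed": int(expr.shape[0]),
            },
        )

    def stage_de() -> None:
        de_dir = io.ensure_dir(out / "de")
        params = cfg.get("de", {})
        expr = io.read_matrix(input_path("expression", "de"))
        labels = io.read_labels(input_path("labels", "de"))
        categories = None
        if "categories" in paths or cfg.get("inputs", {}).get("categories"):
            cat_df = pd.read_csv(input_path("categories", "de"), sep="\t", index_col=0)
            categories = cat_df["category"]
        reference = params.get("reference") or cfg.get("simulate", {}).get(
            "reference", simulate.SimConfig().reference
        )
        fc = float(params.get("fc", 2.0))
        config = diffexpr.DEConfig(
            fc_up=fc, fc_down=1.0 / fc, p_cutoff=float(params.get("p", 0.05))
        )
        conditions = [c for c in labels.unique() if c != reference]
        if not conditions:
            raise ValueError(f"no condition other than reference {reference!r}")
        outputs: dict[str, Path] = {}
        counts: dict[str, int] = {}
        up_sets: dict[str, set[str]] = {}
        for cond in conditions:
            res = diffexpr.fit_moderated_t(
                expr, labels, cond, reference, categories=categories
            )
            sel = diffexpr.select_de(res, config)
            key = f"de_{cond}_vs_{reference}"
            outputs[key] = de_dir / f"{key}.tsv"
            sel.rename_axis("feature").to_csv(outputs[key], sep="\t")
            up, down = diffexpr.de_sets(sel)
            up_sets[cond] = up
            counts[f"{cond}_up"] = len(up)
            counts[f"{cond}_down"] = len(down)
        if len(up_sets) >= 2:
            venn = diffexpr.intersect_de_sets(up_sets)
            outputs["venn_up"] = de_dir / "venn_up_regions.tsv"
            venn.to_csv(outputs["venn_up"], sep="\t", index=False)
        if categories is not None:
            universe = categories.dropna()
            union_up = set().union(*up_sets.values()) & set(universe.index)
            rows = []
            for cat in annotate.CATEGORIES:
                if (universe == cat).sum() == 0:
                    continue
                enr = diffexpr.category_enrichment(union_up, universe, cat)
                rows.append(
                    {
                        "category": cat,
                        "chi2": enr["chi2"],
                        "p": enr["p"],
                        "de_fraction_in_category": enr["de_fraction_in_category"],
                        "low_expected": enr["low_expected"],
                    }
                )
            outputs["enrichment"] = de_dir / "category_enrichment.tsv"
            pd.DataFrame(rows).to_csv(outputs["enrichment"], sep="\t", index=False)
        record("de", outputs, counts)

    def stage_promoters() -> None:
        pr_dir = io.ensure_dir(out / "promoters")
        params = cfg.get("promoters", {})
        annotation = io.read_gtf(input_path("annotation", "promoters"))
        peaks = io.read_bed_peaks(input_path("peaks", "promoters"))
        config = promoter.PromoterConfig(window_bp=int(params.get("window", 10_000)))
        lncs = [t for t in annotation.lncrnas if t.strand in "+-"]
        table = promoter.assign_peaks(lncs, peaks, config)
        n_bound, n_total, pct = promoter.fraction_bound(table["bound"])
        outputs = {"promoter_binding": pr_dir / "promoter_binding.tsv"}
        table.to_csv(outputs["promoter_binding"], sep="\t")
        record(
            "promoters",
            outputs,
            {"n_bound": n_bound, "n_total": n_total, "pct_bound_x10": int(round(pct * 10))},
        )

    def stage_classify() -> None:
        cl_dir = io.ensure_dir(out / "classify")
        params = cfg.get("classify", {})
        expr = io.read_matrix(input_path("expression", "classify"))
        labels = io.read_labels(input_path("labels", "classify"))
        priors = params.get("priors", "proportions")
        model = nsc.fit(expr, labels, priors=priors)
        grid = nsc.default_grid(model, n_points=int(params.get("grid", 30)))
        curve = nsc.cross_validate(
            expr, labels, grid=grid, folds=params.get("folds"),
            seed=run_seed, priors=priors,
        )
        delta_star = nsc.select_threshold(curve)
        shrunk = nsc.shrink(model, delta_star)
        signature = nsc.selected_genes(shrunk)
        scores = nsc.discriminant_scores(shrunk, expr)
        predictions = pd.DataFrame(
            {"true": labels.reindex(expr.columns), "predicted": scores.idxmin(axis=1)}
        ).join(scores.add_prefix("delta_"))
        outputs = {
            "threshold_curve": cl_dir / "threshold_curve.tsv",
            "signature": cl_dir / "signature.tsv",
            "predictions": cl_dir / "predictions.tsv",
            "selected_threshold": cl_dir / "selected_threshold.json",
        }
        curve.to_csv(outputs["threshold_curve"], sep="\t", index=False)
        signature.rename_axis("feature").to_csv(outputs["signature"], sep="\t")
        predictions.rename_axis("sample").to_csv(outputs["predictions"], sep="\t")
        at_star = curve.loc[curve["delta"] == delta_star].iloc[0]
        with open(outputs["selected_threshold"], "w") as fh:
            json.dump(
                {
                    "delta_star": delta_star,
                    "cv_error_at_delta_star": float(at_star["error"]),
                    "n_genes_at_delta_star": int(at_star["n_genes"]),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        record(
            "classify",
            outputs,
            {
                "n_signature_features": int(signature.shape[0]),
                "n_samples": int(expr.shape[1]),
            },
        )

    runners = {
        "simulate": stage_simulate,
        "annotate": stage_annotate,
        "de": stage_de,
        "promoters": stage_promoters,
        "classify": stage_classify,
    }
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            runners[stage]()
        except Exception as exc:
            stage_dir = out / stage
            if stage_dir.exists() and stage not in manifest["stages"]:
                shutil.rmtree(stage_dir, ignore_errors=True)
            if isinstance(exc, StageError):
                raise
            raise StageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def report(run_dir: str | Path, plots: bool = False) -> dict:
    """Summarize a completed run from its stage output files.

    Every reported number is re-derived from the TSVs on disk, never from
    in-memory state; sections whose stage outputs are absent are skipped
    with a notice. Optionally renders the threshold-curve plot.
    """
    run = Path(run_dir)
    summary: dict = {}

    cat_path = run / "annotate" / "categories.tsv"
    if cat_path.exists():
        cats = pd.read_csv(cat_path, sep="\t", index_col=0)
        summary["category_counts"] = cats["category"].value_counts().to_dict()
        rep_path = run / "annotate" / "filter_report.json"
        if rep_path.exists():
            with open(rep_path) as fh:
                summary["filter_report"] = json.load(fh)
    else:
        logger.info("report: annotate outputs absent; section skipped")

    de_dir = run / "de"
    if de_dir.exists():
        de_counts = {}
        for p in sorted(de_dir.glob("de_*.tsv")):
            tab = pd.read_csv(p, sep="\t", index_col=0)
            de_counts[p.stem] = {
                "up": int((tab["direction"] == "up").sum()),
                "down": int((tab["direction"] == "down").sum()),
            }
        summary["de_counts"] = de_counts
        venn_path = de_dir / "venn_up_regions.tsv"
        if venn_path.exists():
            venn = pd.read_csv(venn_path, sep="\t")
            summary["venn_up"] = dict(
                zip(venn["region"], venn["exclusive_count"].astype(int))
            )
    else:
        logger.info("report: de outputs absent; section skipped")

    bind_path = run / "promoters" / "promoter_binding.tsv"
    if bind_path.exists():
        bind = pd.read_csv(bind_path, sep="\t", index_col=0)
        n_bound, n_total, pct = promoter.fraction_bound(bind["bound"])
        summary["promoter_binding"] = {
            "n_bound": n_bound,
            "n_total": n_total,
            "pct_bound": pct,
        }
    else:
        logger.info("report: promoter outputs absent; section skipped")

    cl_dir = run / "classify"
    if (cl_dir / "predictions.tsv").exists():
        pred = pd.read_csv(cl_dir / "predictions.tsv", sep="\t", index_col=0)
        confusion = pd.crosstab(pred["true"], pred["predicted"])
        summary["confusion"] = {
            str(col): confusion[col].to_dict() for col in confusion.columns
        }
        with open(cl_dir / "selected_threshold.json") as fh:
            summary["threshold"] = json.load(fh)
        curve = pd.read_csv(cl_dir / "threshold_curve.tsv", sep="\t")
        summary["min_cv_error"] = float(curve["error"].min())
        if plots:
            _plot_threshold_curve(curve, run / "report_threshold_curve.png")
    else:
        logger.info("report: classify outputs absent; section skipped")

    with open(run / "report_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def _plot_threshold_curve(curve: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["delta"], curve["error"], "o-", label="overall")
    for col in curve.columns:
        if col.startswith("err_"):
            ax.plot(curve["delta"], curve[col], "--", alpha=0.6, label=col[4:])
    ax.set_xlabel("centroid shrinkage threshold")
    ax.set_ylabel("CV misclassification error")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
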