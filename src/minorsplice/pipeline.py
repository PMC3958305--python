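"""End-to-end orchestration: simulate -> quantify -> score -> rank -> events.

``run_all`` executes the stages in order, failing fast with stage-named
errors, and writes every intermediate table plus a JSON run manifest
(package/library versions, all parameters, seed, input checksums and
per-stage row counts) and a human-readable markdown report.  Logs go to
stderr with stage tags; TSV outputs never mix with logs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .annotation import (
    GeneModelSet,
    build_reference_pairs,
    read_gene_models,
    read_genome_tsv,
    read_intron_types,
)
from .cohort import CohortConfig, SplicingOutlierModel
from .errors import ConfigError, DataError, MinorspliceError
from .events import DEFAULT_MIN_SUPPORT, DEFAULT_WINDOW, detect_events
from .quantify import QuantParams, SampleScan, quantify_sample, quants_to_frame
from .scores import DetectionThresholds, compute_scores
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("minorsplice")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    inputs: dict = field(default_factory=dict)  # gtf, genome, intron_types, samples, sam_dir
    quantify: QuantParams = field(default_factory=QuantParams)
    detection: DetectionThresholds = field(default_factory=DetectionThresholds)
    pseudocount: float = 0.5
    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_support: int = DEFAULT_MIN_SUPPORT
    window: int = DEFAULT_WINDOW
    keep_sams: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        if not os.path.exists(path):
            raise ConfigError(f"run config not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"run config {path} must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "outdir" not in data:
            raise ConfigError("run config must set 'outdir'")
        kwargs = dict(
            outdir=data["outdir"],
            seed=int(data.get("seed", 0)),
            pseudocount=float(data.get("pseudocount", 0.5)),
            min_support=int(data.get("min_support", DEFAULT_MIN_SUPPORT)),
            window=int(data.get("window", DEFAULT_WINDOW)),
            keep_sams=bool(data.get("keep_sams", True)),
        )
        sim = data.get("simulate")
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", kwargs["seed"])
            for key in ("exon_length_range", "intron_length_range", "n_exons_range", "cryptic_offset_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulate"] = SimulationConfig(**sim)
            kwargs["simulate"].validate()
        kwargs["inputs"] = dict(data.get("inputs", {}))
        kwargs["quantify"] = QuantParams(**data.get("quantify", {}))
        kwargs["detection"] = DetectionThresholds(**data.get("detection", {}))
        kwargs["cohort"] = CohortConfig(**data.get("cohort", {}))
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            required = {"gtf", "genome", "intron_types", "samples", "sam_dir"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(
                    f"run config needs either a 'simulate' block or inputs {sorted(missing)}"
                )
            for key in required:
                if not os.path.exists(self.inputs[key]):
                    raise ConfigError(f"input {key} not found: {self.inputs[key]}")
        self.quantify.validate()
        self.cohort.validate()
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "inputs": self.inputs,
            "quantify": asdict(self.quantify),
            "detection": asdict(self.detection),
            "pseudocount": self.pseudocount,
            "cohort": asdict(self.cohort),
            "min_support": self.min_support,
            "window": self.window,
            "keep_sams": self.keep_sams,
        }


def _md5(path: str, limit: int = 64 * 1024 * 1024) -> str:
    h = hashlib.md5()
    size = 0
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
            size += len(chunk)
            if size > limit:
                return f"first{limit}bytes:{h.hexdigest()}"
    return h.hexdigest()


def _stage(name: str):
    logger.info("[%s] starting", name)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of output paths."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package": "minorsplice",
        "version": __version__,
        "libraries": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "pysam": pysam.__version__,
        },
        "parameters": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    out = {"outdir": outdir}
    truth = None

    try:
        if config.simulate is not None:
            _stage("simulate")
            paths = simulate_cohort(config.simulate, outdir)
            models: GeneModelSet = paths["state"].models
            affected = sorted(paths["state"].affected_genes)
            sam_paths = paths["sams"]
            samples_df = pd.read_csv(paths["samples"], sep="\t")
            truth = pd.read_csv(paths["truth"], sep="\t")
            for key in ("genome", "gtf", "intron_types", "samples", "truth"):
                manifest["inputs"][key] = {"path": paths[key], "md5": _md5(paths[key])}
            manifest["stages"]["simulate"] = {
                "n_genes": len(models.genes),
                "n_u12_genes": len(models.u12_genes()),
                "n_affected_genes": len(affected),
                "n_samples": len(samples_df),
            }
            out.update({k: paths[k] for k in ("genome", "gtf", "intron_types", "samples", "truth")})
        else:
            _stage("load-inputs")
            genome = read_genome_tsv(config.inputs["genome"])
            models = read_gene_models(config.inputs["gtf"], genome=genome)
            models, type_report = read_intron_types(config.inputs["intron_types"], models)
            samples_df = pd.read_csv(config.inputs["samples"], sep="\t")
            if not {"sample_id", "condition"} <= set(samples_df.columns):
                raise DataError("samples table needs columns sample_id, condition")
            sam_paths = {
                sid: os.path.join(config.inputs["sam_dir"], f"{sid}.sam")
                for sid in samples_df["sample_id"]
            }
            for sid, path in sam_paths.items():
                if not os.path.exists(path):
                    raise ConfigError(f"SAM for sample {sid} not found: {path}")
            for key in ("gtf", "genome", "intron_types", "samples"):
                manifest["inputs"][key] = {
                    "path": config.inputs[key],
                    "md5": _md5(config.inputs[key]),
                }
            manifest["stages"]["load-inputs"] = {
                "n_genes": len(models.genes),
                "intron_type_rows_skipped": type_report["n_skipped_rows"],
            }
            affected = []

        _stage("annotation")
        pairs, exclusions = build_reference_pairs(models)
        exclusion_path = os.path.join(outdir, "excluded_genes.tsv")
        pd.DataFrame(
            sorted(exclusions.items()), columns=["gene_id", "reason"]
        ).to_csv(exclusion_path, sep="\t", index=False)
        out["excluded_genes"] = exclusion_path
        manifest["stages"]["annotation"] = {
            "n_reference_pairs": len(pairs),
            "n_excluded_genes": len(exclusions),
        }

        _stage("quantify")
        conditions = dict(zip(samples_df["sample_id"], samples_df["condition"]))
        quant_frames = []
        scans: dict[str, SampleScan] = {}
        for sid in samples_df["sample_id"]:
            quants, scan = quantify_sample(
                sam_paths[sid], models, pairs, sid, params=config.quantify
            )
            scans[sid] = scan
            quant_frames.append(quants_to_frame(quants))
            logger.info("[quantify] %s: %d mapped reads", sid, scan.total_mapped)
            if not config.keep_sams and config.simulate is not None:
                os.remove(sam_paths[sid])
        quant_df = pd.concat(quant_frames, ignore_index=True)
        quant_path = os.path.join(outdir, "quant.tsv")
        quant_df.to_csv(quant_path, sep="\t", index=False)
        out["quant"] = quant_path
        manifest["stages"]["quantify"] = {"n_rows": len(quant_df)}

        _stage("score")
        scores = compute_scores(quant_df, pseudocount=config.pseudocount)
        from .scores import detection_filter

        detected, det_report = detection_filter(quant_df, config.detection)
        scores_path = os.path.join(outdir, "scores.tsv")
        scores.to_csv(scores_path, sep="\t", index=False)
        det_path = os.path.join(outdir, "detection_report.tsv")
        det_report.to_csv(det_path, sep="\t", index=False)
        out["scores"] = scores_path
        out["detection_report"] = det_path
        manifest["stages"]["score"] = {
            "n_quantified_genes": scores["gene_id"].nunique(),
            "n_detected_genes": len(detected),
        }

        _stage("rank")
        model = SplicingOutlierModel(
            scores[scores["gene_id"].isin(detected)], conditions, config=config.cohort
        )
        results = model.fit()
        ranked_path = os.path.join(outdir, "ranked.tsv")
        results.ranked.to_csv(ranked_path, sep="\t", index=False, float_format="%.6g")
        cv_path = os.path.join(outdir, "cv_report.tsv")
        results.cv_report.to_csv(cv_path, sep="\t", index=False, float_format="%.6g")
        out["ranked"] = ranked_path
        out["cv_report"] = cv_path
        manifest["stages"]["rank"] = {
            "n_ranked": len(results.ranked),
            "n_discarded_by_cv": results.n_discarded,
            "n_flagged": len(results.flagged_genes),
        }

        _stage("events")
        u12_by_gene = {g: models.genes[g].u12_introns for g in models.u12_genes()}
        events_df = detect_events(
            scans, models, u12_by_gene, conditions,
            min_support=config.min_support, window=config.window,
        )
        events_path = os.path.join(outdir, "events.tsv")
        events_df.to_csv(events_path, sep="\t", index=False, float_format="%.6g")
        out["events"] = events_path
        manifest["stages"]["events"] = {"n_event_rows": len(events_df)}

        _stage("report")
        manifest_path = os.path.join(outdir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        out["manifest"] = manifest_path
        report = make_report(outdir, affected_genes=affected)
        report_path = os.path.join(outdir, "report.md")
        with open(report_path, "w") as fh:
            fh.write(report)
        out["report"] = report_path
    except MinorspliceError:
        raise
    except Exception as exc:  # annotate unexpected errors with stage context
        raise DataError(f"pipeline failed: {exc}") from exc
    return out


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{name}: missing column(s) {missing}")


def make_report(outdir: str, affected_genes: Optional[list[str]] = None) -> str:
    """Render a markdown summary from the stage outputs in ``outdir``."""
    ranked = pd.read_csv(os.path.join(outdir, "ranked.tsv"), sep="\t")
    _require_columns(
        ranked, ["gene_id", "flagged", "n_flagged_metrics", "rank_score", "rank"], "ranked.tsv"
    )
    det = pd.read_csv(os.path.join(outdir, "detection_report.tsv"), sep="\t")
    _require_columns(det, ["gene_id", "detected"], "detection_report.tsv")
    cv = pd.read_csv(os.path.join(outdir, "cv_report.tsv"), sep="\t")
    _require_columns(cv, ["gene_id", "discarded"], "cv_report.tsv")
    events_path = os.path.join(outdir, "events.tsv")
    events = pd.read_csv(events_path, sep="\t") if os.path.getsize(events_path) else pd.DataFrame()

    flagged = ranked[ranked["flagged"]]
    lines = ["# minorsplice run report", ""]
    n_det = int(det["detected"].sum())
    lines.append(
        f"- genes detected at sufficient levels: {n_det}/{len(det)} "
        f"({100.0 * n_det / max(len(det), 1):.1f}%)"
    )
    lines.append(f"- genes discarded for high control variability: {int(cv['discarded'].sum())}")
    if len(flagged) == 0:
        lines.append("- flagged genes: none (zero genes beyond threshold)")
    else:
        lines.append(f"- flagged genes: {len(flagged)}")
        lines.append("")
        lines.append("## Flagged genes")
        lines.append("")
        zcols = [c for c in ranked.columns if c.startswith("z_")]
        lines.append(flagged[["rank", "gene_id"] + zcols + ["n_flagged_metrics"]].to_string(index=False))
    if affected_genes:
        hits = sorted(set(affected_genes) & set(flagged["gene_id"]))
        missed = sorted(set(affected_genes) - set(flagged["gene_id"]))
        lines.append("")
        lines.append("## Simulated truth cross-check")
        lines.append("")
        lines.append(f"- simulated affected genes flagged: {len(hits)}/{len(affected_genes)}")
        if hits:
            lines.append(f"- flagged & affected: {', '.join(hits)}")
        if missed:
            lines.append(f"- affected but not flagged: {', '.join(missed)}")
    if len(events):
        _require_columns(events, ["gene_id", "event_class", "case_fraction"], "events.tsv")
        top = (
            events.drop_duplicates(["gene_id", "chrom", "donor", "acceptor"])
            .sort_values("case_fraction", ascending=False)
            .head(10)
        )
        lines.append("")
        lines.append("## Top aberrant events (by pooled case fraction)")
        lines.append("")
        lines.append(
            top[
                ["gene_id", "event_class", "donor", "acceptor", "case_fraction", "control_fraction", "case_exclusive"]
            ].to_string(index=False)
        )
    lines.append("")
    return "\n".join(lines)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("minorsplice")
    root.handlers[:] = [handler]
    root.setLevel(logging.INFO if verbose else logging.WARNING)
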