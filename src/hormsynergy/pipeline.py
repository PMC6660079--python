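"""End-to-end orchestration: config, stage running, reports, heatmap.

A single declarative config names the inputs, thresholds and stages;
``run_pipeline`` executes the requested stages, writes every stage
table plus ``report.json``, and returns the report. Reruns with the
same config and inputs are byte-identical except for the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ExpressionMatrix, TREATMENTS
from .mapping import (
    classify_cohort,
    read_bed,
    read_gene_loci,
    sample_control_genes,
    summarize_fractions,
)
from .model import HormoneTreatmentModel
from .thresholds import Thresholds

log = logging.getLogger("hormsynergy")

TRACK_NAMES = ("GR", "TR", "H3K27Ac", "MED1", "MED12", "POL2")


@dataclass
class PipelineConfig:
    """Declarative run configuration (see ``PipelineConfig.from_yaml``)."""

    expression_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    gene_loci_path: str | None = None
    track_paths: dict[str, str] = field(default_factory=dict)
    cohort_genes_path: str | None = None  # symbols, one per line; default: synergy genes
    thresholds: Thresholds = field(default_factory=Thresholds)
    synergy_mode: str = "baseline_corrected"
    de_test: str = "welch"
    de_test_scale: str = "log2"
    stages: tuple[str, ...] = ("expression", "mapping")
    output_dir: str = "hormsynergy_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds.from_dict(raw.pop("thresholds", {}))
        stages = tuple(raw.pop("stages", ("expression", "mapping")))
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        return cls(thresholds=thresholds, stages=stages, **known)

    def config_hash(self) -> str:
        # analysis-relevant fields only: where the outputs go and how
        # chatty the log is do not change the results
        payload = {
            k: (v.to_dict() if isinstance(v, Thresholds) else v)
            for k, v in vars(self).items()
            if k not in ("output_dir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def row_scale(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each row to [0, 1] (heatmap convention).

    The row minimum maps to 0 (deepest blue) and the maximum to 1
    (deepest red); a constant row maps to 0.5 everywhere. Invariant to
    any positive affine transform of a row.
    """
    frame = matrix.signals if isinstance(matrix, ExpressionMatrix) else matrix
    arr = frame.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span == 0
    span = np.where(flat, 1.0, span)
    scaled = (arr - lo) / span
    scaled = np.where(flat, 0.5, scaled)
    return pd.DataFrame(scaled, index=frame.index, columns=frame.columns)


def _expression_stage(config: PipelineConfig, outdir: Path) -> dict:
    if not config.expression_path or not config.design_path:
        raise FileNotFoundError(
            "stage 'expression' needs expression_path and design_path"
        )
    model = HormoneTreatmentModel.from_files(
        config.expression_path,
        config.design_path,
        config.annotation_path,
        thresholds=config.thresholds,
        synergy_mode=config.synergy_mode,
        test=config.de_test,
        test_scale=config.de_test_scale,
    )
    results = model.fit()
    results.to_directory(outdir)

    # heatmap: row-scaled per-treatment mean signals of the DE probes
    de_any = (results.de_calls != "ns").any(axis=1)
    means = results.probe_stats.loc[de_any, [f"mean_{t}" for t in TREATMENTS]]
    row_scale(means).rename_axis("probe_id").to_csv(
        outdir / "heatmap_scaled.tsv", sep="\t"
    )

    (outdir / "summary.txt").write_text(results.summary() + "\n")
    report = {
        "de_counts": results.de_counts,
        "section_counts": results.section_counts,
        "code_counts": results.code_counts,
        "synergy_counts": results.synergy_counts,
        "partition_identities": results.partition_identities,
    }
    if results.collapse is not None:
        report["n_unannotated_probes"] = results.collapse.n_unannotated
        report["n_collapse_conflicts"] = results.collapse.n_conflicts
    # hand the synergy gene/probe list to the mapping stage
    syn_probes = results.synergy.index[results.synergy["criterion"] != "none"]
    if results.collapse is not None:
        genes = results.collapse.genes
        syn_symbols = sorted(
            set(genes.loc[genes["probe_id"].isin(syn_probes), "gene_symbol"])
        )
    else:
        syn_symbols = sorted(syn_probes)
    (outdir / "synergy_gene_symbols.txt").write_text(
        "\n".join(syn_symbols) + ("\n" if syn_symbols else "")
    )
    report["_synergy_symbols"] = syn_symbols
    report["_de_probe_symbols"] = _de_symbols(results)
    return report


def _de_symbols(results) -> list[str]:
    de_any = (results.de_calls != "ns").any(axis=1)
    probes = results.de_calls.index[de_any]
    if results.collapse is not None:
        genes = results.collapse.genes
        return sorted(set(genes.loc[genes["probe_id"].isin(probes), "gene_symbol"]))
    return sorted(probes)


def _mapping_stage(
    config: PipelineConfig,
    outdir: Path,
    cohort_symbols: list[str] | None,
    exclude_symbols: list[str],
) -> dict:
    if not config.gene_loci_path:
        raise FileNotFoundError("stage 'mapping' needs gene_loci_path")
    loci = read_gene_loci(config.gene_loci_path)
    tracks = {
        name: read_bed(path) for name, path in config.track_paths.items()
    }
    unknown = set(tracks) - set(TRACK_NAMES)
    if unknown:
        raise ValueError(f"unknown track names {sorted(unknown)}")
    # all inputs must share one assembly: chromosome names must overlap
    loci_chroms = set(loci["chrom"])
    for name, track in tracks.items():
        if len(track) and not (set(track["chrom"]) & loci_chroms):
            raise ValueError(
                f"track {name} shares no chromosome names with the gene "
                "loci; inputs must be on one assembly"
            )

    if config.cohort_genes_path:
        cohort_symbols = [
            s.strip()
            for s in Path(config.cohort_genes_path).read_text().splitlines()
            if s.strip()
        ]
    if cohort_symbols is None:
        raise FileNotFoundError(
            "stage 'mapping' needs cohort_genes_path when the expression "
            "stage is not run"
        )
    cohort = loci[loci["gene_symbol"].isin(cohort_symbols)]
    missing = sorted(set(cohort_symbols) - set(cohort["gene_symbol"]))
    if missing:
        log.info("no genomic coordinates for %d cohort genes", len(missing))
    if cohort.empty:
        raise ValueError("no cohort gene has coordinates in the loci table")

    th = config.thresholds
    classes = classify_cohort(cohort, tracks, th)
    classes.to_csv(outdir / "coloc_classes.tsv", sep="\t")
    summary = {"cohort": summarize_fractions(classes)}

    n_control = min(
        th.n_control_genes,
        len(loci) - len(set(exclude_symbols) & set(loci["gene_symbol"])),
    )
    control = sample_control_genes(loci, exclude_symbols, n_control, th.rng_seed)
    control_classes = classify_cohort(control, tracks, th)
    control_classes.to_csv(outdir / "coloc_classes_control.tsv", sep="\t")
    summary["control"] = summarize_fractions(control_classes)
    summary["n_cohort_without_coordinates"] = len(missing)
    with open(outdir / "coloc_summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and write ``report.json``.

    Returns the report dictionary. Raises on a missing stage input,
    naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "thresholds": config.thresholds.to_dict(),
        "stages": list(config.stages),
        "coloc": None,
    }

    cohort_symbols: list[str] | None = None
    exclude_symbols: list[str] = []
    if "expression" in config.stages:
        log.info("running expression stage")
        expr = _expression_stage(config, outdir)
        cohort_symbols = expr.pop("_synergy_symbols")
        exclude_symbols = expr.pop("_de_probe_symbols")
        report["expression"] = expr
    if "mapping" in config.stages:
        log.info("running mapping stage")
        report["coloc"] = _mapping_stage(
            config, outdir, cohort_symbols, exclude_symbols
        )

    report["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
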