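"""End-to-end orchestration: preprocess -> fit -> cluster -> impute -> interpret.

The pipeline is a pure function of (input matrix, config): every stochastic
stage draws from seeds recorded in the config, so a rerun with the same
inputs reproduces the feature matrix byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import gmvae, interpret, preprocess as pp
from .matrix_io import PeakByCellMatrix, write_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested stage configs plus pipeline-level switches.

    ``k`` may be an integer or ``"auto"`` (Tracy-Widom estimate from the
    binarized matrix). ``out_dir`` of None keeps everything in memory.
    """

    filter: pp.FilterConfig = field(default_factory=pp.FilterConfig)
    train: gmvae.TrainConfig = field(default_factory=gmvae.TrainConfig)
    k: int | str = 3
    kmeans_seed: int = cl.DEFAULT_KMEANS_SEED
    specificity_top: int = 200
    feature_cutoff_sd: float = 2.5
    out_dir: str | Path | None = None
    skip_filters: bool = False


@dataclass
class PipelineResult:
    binarized: PeakByCellMatrix
    model: gmvae.GMVAE
    features: np.ndarray
    assignment: cl.ClusterAssignment
    imputed: np.ndarray
    imputed_binary: np.ndarray
    metrics: cl.MetricReport | None
    specificity: pd.DataFrame
    feature_associations: list[interpret.FeaturePeakAssociation]
    report: dict


def _stage(report: dict, name: str, start: float, **info) -> None:
    report[name] = {"seconds": round(time.perf_counter() - start, 3), **info}
    log.info("stage %s done in %.2fs %s", name, report[name]["seconds"], info)


def run_pipeline(m: PeakByCellMatrix, cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in order on a raw peak-by-cell count matrix."""
    report: dict = {"input": {"n_peaks": m.n_peaks, "n_cells": m.n_cells}}

    t0 = time.perf_counter()
    if cfg.skip_filters:
        raw = m
    else:
        raw = pp.filter_peaks(m, cfg.filter)
        raw = pp.filter_cells(raw, cfg.filter)
        if cfg.filter.rare_ubiquitous_x is not None:
            raw = pp.drop_rare_ubiquitous(raw, cfg.filter.rare_ubiquitous_x)
    binarized = pp.binarize_input(raw)
    _stage(report, "preprocess", t0,
           n_peaks=binarized.n_peaks, n_cells=binarized.n_cells)

    t0 = time.perf_counter()
    if cfg.k == "auto":
        k = cl.estimate_k(binarized)
        k = max(k, 2)
        log.info("estimated number of clusters: %d", k)
    else:
        k = int(cfg.k)
    train_cfg = dataclasses.replace(cfg.train, k=k)
    model = gmvae.fit(binarized, train_cfg)
    _stage(report, "fit", t0, k=k, seed=train_cfg.seed,
           final_elbo=model.history[-1]["elbo"])

    t0 = time.perf_counter()
    features = gmvae.extract_features(binarized, model)
    assignment = cl.kmeans_cluster(features, k, seed=cfg.kmeans_seed)
    metrics = None
    if raw.labels is not None:
        metrics = cl.evaluate(assignment, raw.labels)
    _stage(report, "cluster", t0, seed=cfg.kmeans_seed,
           metrics=metrics.as_dict() if metrics else None)

    t0 = time.perf_counter()
    imputed = gmvae.impute(binarized, model)
    imputed_binary = interpret.binarize_imputed(imputed, raw)
    specificity = interpret.specificity_score(imputed, assignment.labels)
    assoc = interpret.feature_peaks(model.params["Wd"].T, cfg.feature_cutoff_sd)
    _stage(report, "interpret", t0)

    result = PipelineResult(binarized, model, features, assignment, imputed,
                            imputed_binary, metrics, specificity, assoc, report)
    if cfg.out_dir is not None:
        _write_outputs(result, raw, Path(cfg.out_dir))
    return result


def _write_outputs(res: PipelineResult, raw: PeakByCellMatrix, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    d = res.features.shape[1]
    pd.DataFrame(res.features, index=raw.cells,
                 columns=[f"feature_{i}" for i in range(d)]).to_csv(
        out / "features.tsv", sep="\t")
    pd.DataFrame({"cell": raw.cells, "cluster": res.assignment.labels}).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(res.imputed, index=raw.peak_ids(), columns=raw.cells).to_csv(
        out / "imputed.tsv", sep="\t", float_format="%.6g")
    write_matrix(raw.with_values(res.imputed_binary), out / "imputed_binary")
    res.specificity.to_csv(out / "specificity.tsv", sep="\t")
    with open(out / "feature_peaks.tsv", "w") as fh:
        fh.write("feature\tpeak_index\tpeak\tweight\n")
        ids = raw.peak_ids()
        for a in res.feature_associations:
            for i, w in zip(a.peaks, a.weights):
                fh.write(f"{a.feature}\t{i}\t{ids[i]}\t{w:.6g}\n")
    res.model.save(out / "model")
    if res.metrics is not None:
        (out / "metrics.json").write_text(
            json.dumps(res.metrics.as_dict(), indent=1))
    (out / "run_report.json").write_text(json.dumps(res.report, indent=1))
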