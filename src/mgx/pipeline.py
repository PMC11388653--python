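"""Orchestration: simulate/load -> reduce -> (select) -> classify -> evaluate,
as one reproducible run with a manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dimred import ReducedFeatureMatrix, reduce_dimensions
from .evaluation import CvResult, MetricsRecord, compute_metrics, tenfold_cv_imbalanced
from .io_formats import ExpressionMatrix, RunConfig

_DR_CACHE: dict[tuple, ReducedFeatureMatrix] = {}


@dataclass
class RunManifest:
    """Enough to re-run a pipeline invocation identically."""

    config: dict
    seed: int
    input_hash: str
    stage_timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _hash_matrix(matrix: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    h.update("|".join(matrix.labels).encode())
    return h.hexdigest()


def run_pipeline(config: RunConfig, data: ExpressionMatrix,
                 use_cache: bool = True) -> tuple[MetricsRecord, CvResult, RunManifest]:
    """Execute DR, optional in-fold feature selection, CV classification and metrics.

    DR outputs are cached by (input hash, method, target_dim) because they
    are classifier-independent, so grid runs reuse them.
    """
    input_hash = _hash_matrix(data)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed,
                           input_hash=input_hash)

    t0 = time.perf_counter()
    target_dim = min(config.target_dim, data.n_genes)
    cache_key = (input_hash, config.dr_method, target_dim)
    if use_cache and cache_key in _DR_CACHE:
        reduced = _DR_CACHE[cache_key]
    else:
        reduced = reduce_dimensions(data, config.dr_method, target_dim)
        if use_cache:
            _DR_CACHE[cache_key] = reduced
    manifest.stage_timings["reduce"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cv = tenfold_cv_imbalanced(reduced, config=config)
    manifest.stage_timings["evaluate"] = time.perf_counter() - t0

    record = compute_metrics(cv.confusion)
    record.dr_method = config.dr_method
    record.fsel_method = config.fsel_method
    record.classifier = config.classifier
    manifest.outputs["confusion"] = dataclasses.asdict(cv.confusion)
    manifest.outputs["metrics"] = {k: getattr(record, k)
                                   for k in ("acc", "f1", "mcc", "er", "ji", "csi",
                                             "gmean", "kappa")}
    manifest.outputs["monitor_mse"] = cv.monitor_mse
    return record, cv, manifest


def run_grid(data: ExpressionMatrix, base_config: RunConfig,
             dr_methods=("HT", "DFA", "LSLR"),
             fsel_methods=("none", "EHO", "CS"),
             classifiers=("BLDC", "NBC", "RFC", "DTC", "SVM_linear", "SVM_poly", "SVM_rbf"),
             ) -> list[MetricsRecord]:
    """The full (or any sub-) grid of DR x FSEL x classifier conditions."""
    records = []
    for dr in dr_methods:
        for fs in fsel_methods:
            for clf in classifiers:
                cfg = dataclasses.replace(base_config, dr_method=dr,
                                          fsel_method=fs, classifier=clf)
                record, _, _ = run_pipeline(cfg, data)
                records.append(record)
    return records
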