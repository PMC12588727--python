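"""End-to-end orchestration: simulate/ingest → OR grid → selection → models → integration.

Stages are independent: each draws its RNG from a per-stage substream spawned
off the global seed, so disabling one stage never changes another's output,
and a rerun with the same config and seed is byte-identical. Every emitted
file is listed, with a SHA-256 checksum, in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import OutbreedingError, SchemaError
from .fitness import selection_table
from .integration import integration_table
from .models import build_model_frame, fit_or_mixed_model, scheirer_ray_hare
from .orstats import or_table
from .simulate import CohortSpec, generate_cohort
from .traits import COMPARISONS, HET_CLASSES, PLOIDIES, TRAIT_BY_NAME, read_table, trait_columns, validate_table

logger = logging.getLogger(__name__)

STAGES = ("or", "selection", "models", "integration")

# fixed substream indices so that disabling a stage never shifts the others
_STAGE_STREAM = {"simulate": 0, "or": 1, "selection": 2, "models": 3, "integration": 4}


@dataclass
class PipelineConfig:
    """Configuration for a full run; defaults follow the study's analysis choices."""

    input: str | None = None            # cohort CSV; None -> simulate
    cohort_spec: CohortSpec | None = None
    n_boot_or: int = 100_000
    n_boot_pint: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "outbreeding-results"
    stages: tuple[str, ...] = STAGES


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed).spawn(len(_STAGE_STREAM))[_STAGE_STREAM[stage]]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_input(path) -> dict:
    """Diagnostics for a cohort CSV: schema, vocabularies, support, group sizes."""
    table = pd.read_csv(path, encoding="utf-8", keep_default_na=False, na_values=[""])
    issues: list[str] = []
    try:
        validate_table(table)
    except SchemaError as exc:
        issues.append(str(exc))
    for name in trait_columns(table):
        col = pd.to_numeric(table[name], errors="coerce")
        kind = TRAIT_BY_NAME[name].kind
        bad = pd.Series(False, index=table.index)
        if kind == "proportion":
            bad = (col < 0) | (col > 1)
        elif kind == "binary":
            bad = col.notna() & ~col.isin([0, 1])
        elif kind == "count":
            bad = col.notna() & ((col < 0) | (col != np.floor(col)))
        elif kind == "positive-continuous":
            bad = col.notna() & (col <= 0)
        for row in np.flatnonzero(bad.to_numpy()):
            issues.append(f"{name}: out-of-support value {table[name].iloc[row]!r} (row {row + 1})")
    sizes = {}
    if {"ploidy", "het_class"} <= set(table.columns):
        for p in PLOIDIES:
            for h in HET_CLASSES:
                sizes[f"{p}x/{h}"] = int(
                    ((table["ploidy"] == p) & (table["het_class"] == h)).sum())
    return {"n_rows": len(table), "issues": issues, "group_sizes": sizes}


def run_all(config: PipelineConfig) -> dict:
    """Run the configured stages; write outputs and return the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            "input": config.input, "n_boot_or": config.n_boot_or,
            "n_boot_pint": config.n_boot_pint, "alpha": config.alpha,
            "seed": config.seed, "stages": list(config.stages),
        },
        "stages": {}, "files": {},
    }

    if config.input is not None:
        cohort = read_table(config.input)
        logger.info("loaded cohort: %d plants from %s", len(cohort), config.input)
    else:
        spec = config.cohort_spec or CohortSpec()
        spec = spec.with_seed(int(_stage_seed(config.seed, "simulate").generate_state(1)[0] % (2**31)))
        cohort = generate_cohort(spec)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        manifest["files"]["cohort.csv"] = _sha256(cohort_path)
        logger.info("simulated cohort: %d plants", len(cohort))

    def _run_stage(name, fn):
        start = time.time()
        try:
            info = fn() or {}
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - start, 2), **info}
        except OutbreedingError as exc:
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {
                "status": "failed", "error": str(exc),
                "seconds": round(time.time() - start, 2),
            }

    or_results: pd.DataFrame | None = None

    if "or" in config.stages:
        def _or():
            nonlocal or_results
            seed = int(_stage_seed(config.seed, "or").generate_state(1)[0] % (2**31))
            or_results = or_table(cohort, n_boot=config.n_boot_or,
                                  alpha=config.alpha, seed=seed)
            path = out / "or.csv"
            or_results.to_csv(path, index=False)
            manifest["files"]["or.csv"] = _sha256(path)
            return {"rows": len(or_results)}
        _run_stage("or", _or)

    if "selection" in config.stages:
        def _sel():
            sel = selection_table(cohort)
            path = out / "selection.csv"
            sel.to_csv(path, index=False)
            manifest["files"]["selection.csv"] = _sha256(path)
            return {"rows": len(sel)}
        _run_stage("selection", _sel)

    if "models" in config.stages:
        def _models():
            if or_results is None:
                raise OutbreedingError("models stage requires the or stage")
            result = {}
            for comparison in COMPARISONS:
                frame = build_model_frame(or_results, comparison)
                mm = fit_or_mixed_model(frame)
                srh = scheirer_ray_hare(frame)
                result[comparison] = {
                    "mixed_model": {
                        "fixed": mm.fixed.round(6).to_dict(orient="index"),
                        "trait_variance": mm.trait_variance, "trait_sd": mm.trait_sd,
                        "residual_variance": mm.residual_variance,
                        "boundary": mm.boundary, "converged": mm.converged,
                        "reference": mm.reference, "n_obs": mm.n_obs,
                    },
                    "scheirer_ray_hare": srh.table.round(6).to_dict(orient="index"),
                }
            path = out / "model.json"
            path.write_text(json.dumps(result, indent=2, default=float))
            manifest["files"]["model.json"] = _sha256(path)
            return {"comparisons": list(result)}
        _run_stage("models", _models)

    if "integration" in config.stages:
        def _integ():
            seed = int(_stage_seed(config.seed, "integration").generate_state(1)[0] % (2**31))
            indices, counts = integration_table(
                cohort, alpha=config.alpha, n_boot=config.n_boot_pint, seed=seed)
            ipath, cpath = out / "integration.csv", out / "counts.csv"
            indices.to_csv(ipath, index=False)
            counts.to_csv(cpath, index=False)
            manifest["files"]["integration.csv"] = _sha256(ipath)
            manifest["files"]["counts.csv"] = _sha256(cpath)
            return {"groups": len(indices)}
        _run_stage("integration", _integ)

    manifest["wall_clock_seconds"] = round(time.time() - t0, 2)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
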