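"""End-to-end orchestration: call UTRs, classify, correlate, validate.

``run_full`` composes the stages into one reproducible run: every stage
output is a pure function of (inputs, parameters, seed), and the manifest
written at the end records package/library versions, all parameters, the
seed and SHA-256 checksums of every input file — enough to reproduce the
run exactly.  Logging (stage timings) goes to stderr; results never do.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from .annotation_io import Annotation, read_bed, read_gff, write_pairs
from .cross_validation import (
    summarize_validation,
    validate_pairs,
    write_validation_records,
)
from .expression_stats import (
    ExpressionMatrix,
    correlate_all_conditions,
    write_correlation_results,
)
from .pair_classifier import classify_adjacent_pairs, summarize
from .utr_caller import (
    CoverageTrack,
    UtrCallParams,
    call_all,
    count_utr_genes,
    write_transcript_models,
)

logger = logging.getLogger("convutr")


class MissingInputError(FileNotFoundError):
    """A configured input file does not exist (raised before any work)."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; flags mirror these keys."""

    annotation: Path
    cov_plus: Path
    cov_minus: Path
    expression: Optional[Path] = None
    expression_scale: str = "log2"
    validation_annotation: Optional[Path] = None
    validation_cov_plus: Optional[Path] = None
    validation_cov_minus: Optional[Path] = None
    params: UtrCallParams = field(default_factory=UtrCallParams)
    n_perm: int = 10_000
    seed: int = 0
    outdir: Path = Path("convutr_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = UtrCallParams(**raw.pop("utr_params", {}))
        paths = {
            k: Path(v)
            for k, v in raw.items()
            if k
            in (
                "annotation",
                "cov_plus",
                "cov_minus",
                "expression",
                "validation_annotation",
                "validation_cov_plus",
                "validation_cov_minus",
                "outdir",
            )
            and v is not None
        }
        rest = {
            k: v
            for k, v in raw.items()
            if k in ("expression_scale", "n_perm", "seed")
        }
        return cls(params=params, **paths, **rest)


def _read_annotation(path: Path) -> Annotation:
    if path.suffix.lower() in (".bed", ".bed6"):
        return read_bed(path)
    return read_gff(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _timed(name: str, start: float) -> None:
    logger.info("stage %-12s %.2fs", name, time.perf_counter() - start)


def run_full(config: PipelineConfig) -> Dict:
    """Execute call-utrs -> classify -> correlate -> (optional) validate.

    Returns the manifest dict, also written to ``<outdir>/manifest.json``.
    Raises :class:`MissingInputError` before any computation if a configured
    input is absent.
    """
    inputs = {
        "annotation": config.annotation,
        "cov_plus": config.cov_plus,
        "cov_minus": config.cov_minus,
    }
    if config.expression is not None:
        inputs["expression"] = config.expression
    if config.validation_annotation is not None:
        inputs["validation_annotation"] = config.validation_annotation
        inputs["validation_cov_plus"] = config.validation_cov_plus
        inputs["validation_cov_minus"] = config.validation_cov_minus
    for name, path in inputs.items():
        if path is None or not Path(path).exists():
            raise MissingInputError(f"input {name!r} missing: {path}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import numpy, pandas, scipy  # versions for the manifest

    manifest: Dict = {
        "convutr_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "parameters": {
            "min_cov": config.params.min_cov,
            "max_gap": config.params.max_gap,
            "max_utr_len": config.params.max_utr_len,
            "expr_min_mean_cov": config.params.expr_min_mean_cov,
            "n_perm": config.n_perm,
        },
        "seed": config.seed,
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(Path(path))}
            for name, path in inputs.items()
        },
        "outputs": {},
    }

    t0 = time.perf_counter()
    annot = _read_annotation(Path(config.annotation))
    cov = CoverageTrack.from_bedgraph(
        config.cov_plus, config.cov_minus, annot.chrom_lengths
    )
    _timed("load", t0)

    t0 = time.perf_counter()
    models = call_all(annot, cov, config.params)
    n_utr5, n_utr3 = count_utr_genes(models)
    models_path = outdir / "transcript_models.tsv"
    write_transcript_models(models, models_path)
    manifest["outputs"]["transcript_models"] = str(models_path)
    manifest["n_genes_with_utr5"] = n_utr5
    manifest["n_genes_with_utr3"] = n_utr3
    _timed("call-utrs", t0)

    t0 = time.perf_counter()
    pairs = classify_adjacent_pairs(models)
    pairs_path = outdir / "pairs.tsv"
    write_pairs(pairs, pairs_path)
    summary = summarize(pairs, annot)
    summary_path = outdir / "classification_summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=2))
    manifest["outputs"]["pairs"] = str(pairs_path)
    manifest["outputs"]["classification_summary"] = str(summary_path)
    manifest["classification"] = summary.to_dict()
    _timed("classify", t0)

    convergent = [p for p in pairs if p.pair_class == "convergent"]

    if config.expression is not None:
        t0 = time.perf_counter()
        expr = ExpressionMatrix.read_tsv(
            config.expression, scale=config.expression_scale
        )
        multi = correlate_all_conditions(
            convergent, expr, n_perm=config.n_perm, seed=config.seed
        )
        corr_path = outdir / "pair_correlations.tsv"
        write_correlation_results(multi.results, corr_path)
        manifest["outputs"]["pair_correlations"] = str(corr_path)
        manifest["correlation"] = {
            "r_min": multi.r_min,
            "r_max": multi.r_max,
            "n_conditions": len(multi.results),
        }
        _timed("correlate", t0)

    if config.validation_annotation is not None:
        t0 = time.perf_counter()
        vannot = _read_annotation(Path(config.validation_annotation))
        vcov = CoverageTrack.from_bedgraph(
            config.validation_cov_plus,
            config.validation_cov_minus,
            vannot.chrom_lengths,
        )
        records = validate_pairs(convergent, vannot, vcov, config.params)
        vpath = outdir / "validation.tsv"
        write_validation_records(records, vpath)
        vsummary = summarize_validation(records)
        manifest["outputs"]["validation"] = str(vpath)
        manifest["validation"] = vsummary.to_dict()
        _timed("validate", t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
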