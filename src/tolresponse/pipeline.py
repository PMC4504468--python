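"""End-to-end pipeline: preprocess -> DE dynamics -> frame enrichment -> classification.

Driven by a YAML config with sections ``inputs`` (matrix/samples/annotation
paths), ``synthetic`` (generator parameters used when no input paths are
given), ``thresholds`` (overrides of the default cut-offs) and ``output``
(directory and options).  Every stage writes a stable tab-separated table;
a fixed config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import yaml

from . import de_dynamics, frame_enrichment, preprocess, simulate, strain_compare
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    Thresholds,
    read_annotation,
    read_expression_matrix,
    write_expression_matrix,
)

__all__ = ["load_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("tolresponse")

_FLOAT_FMT = "%.10g"

OUTPUT_FILES = (
    "normalized_matrix.tsv",
    "normalized_samples.tsv",
    "preprocess_report.tsv",
    "de_calls.tsv",
    "de_counts.tsv",
    "frame_responses.tsv",
    "enrichment.tsv",
    "classification.tsv",
    "group_summary.tsv",
)


class PipelineError(RuntimeError):
    """Stage failure; message names the stage and the cause."""


def load_config(path: str | Path) -> dict[str, Any]:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"config file not found: {p}")
    with open(p) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {p} must be a YAML mapping")
    return cfg


def _load_inputs(
    cfg: dict[str, Any], seed: int | None
) -> tuple[ExpressionMatrix, list[GeneAnnotation]]:
    inputs = cfg.get("inputs") or {}
    if inputs.get("matrix"):
        for key in ("matrix", "samples"):
            p = inputs.get(key)
            if not p or not Path(p).exists():
                raise PipelineError(f"input file missing: {key} = {p!r}")
        matrix = read_expression_matrix(inputs["matrix"], inputs["samples"])
        ann_path = inputs.get("annotation")
        if ann_path:
            if not Path(ann_path).exists():
                raise PipelineError(f"input file missing: annotation = {ann_path!r}")
            ann = read_annotation(ann_path)
        else:
            ann = []
        return matrix, ann
    syn = dict(cfg.get("synthetic") or {})
    if seed is not None:
        syn["seed"] = seed
    for tup_key in ("group_fractions", "amplitude_range", "intrinsic_range"):
        if tup_key in syn:
            syn[tup_key] = tuple(syn[tup_key])
    if "enrichment_plants" in syn:
        syn["enrichment_plants"] = tuple(tuple(p) for p in syn["enrichment_plants"])
    spec = simulate.SyntheticSpec(**syn)
    matrix, ann, truth = simulate.generate(spec)
    _load_inputs.last_truth = truth  # type: ignore[attr-defined]
    return matrix, ann


def run_pipeline(
    config: str | Path | dict[str, Any],
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Run every stage in order; returns the output directory.

    Raises :class:`PipelineError` with a stage-named message on failure.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    thresholds = Thresholds.from_dict(cfg.get("thresholds"))
    out = Path(out_dir or (cfg.get("output") or {}).get("dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    matrix, ann = stage("load", _load_inputs, cfg, seed)
    log.info("loaded %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    truth = getattr(_load_inputs, "last_truth", None)
    if truth is not None and not (cfg.get("inputs") or {}).get("matrix"):
        simulate.write_truth(truth, out / "truth.tsv")
        from .io import write_annotation

        write_annotation(ann, out / "annotation.tsv")
        write_expression_matrix(matrix, out / "input_matrix.tsv", out / "input_samples.tsv")

    control_ids = frozenset((cfg.get("inputs") or {}).get("control_ids") or [])
    norm, report = stage("preprocess", preprocess.run_preprocess, matrix, thresholds, control_ids)
    log.info(
        "preprocess: %d in, %d controls removed, %d non-changing removed, %d retained",
        report.n_input_genes,
        report.n_control_removed,
        report.n_nonchanging_removed,
        report.n_retained,
    )
    write_expression_matrix(norm, out / "normalized_matrix.tsv", out / "normalized_samples.tsv")
    import pandas as pd

    pd.DataFrame([report.__dict__]).to_csv(out / "preprocess_report.tsv", sep="\t", index=False)

    profiles = {
        s: stage("de_dynamics", de_dynamics.log2_ratio_profile, norm, s)
        for s in norm.strains()
    }
    calls = stage("de_dynamics", de_dynamics.call_de, profiles, thresholds)
    counts = stage("de_dynamics", de_dynamics.count_series, calls)
    calls.to_csv(out / "de_calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    counts.to_csv(out / "de_counts.tsv", sep="\t", float_format=_FLOAT_FMT)
    log.info("de_dynamics: peak WT count %d, peak KO count %d", counts["n_de_wt"].max(), counts["n_de_ko"].max())

    frames = stage("frame_enrichment", frame_enrichment.classify_frames, norm, thresholds)
    frames.to_csv(out / "frame_responses.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if ann:
        enr = stage("frame_enrichment", frame_enrichment.enrich, frames, ann, thresholds)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        log.info("frame_enrichment: %d significant cells", int(enr["significant"].sum()))
    else:
        (out / "enrichment.tsv").write_text(
            "strain\tt_start\tt_end\tdirection\tcog\tk\tn\tK\tN\tp_value\tneg_log10_p\tsignificant\tbh_q\n"
        )

    classes = stage("strain_compare", strain_compare.classify, norm, thresholds)
    summary = stage("strain_compare", strain_compare.summarize, classes, ann, thresholds)
    classes.to_csv(out / "classification.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    summary.to_csv(out / "group_summary.tsv", sep="\t", float_format=_FLOAT_FMT)
    log.info(
        "strain_compare: group sizes %s",
        summary["n_genes"].to_dict(),
    )
    return out
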