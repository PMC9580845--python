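"""End-to-end orchestration: predict -> post-process -> quantify.

``run_full`` segments one stack and writes the cleaned multiclass mask plus
a JSON volumetry report; ``run_series`` maps a longitudinal list of stacks
to a growth table (CSV). Every run also writes a small provenance JSON
(config hash, seeds, package version, inputs) next to its outputs so that
results remain attributable to an exact configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .core_io import read_stack, write_labelstack
from .network import UNet3Plus, load_checkpoint, predict_stack
from .postprocess import postprocess_stack
from .quantify import VolumetryReport, compute_volumes, summarize_series

__all__ = ["run_full", "run_series"]


def _write_provenance(outdir: Path, config: PipelineConfig, inputs: list, extra=None):
    record = {
        "package": "lungmet",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "inputs": [str(p) for p in inputs],
    }
    if extra:
        record.update(extra)
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2))


def _load_model(weights) -> UNet3Plus:
    return weights if isinstance(weights, UNet3Plus) else load_checkpoint(weights)


def run_full(stack_path, weights, config: PipelineConfig, outdir) -> VolumetryReport:
    """Segment one stack and quantify it.

    Writes ``mask.tif`` (cleaned multiclass mask), ``report.json`` and
    ``provenance.json`` into ``outdir``; returns the volumetry report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = _load_model(weights)
    stack = read_stack(stack_path, spacing_mm=config.spacing_mm)
    raw = predict_stack(model, stack)
    clean = postprocess_stack(raw, stack, config.postprocess)
    report = compute_volumes(clean)
    write_labelstack(clean, outdir / "mask.tif")
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _write_provenance(outdir, config, [stack_path])
    return report


def run_series(stack_paths, weights, config: PipelineConfig, outdir):
    """Quantify a longitudinal series of stacks into a growth table.

    One row per timepoint (input order); writes ``series.csv`` and the
    per-timepoint masks. Returns the growth table DataFrame.
    """
    stack_paths = list(stack_paths)
    if not stack_paths:
        raise ValueError("run_series needs at least one stack")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = _load_model(weights)
    reports = []
    for t, path in enumerate(stack_paths):
        stack = read_stack(path, spacing_mm=config.spacing_mm)
        raw = predict_stack(model, stack)
        clean = postprocess_stack(raw, stack, config.postprocess)
        write_labelstack(clean, outdir / f"mask_t{t:03d}.tif")
        reports.append(compute_volumes(clean))
    table = summarize_series(reports)
    table.to_csv(outdir / "series.csv", index=False)
    _write_provenance(outdir, config, stack_paths, {"n_timepoints": len(reports)})
    return table
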