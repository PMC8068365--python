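"""Run orchestration: preview and summary modes, outputs and log files.

Preview mode builds one montage per condition from all of its fields of
view; summary mode builds a single montage from one representative field of
view per condition.  All outputs (montages + one log file) are written to
the parent directory and share a ``YYYYMMDD-HHMMSS`` timestamp token so
they can be unequivocally paired.  Re-running never overwrites prior
outputs: a colliding timestamp gets a ``-2``, ``-3``, ... suffix.

Contrast pooling boundary: in preview mode, joint-scope bounds pool over
the records of one subfolder only (they share a montage file); in summary
mode they pool over all selected representatives.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .contrast_engine import BoundsEntry, ContrastPolicy, enhance_dataset
from .dataset_discovery import (
    DatasetSpec,
    Diagnostic,
    ImageRecord,
    collect_images,
    discover_subfolders,
)
from .errors import ConfigurationError, DatasetError
from .image_io import ReaderHook, montage_extension, write_montage
from .render import RenderOptions, assemble_montage, colorize, label_tile, merge_channels

__all__ = ["RunConfig", "RunResult", "SubfolderResult", "run", "run_preview", "run_summary"]

TIMESTAMP_FORMAT = "%Y%m%d-%H%M%S"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one run."""

    mode: str
    spec: DatasetSpec
    contrast: ContrastPolicy = ContrastPolicy()
    render: RenderOptions = RenderOptions()
    representatives: Optional[Dict[str, Union[str, int]]] = None
    reader_hook: Optional[ReaderHook] = None

    def __post_init__(self) -> None:
        if self.mode not in ("preview", "summary"):
            raise ConfigurationError(f"mode must be 'preview' or 'summary', got {self.mode!r}")
        if self.representatives is not None and self.mode != "summary":
            raise ConfigurationError("representatives are only meaningful in summary mode")


@dataclass
class SubfolderResult:
    """Discovery outcome for one condition, as recorded in the log."""

    name: str
    records: List[ImageRecord]
    diagnostics: List[Diagnostic]
    selected: List[str] = field(default_factory=list)
    bounds: List[BoundsEntry] = field(default_factory=list)


@dataclass(frozen=True)
class RunResult:
    """Paths and timing of a completed run."""

    montage_paths: Tuple[Path, ...]
    log_path: Path
    timestamp: str
    duration_seconds: float


def run(config: RunConfig) -> RunResult:
    if config.mode == "preview":
        return run_preview(config)
    return run_summary(config)


def _unique_timestamp(parent: Path) -> str:
    """Timestamp token not present in any existing file name in the parent."""
    base = datetime.now().strftime(TIMESTAMP_FORMAT)
    token = base
    n = 1
    existing = [p.name for p in parent.iterdir() if p.is_file()]
    while any(token in name for name in existing):
        n += 1
        token = f"{base}-{n}"
    return token


def _discover_all(config: RunConfig) -> List[SubfolderResult]:
    subfolders = discover_subfolders(config.spec)
    results = []
    for name in subfolders:
        records, diagnostics = collect_images(name, config.spec, reader_hook=config.reader_hook)
        results.append(SubfolderResult(name=name, records=records, diagnostics=diagnostics))
    return results


def _render_record_tiles(
    record: ImageRecord, options: RenderOptions
) -> List[np.ndarray]:
    """One row of tiles for a field of view: shown single channels, then merge."""
    n = record.n_channels
    tiles = []
    for c in options.shown_channels(n):
        tile = colorize(record.planes[c - 1], "gray")
        tiles.append(
            label_tile(tile, f"C{c}", record.subfolder_name, record.base_name,
                       enabled=options.label_tiles)
        )
    merged = merge_channels(record.planes, options)
    tiles.append(
        label_tile(merged, "merge", record.subfolder_name, record.base_name,
                   enabled=options.label_tiles)
    )
    return tiles


def _build_montage(records: Sequence[ImageRecord], options: RenderOptions) -> np.ndarray:
    grid = [_render_record_tiles(r, options) for r in records]
    return assemble_montage(grid, options)


def run_preview(config: RunConfig) -> RunResult:
    """One montage per condition, gathering all of its compliant images."""
    start = time.perf_counter()
    parent = config.spec.parent_path
    results = _discover_all(config)
    timestamp = _unique_timestamp(parent)

    populated = [r for r in results if r.records]
    if not populated:
        log_path = write_log(config, results, timestamp, time.perf_counter() - start, [])
        raise DatasetError(
            f"no usable images found in any subfolder of {parent}; see log {log_path.name}"
        )

    n_channels = populated[0].records[0].n_channels
    config.render.validate_for(n_channels)
    ext = montage_extension(config.render.export_format)

    montage_paths = []
    for result in populated:
        enhanced, bounds = enhance_dataset(result.records, config.contrast)
        result.bounds = bounds
        result.selected = [r.base_name for r in result.records]
        montage = _build_montage(enhanced, config.render)
        path = parent / f"{result.name}_preview_{timestamp}.{ext}"
        write_montage(montage, path, config.render.export_format)
        montage_paths.append(path)

    duration = time.perf_counter() - start
    log_path = write_log(config, results, timestamp, duration, montage_paths)
    return RunResult(tuple(montage_paths), log_path, timestamp, round(duration, 3))


def _select_representative(result: SubfolderResult, ref: Union[str, int]) -> ImageRecord:
    names = [r.base_name for r in result.records]
    if isinstance(ref, int):
        if not 1 <= ref <= len(result.records):
            raise DatasetError(
                f"representative index {ref} out of range for subfolder "
                f"{result.name!r}; available: {', '.join(names)}"
            )
        return result.records[ref - 1]
    for record in result.records:
        if record.base_name == ref:
            return record
    raise DatasetError(
        f"representative {ref!r} not found in subfolder {result.name!r}; "
        f"available: {', '.join(names)}"
    )


def run_summary(config: RunConfig) -> RunResult:
    """One experiment-wide montage with one representative image per condition.

    Default representative is the first record in lexicographic order.
    Joint-scope contrast pools across all selected records, since they share
    the single montage file.
    """
    start = time.perf_counter()
    parent = config.spec.parent_path
    results = _discover_all(config)
    timestamp = _unique_timestamp(parent)

    representatives = config.representatives or {}
    selected: List[ImageRecord] = []
    for result in results:
        if not result.records:
            continue
        record = _select_representative(result, representatives.get(result.name, 1))
        result.selected = [record.base_name]
        selected.append(record)

    if not selected:
        log_path = write_log(config, results, timestamp, time.perf_counter() - start, [])
        raise DatasetError(
            f"no usable images found in any subfolder of {parent}; see log {log_path.name}"
        )

    config.render.validate_for(selected[0].n_channels)
    ext = montage_extension(config.render.export_format)

    enhanced, bounds = enhance_dataset(selected, config.contrast)
    run_bounds = [e for e in bounds if e.record is None]  # joint: whole montage
    individual = [e for e in bounds if e.record is not None]
    for result in results:
        result.bounds = [e for e in individual if e.record in result.selected]
    montage = _build_montage(enhanced, config.render)
    path = parent / f"summary_{timestamp}.{ext}"
    write_montage(montage, path, config.render.export_format)

    duration = time.perf_counter() - start
    log_path = write_log(config, results, timestamp, duration, [path], run_bounds)
    return RunResult((path,), log_path, timestamp, round(duration, 3))


def _format_policy(config: RunConfig) -> List[str]:
    lines = [f"contrast mode: {config.contrast.mode}"]
    if config.contrast.mode == "user_defined":
        for i, ch in enumerate(config.contrast.channels, start=1):
            lines.append(
                f"  channel {i}: enhance={ch.enhance} "
                f"saturation={ch.saturation_fraction:g} scope={ch.scope}"
            )
        lines.append(
            "  saturation split: half of the pixel budget clipped per histogram tail"
        )
    for note in config.contrast.warnings():
        lines.append(f"  note: {note}")
    options = config.render
    lines += [
        f"palette: {options.palette if options.palette else 'default'}",
        f"label tiles: {options.label_tiles}",
        f"orientation: {options.orientation}",
        f"export format: {options.export_format}",
        f"omit from singles: {sorted(options.omit_from_singles) or 'none'}",
        f"omit from merge: {sorted(options.omit_from_merge) or 'none'}",
        "merge blending: additive, clamped to 255 per component",
    ]
    return lines


def write_log(
    config: RunConfig,
    results: Sequence[SubfolderResult],
    timestamp: str,
    duration_seconds: float,
    montage_paths: Sequence[Path],
    run_bounds: Sequence[BoundsEntry] = (),
) -> Path:
    """Write the four-section run log and return its path.

    Sections: (1) tool and execution date, (2) user inputs and resolved
    parameters, (3) parent-directory listing, (4) per-subdirectory selected
    files, skips and contrast bounds.  The final line reports the duration.
    """
    parent = config.spec.parent_path
    spec = config.spec
    lines: List[str] = []
    lines.append(f"(1) picmontage {config.mode} v{__version__}")
    lines.append(f"Executed on {timestamp} (YYYYMMDD-HHMMSS)")
    lines.append("")
    lines.append("(2) Parameters")
    lines.append(f"mode: {config.mode}")
    lines.append(f"parent directory: {parent}")
    lines.append(f"structure: {spec.structure}")
    lines.append(f"extension: {spec.extension}")
    lines.append(f"channels: {spec.n_channels}")
    if spec.channel_identifiers:
        lines.append(f"channel identifiers: {', '.join(spec.channel_identifiers)}")
    if config.mode == "summary":
        reps = config.representatives or {}
        lines.append(f"representatives: {reps if reps else 'default (first image per subfolder)'}")
        lines.append("joint contrast pooling: across all selected representatives")
    lines.extend(_format_policy(config))
    lines.append("")
    lines.append(f"(3) Content of parent directory {parent}")
    for entry in sorted(parent.iterdir(), key=lambda p: p.name):
        lines.append(f"  {entry.name}{'/' if entry.is_dir() else ''}")
    lines.append("")
    lines.append("(4) Files per subdirectory")
    for result in results:
        lines.append(f"[{result.name}]")
        if not result.records:
            lines.append("  no usable images; subfolder omitted from the montages")
        for name in result.selected:
            lines.append(f"  selected: {name}")
        for diag in result.diagnostics:
            label = "skipped" if diag.kind == "skip" else "warning"
            lines.append(f"  {label}: {diag.file_name} ({diag.reason})")
        for entry in result.bounds:
            where = "all pictures" if entry.record is None else entry.record
            lines.append(
                f"  channel {entry.channel} bounds ({entry.scope}, {where}): "
                f"{entry.bounds.low}-{entry.bounds.high}"
            )
    for entry in run_bounds:
        lines.append(
            f"  channel {entry.channel} bounds ({entry.scope}, whole montage): "
            f"{entry.bounds.low}-{entry.bounds.high}"
        )
    if montage_paths:
        lines.append("")
        lines.append("Montage files written:")
        for path in montage_paths:
            lines.append(f"  {path.name}")
    lines.append("")
    lines.append(
        f"Macro finished on {timestamp} (YYYYMMDD-HHMMSS) and lasted {duration_seconds:.3f} s"
    )

    log_path = parent / f"{config.mode}_log_{timestamp}.txt"
    try:
        log_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise DatasetError(f"cannot write log file to {parent}: {exc}") from exc
    return log_path
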