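"""Resolve an experiment directory into logical multichannel image records.

An experiment is a parent directory holding one subdirectory per condition.
Each subdirectory contains either one multichannel file per field of view
(``single_file`` structure) or one single-channel file per channel whose
names differ only by a channel-identifier substring (``separated_channels``).

Files that do not match the declared extension/channel count, or that carry
extra dimensions (z-stack, time-lapse, multi-series), are skipped with a
diagnostic rather than aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ConfigurationError, DatasetError, ImageReadError
from .image_io import ChannelPlane, ReaderHook, read_image

__all__ = [
    "DatasetSpec",
    "ImageRecord",
    "ChannelGroup",
    "Diagnostic",
    "discover_subfolders",
    "group_separated_channels",
    "collect_images",
]

#: combined "subfolder/filename" lengths beyond this get a provenance warning
#: (the historical tooling this mirrors misbehaved past 61 characters; we do
#: not reproduce the failure, only flag the condition).
PATH_LENGTH_WARNING = 61

STRUCTURES = ("single_file", "separated_channels")


@dataclass(frozen=True)
class DatasetSpec:
    """User-declared description of the dataset on disk.

    Parameters
    ----------
    parent_path:
        Experiment directory; its immediate subdirectories are the conditions.
    structure:
        ``"single_file"`` (all channels in one file per field of view) or
        ``"separated_channels"`` (one file per channel).
    extension:
        Image file extension without the dot; matched case-insensitively.
    n_channels:
        Number of acquired channels; files disagreeing with it are skipped.
    channel_identifiers:
        Required for ``separated_channels``: the per-channel name substrings,
        in channel order.  Must be non-empty, pairwise distinct, and no
        identifier may be a substring of another.
    """

    parent_path: Path
    structure: str = "single_file"
    extension: str = "tif"
    n_channels: int = 1
    channel_identifiers: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_path", Path(self.parent_path))
        if self.structure not in STRUCTURES:
            raise ConfigurationError(
                f"structure must be one of {STRUCTURES}, got {self.structure!r}"
            )
        if not self.extension or self.extension.startswith("."):
            raise ConfigurationError("extension must be non-empty and given without a dot")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.structure == "separated_channels":
            ids = self.channel_identifiers
            if ids is None:
                raise ConfigurationError(
                    "channel_identifiers are required for separated_channels structure"
                )
            ids = tuple(ids)
            object.__setattr__(self, "channel_identifiers", ids)
            if len(ids) != self.n_channels:
                raise ConfigurationError(
                    f"expected {self.n_channels} channel identifiers, got {len(ids)}"
                )
            if any(not i for i in ids):
                raise ConfigurationError("channel identifiers must be non-empty")
            if len(set(ids)) != len(ids):
                raise ConfigurationError("channel identifiers must be pairwise distinct")
            for a in ids:
                for b in ids:
                    if a != b and a in b:
                        raise ConfigurationError(
                            f"identifier {a!r} is a substring of {b!r}; grouping would be ambiguous"
                        )
        elif self.channel_identifiers is not None:
            raise ConfigurationError(
                "channel_identifiers are only meaningful for separated_channels structure"
            )

    def matches_extension(self, file_name: str) -> bool:
        return file_name.lower().endswith("." + self.extension.lower())


@dataclass(frozen=True)
class ImageRecord:
    """One logical multichannel field of view with its provenance."""

    subfolder_name: str
    base_name: str
    source_paths: Tuple[Path, ...]
    planes: Tuple[ChannelPlane, ...]

    def __post_init__(self) -> None:
        if not self.planes:
            raise ConfigurationError("ImageRecord needs at least one plane")
        first = self.planes[0]
        for p in self.planes[1:]:
            if p.shape != first.shape or p.bit_depth != first.bit_depth:
                raise ConfigurationError(
                    f"{self.subfolder_name}/{self.base_name}: planes differ in size or bit depth"
                )

    @property
    def n_channels(self) -> int:
        return len(self.planes)

    @property
    def bit_depth(self) -> int:
        return self.planes[0].bit_depth

    @property
    def shape(self) -> Tuple[int, int]:
        return self.planes[0].shape

    def with_planes(self, planes: Sequence[ChannelPlane]) -> "ImageRecord":
        return replace(self, planes=tuple(planes))


@dataclass(frozen=True)
class ChannelGroup:
    """A resolved separated-channels group: one file name per channel."""

    base_name: str
    file_names: Tuple[str, ...]


@dataclass(frozen=True)
class Diagnostic:
    """A per-file notice emitted during discovery.

    ``kind`` is ``"skip"`` (file excluded from the montage) or ``"warning"``
    (file kept, but flagged — e.g. very long path).
    """

    file_name: str
    reason: str
    kind: str = "skip"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.file_name}: {self.reason} [{self.kind}]"


def discover_subfolders(spec: DatasetSpec) -> List[str]:
    """Enumerate condition subdirectories of the parent, sorted by name.

    Files directly inside the parent directory are never dataset images.

    Raises
    ------
    DatasetError
        If the parent is missing/unreadable or contains no subdirectories.
    """
    parent = spec.parent_path
    if not parent.is_dir():
        raise DatasetError(f"parent directory not found or not readable: {parent}")
    try:
        subfolders = sorted(entry.name for entry in parent.iterdir() if entry.is_dir())
    except OSError as exc:
        raise DatasetError(f"cannot list parent directory {parent}: {exc}") from exc
    if not subfolders:
        raise DatasetError(
            f"no subfolders found in {parent}; images must live in one subdirectory "
            "per condition — remember to select the parent directory, not the "
            "directory directly containing the pictures"
        )
    return subfolders


def group_separated_channels(
    file_names: Sequence[str], identifiers: Sequence[str]
) -> Tuple[List[ChannelGroup], List[Diagnostic]]:
    """Group per-channel files into logical multichannel records.

    The first identifier acts as the pivot: every file containing it exactly
    once defines a group whose sibling names are formed by substituting the
    pivot with each other identifier.  A group is emitted only when all
    siblings exist.  Ambiguous pivots (identifier occurring more than once)
    and incomplete groups become skip diagnostics.
    """
    identifiers = list(identifiers)
    pivot = identifiers[0]
    names = set(file_names)
    groups: List[ChannelGroup] = []
    diagnostics: List[Diagnostic] = []
    consumed: set = set()

    for name in sorted(names):
        count = name.count(pivot)
        if count == 0:
            continue
        if count > 1:
            diagnostics.append(
                Diagnostic(name, f"ambiguous identifier: {pivot!r} occurs {count} times")
            )
            consumed.add(name)
            continue
        siblings = tuple(name.replace(pivot, ident) for ident in identifiers)
        missing = [s for s in siblings if s not in names]
        if missing:
            diagnostics.append(
                Diagnostic(name, f"incomplete group: missing {', '.join(sorted(missing))}")
            )
            consumed.add(name)
            continue
        base = Path(name.replace(pivot, "")).stem
        groups.append(ChannelGroup(base_name=base, file_names=siblings))
        consumed.update(siblings)

    for name in sorted(names - consumed):
        diagnostics.append(
            Diagnostic(name, f"incomplete group: no matching file with identifier {pivot!r}")
        )

    groups.sort(key=lambda g: g.base_name)
    return groups, diagnostics


def collect_images(
    subfolder: str,
    spec: DatasetSpec,
    reader_hook: Optional[ReaderHook] = None,
) -> Tuple[List[ImageRecord], List[Diagnostic]]:
    """Load all compliant fields of view from one condition subdirectory.

    Returns the records (sorted by base name) plus skip/warning diagnostics.
    A subfolder yielding zero records is not an error here; the pipeline
    reports it and omits it from the montages.
    """
    folder = spec.parent_path / subfolder
    if not folder.is_dir():
        raise DatasetError(f"subfolder not found: {folder}")
    file_names = sorted(
        entry.name
        for entry in folder.iterdir()
        if entry.is_file() and spec.matches_extension(entry.name)
    )

    if spec.structure == "single_file":
        records, diagnostics = _collect_single_file(folder, subfolder, file_names, spec, reader_hook)
    else:
        records, diagnostics = _collect_separated(folder, subfolder, file_names, spec, reader_hook)

    for record in records:
        for path in record.source_paths:
            rel = f"{subfolder}/{path.name}"
            if len(rel) > PATH_LENGTH_WARNING:
                diagnostics.append(
                    Diagnostic(
                        path.name,
                        f"path {rel!r} exceeds {PATH_LENGTH_WARNING} characters",
                        kind="warning",
                    )
                )
    records.sort(key=lambda r: r.base_name)
    return records, diagnostics


def _collect_single_file(folder, subfolder, file_names, spec, reader_hook):
    records: List[ImageRecord] = []
    diagnostics: List[Diagnostic] = []
    for name in file_names:
        path = folder / name
        try:
            planes, info = read_image(path, reader_hook=reader_hook)
        except ImageReadError as exc:
            diagnostics.append(Diagnostic(name, f"unreadable: {exc}"))
            continue
        reason = _dimension_skip_reason(info, spec.n_channels)
        if reason is not None:
            diagnostics.append(Diagnostic(name, reason))
            continue
        records.append(
            ImageRecord(
                subfolder_name=subfolder,
                base_name=Path(name).stem,
                source_paths=(path,),
                planes=tuple(planes),
            )
        )
    return records, diagnostics


def _collect_separated(folder, subfolder, file_names, spec, reader_hook):
    groups, diagnostics = group_separated_channels(file_names, spec.channel_identifiers)
    records: List[ImageRecord] = []
    for group in groups:
        planes: List[ChannelPlane] = []
        failure: Optional[str] = None
        for name in group.file_names:
            try:
                file_planes, info = read_image(folder / name, reader_hook=reader_hook)
            except ImageReadError as exc:
                failure = f"unreadable member {name}: {exc}"
                break
            if not info.is_plain_multichannel or info.n_channels != 1:
                failure = f"member {name} is not a plain single-channel 2-D image"
                break
            planes.append(file_planes[0])
        if failure is None:
            shapes = {p.shape for p in planes}
            depths = {p.bit_depth for p in planes}
            if len(shapes) > 1 or len(depths) > 1:
                failure = "channel files differ in size or bit depth"
        if failure is not None:
            diagnostics.append(Diagnostic(group.file_names[0], failure))
            continue
        records.append(
            ImageRecord(
                subfolder_name=subfolder,
                base_name=group.base_name,
                source_paths=tuple(folder / n for n in group.file_names),
                planes=tuple(planes),
            )
        )
    return records, diagnostics


def _dimension_skip_reason(info, n_channels: int) -> Optional[str]:
    if info.n_z > 1:
        return f"multi-slice file ignored ({info.n_z} z-slices)"
    if info.n_t > 1:
        return f"multi-frame file ignored ({info.n_t} time frames)"
    if info.n_series > 1:
        return f"multi-series file ignored ({info.n_series} series/positions)"
    if info.n_channels != n_channels:
        return (
            f"channel count mismatch: file has {info.n_channels}, expected {n_channels}"
        )
    return None
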