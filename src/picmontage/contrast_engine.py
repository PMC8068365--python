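"""Histogram-stretch contrast enhancement.

Three run modes:

* ``none`` — planes pass through untouched.
* ``autoscale`` — every channel of every record is min-max stretched on its
  own histogram (saturation 0).
* ``user_defined`` — per-channel settings: enhancement on/off, a saturation
  fraction, and a scope.  With ``individual`` scope each record's own channel
  histogram sets the stretch bounds; with ``joint`` scope one bounds pair is
  computed from the pooled histograms of that channel across all records of
  the montage group, so relative intensities between records stay comparable.

The saturation fraction is split equally between the low and high tails:
with N pooled pixels and fraction f, up to floor(N*f/2) pixels per tail are
pushed to the extremes.  All pixels sharing the boundary intensity clip
together (histogram-bin granularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dataset_discovery import ImageRecord
from .errors import ConfigurationError, ContrastError
from .image_io import ChannelPlane

__all__ = [
    "CANONICAL_SATURATIONS",
    "ChannelContrast",
    "ContrastPolicy",
    "ClipBounds",
    "BoundsEntry",
    "compute_histogram",
    "compute_clip_bounds",
    "apply_linear_stretch",
    "enhance_dataset",
]

#: saturation fractions offered by the menu (0%, 0.01%, 0.1%, 0.4%, 1%)
CANONICAL_SATURATIONS = (0.0, 0.0001, 0.001, 0.004, 0.01)

MODES = ("none", "autoscale", "user_defined")
SCOPES = ("joint", "individual")


@dataclass(frozen=True)
class ChannelContrast:
    """User-defined contrast settings for one channel."""

    enhance: bool = True
    saturation_fraction: float = 0.0
    scope: str = "joint"

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation_fraction <= 0.01:
            raise ConfigurationError(
                f"saturation_fraction must be in [0, 0.01], got {self.saturation_fraction}"
            )
        if self.scope not in SCOPES:
            raise ConfigurationError(f"scope must be one of {SCOPES}, got {self.scope!r}")

    @property
    def is_canonical(self) -> bool:
        return any(
            math.isclose(self.saturation_fraction, c, abs_tol=1e-12)
            for c in CANONICAL_SATURATIONS
        )


@dataclass(frozen=True)
class ContrastPolicy:
    """Run-wide contrast mode plus per-channel settings (user_defined only)."""

    mode: str = "none"
    channels: Optional[Tuple[ChannelContrast, ...]] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "user_defined":
            if not self.channels:
                raise ConfigurationError("user_defined mode requires per-channel settings")
            object.__setattr__(self, "channels", tuple(self.channels))
        elif self.channels is not None:
            raise ConfigurationError(
                "per-channel settings are only meaningful in user_defined mode"
            )

    def validate_channel_count(self, n_channels: int) -> None:
        if self.mode == "user_defined" and len(self.channels) != n_channels:
            raise ConfigurationError(
                f"user_defined policy has {len(self.channels)} channel entries, "
                f"dataset declares {n_channels} channels"
            )

    def warnings(self) -> List[str]:
        """Notices to surface in the run log (non-canonical saturations)."""
        notes = []
        if self.mode == "user_defined":
            for i, ch in enumerate(self.channels, start=1):
                if ch.enhance and not ch.is_canonical:
                    notes.append(
                        f"channel {i}: saturation {ch.saturation_fraction} is outside "
                        "the canonical menu (0, 0.0001, 0.001, 0.004, 0.01)"
                    )
        return notes


@dataclass(frozen=True)
class ClipBounds:
    """Stretch endpoints: intensities at/below low map to 0, at/above high to full scale."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high:
            raise ContrastError(f"invalid clip bounds ({self.low}, {self.high})")


@dataclass(frozen=True)
class BoundsEntry:
    """One bounds decision, for the run log: which channel/record, which bounds."""

    channel: int  # 1-based
    scope: str  # "joint" or "individual"
    bounds: ClipBounds
    record: Optional[str] = None  # base name; None for joint entries


def compute_histogram(plane: ChannelPlane) -> np.ndarray:
    """Exact intensity histogram with one bin per representable value.

    Bin ``b`` counts pixels of intensity ``b``; the bins sum to width*height.
    """
    return np.bincount(plane.pixels.ravel(), minlength=1 << plane.bit_depth)


def compute_clip_bounds(
    histograms: Iterable[np.ndarray] | np.ndarray,
    saturation_fraction: float,
    bit_depth: int,
) -> ClipBounds:
    """Derive stretch endpoints from one or more pooled histograms.

    With N pooled pixels and k = floor(N * saturation_fraction / 2):
    ``low`` is the smallest intensity whose cumulative count strictly exceeds
    k, ``high`` the largest intensity whose cumulative-from-above count
    strictly exceeds k.  Saturation 0 therefore yields the pooled min/max.
    """
    if isinstance(histograms, np.ndarray) and histograms.ndim == 1:
        histograms = [histograms]
    n_bins = 1 << bit_depth
    pooled = np.zeros(n_bins, dtype=np.int64)
    for h in histograms:
        h = np.asarray(h, dtype=np.int64)
        if h.size > n_bins:
            raise ContrastError(
                f"histogram has {h.size} bins, more than 2^{bit_depth}"
            )
        pooled[: h.size] += h
    total = int(pooled.sum())
    if total == 0:
        raise ContrastError("cannot compute clip bounds from an empty histogram")

    k = math.floor(total * saturation_fraction / 2)
    cum = np.cumsum(pooled)
    low = int(np.searchsorted(cum, k, side="right"))
    rcum = np.cumsum(pooled[::-1])
    high = n_bins - 1 - int(np.searchsorted(rcum, k, side="right"))
    if high < low:  # extreme clipping collapsed the range; degenerate pass-through
        low = high = int(np.argmax(cum > total // 2))
    return ClipBounds(low=low, high=high)


def apply_linear_stretch(plane: ChannelPlane, bounds: ClipBounds) -> ChannelPlane:
    """Map [low, high] linearly onto the full bit-depth range.

    Pixels below ``low`` clip to 0, above ``high`` to full scale; values are
    rounded half-up and stored at the original bit depth.  A degenerate
    ``low == high`` (constant input) passes through unchanged so blank
    control images still build.
    """
    if bounds.high == bounds.low:
        return ChannelPlane(plane.pixels.copy())
    full = plane.max_value
    if bounds.high > full:
        raise ContrastError(
            f"bounds ({bounds.low}, {bounds.high}) exceed bit depth {plane.bit_depth}"
        )
    clipped = np.clip(plane.pixels, bounds.low, bounds.high).astype(np.float64)
    # multiply before dividing: keeps exact halves (e.g. 127.5) exact
    scaled = (clipped - bounds.low) * full / (bounds.high - bounds.low)
    out = np.floor(scaled + 0.5).astype(plane.pixels.dtype)
    return ChannelPlane(out)


def enhance_dataset(
    records: Sequence[ImageRecord],
    policy: ContrastPolicy,
) -> Tuple[List[ImageRecord], List[BoundsEntry]]:
    """Apply the contrast policy to all records of one montage group.

    Joint scope pools histograms across exactly the records given here, so
    the caller controls the pooling boundary (per condition in preview mode,
    across selected representatives in summary mode).

    Returns the enhanced records plus the bounds used, for the run log.
    """
    records = list(records)
    if not records:
        return [], []
    depths = {r.bit_depth for r in records}
    if len(depths) > 1:
        raise ContrastError(
            f"mixed bit depths within one montage group: {sorted(depths)}"
        )
    n_channels = records[0].n_channels
    if any(r.n_channels != n_channels for r in records):
        raise ContrastError("records in one montage group differ in channel count")
    policy.validate_channel_count(n_channels)

    if policy.mode == "none":
        return records, []

    bit_depth = records[0].bit_depth
    report: List[BoundsEntry] = []
    new_planes: List[List[ChannelPlane]] = [list(r.planes) for r in records]

    for c in range(n_channels):
        if policy.mode == "autoscale":
            saturation, scope = 0.0, "individual"
        else:
            setting = policy.channels[c]
            if not setting.enhance:
                continue
            saturation, scope = setting.saturation_fraction, setting.scope

        if scope == "joint":
            pooled = [compute_histogram(r.planes[c]) for r in records]
            bounds = compute_clip_bounds(pooled, saturation, bit_depth)
            report.append(BoundsEntry(channel=c + 1, scope="joint", bounds=bounds))
            for i, record in enumerate(records):
                new_planes[i][c] = apply_linear_stretch(record.planes[c], bounds)
        else:
            for i, record in enumerate(records):
                hist = compute_histogram(record.planes[c])
                bounds = compute_clip_bounds(hist, saturation, bit_depth)
                report.append(
                    BoundsEntry(
                        channel=c + 1,
                        scope="individual",
                        bounds=bounds,
                        record=record.base_name,
                    )
                )
                new_planes[i][c] = apply_linear_stretch(record.planes[c], bounds)

    enhanced = [r.with_planes(p) for r, p in zip(records, new_planes)]
    return enhanced, report
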