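import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picmontage.contrast_engine import (
    CANONICAL_SATURATIONS,
    ChannelContrast,
    ClipBounds,
    ContrastPolicy,
    apply_linear_stretch,
    compute_clip_bounds,
    compute_histogram,
    enhance_dataset,
)
from picmontage.dataset_discovery import ImageRecord
from picmontage.errors import ConfigurationError, ContrastError
from picmontage.image_io import ChannelPlane

from conftest import plane8, plane16


def record(name, *channel_arrays, dtype=np.uint8, subfolder="WT"):
    planes = tuple(ChannelPlane(np.asarray(a, dtype=dtype)) for a in channel_arrays)
    return ImageRecord(subfolder_name=subfolder, base_name=name,
                       source_paths=(), planes=planes)


def sort_oracle_bounds(pixels: np.ndarray, fraction: float) -> tuple:
    """Independent sort-based clip-bound computation."""
    a = np.sort(np.asarray(pixels).ravel())
    k = math.floor(a.size * fraction / 2)
    return int(a[k]), int(a[a.size - 1 - k])


class TestPolicy:
    def test_user_defined_needs_channels(self):
        with pytest.raises(ConfigurationError):
            ContrastPolicy(mode="user_defined")

    def test_channels_only_for_user_defined(self):
        with pytest.raises(ConfigurationError):
            ContrastPolicy(mode="autoscale", channels=(ChannelContrast(),))

    def test_saturation_range(self):
        with pytest.raises(ConfigurationError):
            ChannelContrast(saturation_fraction=0.02)
        with pytest.raises(ConfigurationError):
            ChannelContrast(saturation_fraction=-0.001)

    def test_non_canonical_saturation_is_logged_not_rejected(self):
        policy = ContrastPolicy(
            mode="user_defined",
            channels=(ChannelContrast(saturation_fraction=0.002),),
        )
        assert any("canonical" in w for w in policy.warnings())
        canonical = ContrastPolicy(
            mode="user_defined",
            channels=tuple(ChannelContrast(saturation_fraction=f) for f in CANONICAL_SATURATIONS),
        )
        assert canonical.warnings() == []

    def test_channel_count_check(self):
        policy = ContrastPolicy(mode="user_defined", channels=(ChannelContrast(),))
        with pytest.raises(ConfigurationError):
            policy.validate_channel_count(3)


class TestHistogram:
    def test_16bit_megapixel_total(self, rng):
        plane = ChannelPlane(rng.integers(0, 65536, (1024, 1024)).astype(np.uint16))
        hist = compute_histogram(plane)
        assert hist.size == 65536
        assert int(hist.sum()) == 1_048_576

    def test_constant_zero_plane(self):
        hist = compute_histogram(plane8(np.zeros((2, 2))))
        assert hist[0] == 4
        assert hist.sum() == 4

    def test_matches_bruteforce_tally(self, rng):
        pixels = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        hist = compute_histogram(ChannelPlane(pixels))
        brute = np.zeros(256, dtype=int)
        for v in pixels.ravel():
            brute[v] += 1
        np.testing.assert_array_equal(hist, brute)


class TestClipBounds:
    def test_zero_saturation_is_minmax(self):
        p = plane8([[10, 50], [120, 200]])
        bounds = compute_clip_bounds(compute_histogram(p), 0.0, 8)
        assert (bounds.low, bounds.high) == (10, 200)

    def test_constant_plane(self):
        p = plane8(np.full((5, 5), 42))
        bounds = compute_clip_bounds(compute_histogram(p), 0.01, 8)
        assert bounds.low == bounds.high == 42

    def test_uniform_ramp_discards_two_per_tail(self):
        pixels = np.arange(100, dtype=np.uint8).reshape(10, 10)
        bounds = compute_clip_bounds(compute_histogram(ChannelPlane(pixels)), 0.04, 8)
        assert (bounds.low, bounds.high) == sort_oracle_bounds(pixels, 0.04) == (2, 97)

    def test_empty_histogram_is_error(self):
        with pytest.raises(ContrastError):
            compute_clip_bounds(np.zeros(256, dtype=int), 0.0, 8)

    def test_pooled_histograms(self):
        a = plane8(np.full((4, 4), 10))
        b = plane8(np.full((4, 4), 200))
        bounds = compute_clip_bounds(
            [compute_histogram(a), compute_histogram(b)], 0.0, 8
        )
        assert (bounds.low, bounds.high) == (10, 200)

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(st.integers(0, 255), min_size=1, max_size=2000),
        fraction=st.sampled_from(CANONICAL_SATURATIONS)
        | st.floats(0.0, 0.01, allow_nan=False),
    )
    def test_histogram_path_equals_sort_oracle(self, data, fraction):
        pixels = np.asarray(data, dtype=np.uint8).reshape(1, -1)
        plane = ChannelPlane(pixels)
        bounds = compute_clip_bounds(compute_histogram(plane), fraction, 8)
        assert (bounds.low, bounds.high) == sort_oracle_bounds(pixels, fraction)


class TestStretch:
    def test_worked_mapping(self):
        p = plane8([[10, 105, 200]])
        out = apply_linear_stretch(p, ClipBounds(10, 200))
        # round half-up of (105-10)*255/190 = 127.5
        np.testing.assert_array_equal(out.pixels, [[0, 128, 255]])

    def test_full_range_bounds_are_identity(self, rng):
        p = plane8(rng.integers(0, 256, (6, 6)))
        out = apply_linear_stretch(p, ClipBounds(0, 255))
        np.testing.assert_array_equal(out.pixels, p.pixels)

    def test_clamping(self):
        p = plane8([[5, 250]])
        out = apply_linear_stretch(p, ClipBounds(10, 200))
        np.testing.assert_array_equal(out.pixels, [[0, 255]])

    def test_degenerate_bounds_pass_through(self):
        p = plane8(np.full((3, 3), 7))
        out = apply_linear_stretch(p, ClipBounds(7, 7))
        np.testing.assert_array_equal(out.pixels, p.pixels)

    def test_preserves_dtype_16bit(self, rng):
        p = plane16(rng.integers(0, 65536, (4, 4)))
        out = apply_linear_stretch(p, ClipBounds(0, 30000))
        assert out.pixels.dtype == np.uint16

    @settings(max_examples=100, deadline=None)
    @given(
        values=st.lists(st.integers(0, 255), min_size=2, max_size=200),
        low=st.integers(0, 255),
        span=st.integers(0, 255),
    )
    def test_monotonicity(self, values, low, span):
        high = min(255, low + span)
        p = plane8(np.asarray(values).reshape(1, -1))
        out = apply_linear_stretch(p, ClipBounds(low, high)).pixels.ravel()
        order = np.argsort(np.asarray(values), kind="stable")
        assert np.all(np.diff(out[order]) >= 0)

    @settings(max_examples=100, deadline=None)
    @given(values=st.lists(st.integers(0, 255), min_size=2, max_size=500))
    def test_full_span_and_idempotence(self, values):
        p = plane8(np.asarray(values).reshape(1, -1))
        bounds = compute_clip_bounds(compute_histogram(p), 0.0, 8)
        once = apply_linear_stretch(p, bounds)
        if bounds.low != bounds.high:
            assert once.pixels.min() == 0
            assert once.pixels.max() == 255
        bounds2 = compute_clip_bounds(compute_histogram(once), 0.0, 8)
        twice = apply_linear_stretch(once, bounds2)
        assert np.max(np.abs(twice.pixels.astype(int) - once.pixels.astype(int))) <= 1

    def test_saturation_accounting(self, rng):
        pixels = rng.integers(20, 235, 10_000).astype(np.uint8).reshape(100, 100)
        plane = ChannelPlane(pixels)
        fraction = 0.01
        bounds = compute_clip_bounds(compute_histogram(plane), fraction, 8)
        out = apply_linear_stretch(plane, bounds).pixels
        n_extreme = int(np.sum(out == 0) + np.sum(out == 255))
        hist = compute_histogram(plane)
        ties = int(hist[bounds.low] + hist[bounds.high])
        assert n_extreme <= pixels.size * fraction + ties


class TestEnhanceDataset:
    def test_none_is_identity(self, rng):
        recs = [record("a", rng.integers(0, 256, (4, 4)))]
        out, report = enhance_dataset(recs, ContrastPolicy(mode="none"))
        np.testing.assert_array_equal(out[0].planes[0].pixels, recs[0].planes[0].pixels)
        assert report == []

    def test_autoscale_each_plane_minmax(self):
        recs = [record("a", [[10, 110]], [[0, 50]])]
        out, report = enhance_dataset(recs, ContrastPolicy(mode="autoscale"))
        np.testing.assert_array_equal(out[0].planes[0].pixels, [[0, 255]])
        np.testing.assert_array_equal(out[0].planes[1].pixels, [[0, 255]])
        assert all(e.scope == "individual" for e in report)

    def test_joint_scope_shares_reference(self):
        # pooled max (200) is the reference: A's brightest maps below 255
        a = record("A", [[0, 100]])
        b = record("B", [[0, 200]])
        policy = ContrastPolicy(
            mode="user_defined",
            channels=(ChannelContrast(saturation_fraction=0.0, scope="joint"),),
        )
        out, report = enhance_dataset([a, b], policy)
        assert out[0].planes[0].pixels[0, 1] == 128  # 100*255/200 rounded
        assert out[1].planes[0].pixels[0, 1] == 255
        assert len(report) == 1 and report[0].record is None
        assert (report[0].bounds.low, report[0].bounds.high) == (0, 200)

    def test_individual_scope_each_max_full_scale(self):
        a = record("A", [[0, 100]])
        b = record("B", [[0, 200]])
        policy = ContrastPolicy(
            mode="user_defined",
            channels=(ChannelContrast(saturation_fraction=0.0, scope="individual"),),
        )
        out, report = enhance_dataset([a, b], policy)
        assert out[0].planes[0].pixels[0, 1] == 255
        assert out[1].planes[0].pixels[0, 1] == 255
        assert {e.record for e in report} == {"A", "B"}

    def test_disabled_channel_untouched(self):
        rec = record("a", [[10, 100]], [[10, 100]])
        policy = ContrastPolicy(
            mode="user_defined",
            channels=(
                ChannelContrast(enhance=False),
                ChannelContrast(saturation_fraction=0.0, scope="individual"),
            ),
        )
        out, _ = enhance_dataset([rec], policy)
        np.testing.assert_array_equal(out[0].planes[0].pixels, [[10, 100]])
        np.testing.assert_array_equal(out[0].planes[1].pixels, [[0, 255]])

    def test_mixed_bit_depths_fatal(self):
        a = record("a", [[0, 100]], dtype=np.uint8)
        b = record("b", [[0, 100]], dtype=np.uint16)
        with pytest.raises(ContrastError, match="bit depth"):
            enhance_dataset([a, b], ContrastPolicy(mode="autoscale"))

    def test_channel_count_mismatch_with_policy(self):
        rec = record("a", [[0, 1]])
        policy = ContrastPolicy(
            mode="user_defined", channels=(ChannelContrast(), ChannelContrast())
        )
        with pytest.raises(ConfigurationError):
            enhance_dataset([rec], policy)

    def test_joint_ratio_preservation(self, rng):
        # with pooled low bound 0, mean ratios between records survive stretching
        base = rng.integers(0, 3000, (16, 16)).astype(np.uint16)
        a = record("a", base, dtype=np.uint16)
        b = record("b", base * 3, dtype=np.uint16)
        zero = record("z", np.zeros((16, 16), dtype=np.uint16), dtype=np.uint16)
        policy = ContrastPolicy(
            mode="user_defined",
            channels=(ChannelContrast(saturation_fraction=0.0, scope="joint"),),
        )
        out, _ = enhance_dataset([a, b, zero], policy)
        mean_a = out[0].planes[0].pixels.mean()
        mean_b = out[1].planes[0].pixels.mean()
        assert mean_b / mean_a == pytest.approx(3.0, rel=1e-3)
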