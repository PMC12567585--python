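"""Signal-to-image encoding: ENMO, normalisation, polar/Gramian transform,
PAA downsampling and windowing."""

import numpy as np
import pytest

from actifuse.gaf import (EnmoSeries, TriaxialSeries, WindowingConfig,
                          compute_enmo, gaf_matrix, minmax_normalise,
                          paa_downsample, polar_encode, rescale_unit,
                          window_to_sequence)
from conftest import make_series


def triax(x, y, z):
    n = len(x)
    return TriaxialSeries(timestamps=np.arange(n) / 100.0, x=x, y=y, z=z)


class TestEnmo:
    @pytest.mark.parametrize("xyz,expected", [
        ((0.0, 0.0, 1.0), 0.0),    # stationary device under 1 g
        ((0.6, 0.8, 0.0), 0.0),    # any unit-norm orientation
        ((1.0, 2.0, 2.0), 2.0),    # sqrt(9) - 1
    ])
    def test_known_values(self, xyz, expected):
        series = triax(*[np.array([v, v]) for v in xyz])
        np.testing.assert_allclose(compute_enmo(series).values, expected, atol=1e-12)

    def test_unit_norm_signal_gives_identically_zero(self, rng):
        # any rotation of gravity has norm 1, so ENMO must vanish everywhere
        phi = rng.uniform(0, 2 * np.pi, 50)
        psi = rng.uniform(0, np.pi, 50)
        series = triax(np.sin(psi) * np.cos(phi), np.sin(psi) * np.sin(phi), np.cos(psi))
        np.testing.assert_allclose(compute_enmo(series).values, 0.0, atol=1e-12)

    def test_clip_negative(self):
        series = triax(np.array([0.0, 0.3]), np.array([0.0, 0.0]), np.array([0.5, 0.4]))
        raw = compute_enmo(series, clip_negative=False).values
        clipped = compute_enmo(series, clip_negative=True).values
        assert raw[0] < 0 and clipped[0] == 0.0
        assert np.all(clipped >= 0)

    def test_non_finite_sample_named_in_error(self):
        with pytest.raises(ValueError, match="index 3"):
            triax(np.r_[np.ones(3), np.nan, 1.0], np.zeros(5), np.zeros(5))


class TestMinMaxNormalise:
    def test_examples(self):
        np.testing.assert_allclose(minmax_normalise([0, 5, 10]).values, [-1, 0, 1])
        np.testing.assert_allclose(minmax_normalise([-1, 1]).values, [-1, 1])

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalise([3.0, 3.0, 3.0])

    def test_endpoints_always_attained(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 40))
            if v.max() == v.min():
                continue
            out = minmax_normalise(v).values
            assert out.min() == -1.0 and out.max() == 1.0

    def test_source_range_retained(self):
        out = minmax_normalise([2.0, 4.0, 8.0])
        assert out.source_min == 2.0 and out.source_max == 8.0


class TestPolarEncode:
    def test_angle_anchors(self):
        norm = minmax_normalise([1.0, 0.0, -1.0])  # maps onto itself
        polar = polar_encode(norm)
        np.testing.assert_allclose(polar.theta, [0.0, np.pi / 2, np.pi], atol=1e-12)

    def test_radius_is_normalised_time_index(self):
        polar = polar_encode(minmax_normalise([0, 1, 2, 3]))
        np.testing.assert_allclose(polar.radius, [0.25, 0.5, 0.75, 1.0])
        assert np.all(np.diff(polar.radius) > 0)

    def test_arccos_inverts(self, rng):
        v = rng.uniform(-1, 1, 64)
        from actifuse.gaf import NormalisedSeries
        polar = polar_encode(NormalisedSeries(values=v, source_min=-1, source_max=1))
        np.testing.assert_allclose(np.cos(polar.theta), v, atol=1e-12)

    def test_out_of_range_raises_but_tolerance_clamps(self):
        from actifuse.gaf import NormalisedSeries
        ns = NormalisedSeries(values=np.array([1.0 + 1e-12, -1.0]), source_min=-1, source_max=1)
        polar = polar_encode(ns)  # within tolerance: clamped
        assert np.isfinite(polar.theta).all()
        bad = NormalisedSeries(values=np.array([1.5, 0.0]), source_min=-1, source_max=1)
        with pytest.raises(ValueError, match="outside"):
            polar_encode(bad)


class TestGafMatrix:
    def test_two_point_examples(self):
        from actifuse.gaf import NormalisedSeries

        def gaf_of(v):
            return gaf_matrix(polar_encode(
                NormalisedSeries(values=np.asarray(v, float), source_min=-1, source_max=1)))

        np.testing.assert_allclose(gaf_of([1, -1]), [[1, -1], [-1, 1]], atol=1e-12)
        np.testing.assert_allclose(gaf_of([0, 0]), [[-1, -1], [-1, -1]], atol=1e-12)

    def test_trig_identity_oracle(self, rng):
        # cos(a+b) = cos a cos b - sin a sin b gives the algebraic form
        # v v^T - sqrt(1-v^2) sqrt(1-v^2)^T, computed without arccos/cos
        from actifuse.gaf import NormalisedSeries
        for _ in range(50):
            v = rng.uniform(-1, 1, rng.integers(2, 64))
            G = gaf_matrix(polar_encode(NormalisedSeries(values=v, source_min=-1, source_max=1)))
            s = np.sqrt(1.0 - v ** 2)
            oracle = np.outer(v, v) - np.outer(s, s)
            np.testing.assert_allclose(G, oracle, atol=1e-10)
            assert np.allclose(G, G.T) and np.all(np.abs(G) <= 1 + 1e-12)

    def test_diagonal_is_double_angle(self, rng):
        from actifuse.gaf import NormalisedSeries
        v = rng.uniform(-1, 1, 32)
        G = gaf_matrix(polar_encode(NormalisedSeries(values=v, source_min=-1, source_max=1)))
        np.testing.assert_allclose(np.diag(G), 2 * v ** 2 - 1, atol=1e-10)

    def test_order_sensitivity(self):
        # equal cumulative activity, different temporal pattern -> different image
        v = np.array([0.9, -0.2, 0.1, -0.8, 0.4])
        from actifuse.gaf import NormalisedSeries

        def gaf_of(vv):
            return gaf_matrix(polar_encode(
                NormalisedSeries(values=vv, source_min=-1, source_max=1)))

        assert not np.allclose(gaf_of(v), gaf_of(v[::-1]))

    def test_empty_rejected(self):
        from actifuse.gaf import PolarSeries
        with pytest.raises(ValueError):
            gaf_matrix(PolarSeries(theta=np.array([]), radius=np.array([])))


class TestRescaleUnit:
    def test_affine_anchors_and_roundtrip(self, rng):
        G = np.array([[-1.0, 0.0], [0.0, 1.0]])
        img = rescale_unit(G).matrix
        np.testing.assert_allclose(img, [[0.0, 0.5], [0.5, 1.0]])
        H = rng.uniform(-1, 1, (8, 8))
        H = (H + H.T) / 2
        img = rescale_unit(H).matrix
        assert np.allclose(img, img.T)
        np.testing.assert_allclose(2 * img - 1, H, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rescale_unit(np.array([[1.7]]))


class TestPaaDownsample:
    def test_examples(self):
        np.testing.assert_allclose(paa_downsample([1, 1, 2, 2], 2), [1.0, 2.0])
        np.testing.assert_allclose(paa_downsample([1, 2, 3], 3), [1, 2, 3])
        np.testing.assert_allclose(paa_downsample([1, 2, 3], 2), [4 / 3, 8 / 3], atol=1e-12)

    def test_fractional_bin_oracle(self, rng):
        # brute-force oracle: integrate the step function over each bin
        for _ in range(25):
            n = int(rng.integers(2, 60))
            m = int(rng.integers(1, n + 1))
            v = rng.normal(size=n)
            grid = 720  # fine subdivision of each sample
            fine = np.repeat(v, grid)
            expected = fine[: (n * grid // m) * m].reshape(m, -1).mean(axis=1) \
                if (n * grid) % m == 0 else None
            if expected is None:
                continue
            np.testing.assert_allclose(paa_downsample(v, m), expected, atol=1e-9)

    def test_mean_preserved(self, rng):
        v = rng.normal(size=37)
        out = paa_downsample(v, 11)
        # equal-measure bins: the weighted mean of bin means equals the mean
        np.testing.assert_allclose(out.mean(), v.mean(), atol=1e-10)

    def test_no_upsampling(self):
        with pytest.raises(ValueError, match="upsample"):
            paa_downsample([1, 2], 3)


class TestWindowToSequence:
    def test_floor_rule(self, tiny_windowing, rng):
        # 0.5 s windows at 100 Hz = 50 samples; 5 frames/sequence = 250 samples
        for n_windows, expect in [(5, 1), (9, 1), (10, 2), (4, 0)]:
            enmo = EnmoSeries(values=rng.normal(size=50 * n_windows), rate_hz=100.0)
            seqs = window_to_sequence(enmo, tiny_windowing, subject_id="s")
            assert len(seqs) == expect

    def test_window_bookkeeping_and_shape(self, tiny_windowing, rng):
        enmo = EnmoSeries(values=rng.normal(size=50 * 10), rate_hz=100.0)
        seqs = window_to_sequence(enmo, tiny_windowing)
        seq = seqs[1]
        assert seq.frames.shape == (5, 3, 16, 16)
        assert seq.windows[0] == (250, 300)  # half-open, 0-based, consecutive
        assert seq.windows[-1] == (450, 500)
        # replicate mode: all three channels identical
        np.testing.assert_array_equal(seq.frames[0, 0], seq.frames[0, 1])
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0

    def test_sequence_count_formula(self):
        series = make_series(n=6100, seed=3)
        cfg = WindowingConfig(window_seconds=1.0, image_size=32, frames_per_sequence=5)
        seqs = window_to_sequence(compute_enmo(series), cfg)
        # 6100 samples -> 61 windows -> floor(61 / 5) = 12 sequences
        assert len(seqs) == 12

    def test_per_axis_mode(self, rng):
        series = make_series(n=300, seed=4)
        cfg = WindowingConfig(window_seconds=0.5, image_size=16,
                              frames_per_sequence=5, channel_mode="per_axis")
        enmo = compute_enmo(series)
        seqs = window_to_sequence(enmo, cfg, axes=(series.x, series.y, series.z))
        assert len(seqs) == 1
        # channels now differ (different axes)
        assert not np.allclose(seqs[0].frames[0, 0], seqs[0].frames[0, 2])

    def test_short_series_warns_not_raises(self, tiny_windowing, caplog):
        import logging
        enmo = EnmoSeries(values=np.random.default_rng(0).normal(size=100), rate_hz=100.0)
        with caplog.at_level(logging.WARNING, logger="actifuse.gaf"):
            assert window_to_sequence(enmo, tiny_windowing) == []
        assert any("too short" in r.message for r in caplog.records)
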