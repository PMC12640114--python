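"""Independent-oracle tests for RF tuning metrics and weight dynamics."""

import numpy as np
import pytest

from plastinet.network import ArchConfig, build_model
from plastinet.representations import (
    FilterRaster,
    adjacent_epoch_correlation,
    below_diagonal_count,
    color_tuning_score,
    dynamics_profile,
    extract_first_layer,
    filter_mosaic,
    sf_centroid,
    weight_change_magnitude,
)


def _random_filter(rng, k=5):
    return FilterRaster(0, rng.standard_normal((k, k, 3)))


class TestColorTuningScore:
    def test_equal_channels_score_zero(self, rng):
        g = rng.standard_normal((5, 5, 1))
        f = FilterRaster(0, np.repeat(g, 3, axis=2))
        assert color_tuning_score(f) == pytest.approx(0.0, abs=1e-12)

    def test_zero_sum_channels_score_one(self):
        w = np.zeros((5, 5, 3))
        w[..., 0], w[..., 1] = 1.0, -1.0
        assert color_tuning_score(FilterRaster(0, w)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_pixel_projection_oracle(self, rng):
        f = _random_filter(rng)
        # brute force: loop over pixels, project each RGB triplet
        axis = np.ones(3) / np.sqrt(3)
        resid = total = 0.0
        for i in range(5):
            for j in range(5):
                v = f.weights[i, j]
                a = np.dot(v, axis) * axis
                resid += np.sum((v - a) ** 2)
                total += np.sum(v**2)
        assert color_tuning_score(f) == pytest.approx(resid / total, abs=1e-10)

    def test_scale_invariant(self, rng):
        f = _random_filter(rng)
        scaled = FilterRaster(0, 7.3 * f.weights)
        assert color_tuning_score(scaled) == pytest.approx(color_tuning_score(f), abs=1e-12)

    def test_all_zero_filter_defined(self):
        assert color_tuning_score(FilterRaster(0, np.zeros((5, 5, 3)))) == 0.0


class TestSfCentroid:
    def test_constant_filter_zero(self):
        assert sf_centroid(FilterRaster(0, np.ones((5, 5, 3)))) == 0.0

    def test_pure_sinusoid_recovers_frequency(self):
        # 16x16 filter, horizontal sinusoid at exactly 0.25 cycles/pixel
        x = np.arange(16)
        wave = np.cos(2 * np.pi * 0.25 * x)
        w = np.repeat(np.tile(wave, (16, 1))[:, :, None], 3, axis=2)
        assert sf_centroid(FilterRaster(0, w)) == pytest.approx(0.25, abs=1e-9)

    def test_blurred_filter_has_lower_centroid(self, rng):
        from scipy import ndimage

        w = rng.standard_normal((15, 15, 3))
        blurred = ndimage.gaussian_filter(w, sigma=(1.5, 1.5, 0))
        assert sf_centroid(FilterRaster(0, blurred)) <= sf_centroid(FilterRaster(0, w))

    def test_amplitude_and_offset_invariance(self, rng):
        f = _random_filter(rng, k=7)
        shifted = FilterRaster(0, 3.0 * f.weights + 2.0)
        assert sf_centroid(shifted) == pytest.approx(sf_centroid(f), abs=1e-9)


class TestBelowDiagonalCount:
    def test_ties_do_not_count(self):
        assert below_diagonal_count([(0.3, 0.3)] * 4) == (0, 4)

    def test_mixed_example(self):
        assert below_diagonal_count([(0.1, 0.2), (0.3, 0.3), (0.5, 0.4)]) == (1, 3)

    def test_matches_loop_oracle(self, rng):
        pairs = [tuple(p) for p in rng.random((50, 2))]
        count = sum(1 for a, b in pairs if a < b)
        assert below_diagonal_count(pairs) == (count, 50)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            below_diagonal_count([])


class TestWeightDynamics:
    @pytest.fixture()
    def checkpoints(self, tiny_arch, rng):
        c0 = build_model(tiny_arch, seed=1)
        c1 = build_model(tiny_arch, seed=1)
        c1.epoch = 1
        for layer in c1.layers.values():
            layer["W"] = layer["W"] + rng.standard_normal(layer["W"].shape).astype("f4") * 0.01
        return c0, c1

    def test_identical_checkpoints(self, tiny_arch):
        c0 = build_model(tiny_arch, seed=1)
        c1 = build_model(tiny_arch, seed=1)
        assert weight_change_magnitude(c0, c1, "conv1") == 0.0
        assert adjacent_epoch_correlation(c0, c1, "conv1") == pytest.approx(1.0)

    def test_constant_shift_gives_shift_magnitude(self, tiny_arch):
        c0 = build_model(tiny_arch, seed=1)
        c1 = build_model(tiny_arch, seed=1)
        c1.layers["conv2"]["W"] = c1.layers["conv2"]["W"] + 0.25
        assert weight_change_magnitude(c0, c1, "conv2") == pytest.approx(0.25, rel=1e-6)

    def test_magnitude_matches_elementwise_oracle(self, checkpoints):
        c0, c1 = checkpoints
        a = c0.layers["fc1"]["W"].ravel()
        b = c1.layers["fc1"]["W"].ravel()
        brute = sum(abs(float(x) - float(y)) for x, y in zip(a, b)) / a.size
        assert weight_change_magnitude(c0, c1, "fc1") == pytest.approx(brute, abs=1e-12)

    def test_correlation_scale_and_sign(self, tiny_arch):
        c0 = build_model(tiny_arch, seed=1)
        scaled = build_model(tiny_arch, seed=1)
        scaled.layers["conv1"]["W"] = 2.0 * scaled.layers["conv1"]["W"]
        negated = build_model(tiny_arch, seed=1)
        negated.layers["conv1"]["W"] = -negated.layers["conv1"]["W"]
        assert adjacent_epoch_correlation(c0, scaled, "conv1") == pytest.approx(1.0)
        assert adjacent_epoch_correlation(c0, negated, "conv1") == pytest.approx(-1.0)

    def test_affine_invariance(self, checkpoints):
        c0, c1 = checkpoints
        base = adjacent_epoch_correlation(c0, c1, "conv1")
        c1.layers["conv1"]["W"] = 1.7 * c1.layers["conv1"]["W"] + 0.3
        assert adjacent_epoch_correlation(c0, c1, "conv1") == pytest.approx(base, abs=1e-6)

    def test_zero_variance_flagged_nan(self, tiny_arch):
        c0 = build_model(tiny_arch, seed=1)
        c1 = build_model(tiny_arch, seed=1)
        c1.layers["fc2"]["W"] = np.zeros_like(c1.layers["fc2"]["W"])
        assert np.isnan(adjacent_epoch_correlation(c0, c1, "fc2"))

    def test_shape_mismatch_rejected(self, tiny_arch):
        from plastinet.network import ConvLayerSpec

        c0 = build_model(tiny_arch, seed=1)
        other = ArchConfig(
            conv_layers=(ConvLayerSpec(4, 5, 1, True), ConvLayerSpec(8, 3, 1, True)),
            fc_layers=(16,), n_classes=4, input_size=24,
        )
        c1 = build_model(other, seed=1)
        with pytest.raises(ValueError):
            weight_change_magnitude(c0, c1, "conv1")


class TestExtractionAndProfile:
    def test_first_layer_extraction(self, tiny_arch):
        ckpt = build_model(tiny_arch, seed=4)
        filters = extract_first_layer(ckpt)
        assert len(filters) == tiny_arch.first_layer_filters
        assert filters[0].weights.shape == (3, 3, 3)
        again = extract_first_layer(ckpt)
        np.testing.assert_array_equal(filters[2].weights, again[2].weights)

    def test_mosaic_dimensions(self, tiny_arch):
        filters = extract_first_layer(build_model(tiny_arch, seed=4))
        tile = filter_mosaic(filters, n_cols=2, pad=1)
        # 2 rows x 2 cols of 3-px tiles with 1-px padding
        assert tile.shape == (2 * 4 + 1, 2 * 4 + 1, 3)
        assert tile.min() >= 0 and tile.max() <= 1

    def test_profile_bookkeeping(self, tiny_arch):
        from plastinet.training import RunRecord

        ckpts = [build_model(tiny_arch, seed=s) for s in (1, 2, 3)]
        for i, c in enumerate(ckpts):
            c.epoch = i
        run = RunRecord(regimen=None, lr_schedule=None, seed=0,
                        checkpoints=ckpts, per_epoch=[], arch=tiny_arch)
        records, stab = dynamics_profile(run)
        n_layers = len(tiny_arch.layer_names())
        assert len(records) == n_layers * 2
        assert set(stab) == set(tiny_arch.layer_names())

    def test_profile_requires_two_checkpoints(self, tiny_arch):
        from plastinet.training import RunRecord

        run = RunRecord(regimen=None, lr_schedule=None, seed=0,
                        checkpoints=[build_model(tiny_arch, seed=1)],
                        per_epoch=[], arch=tiny_arch)
        with pytest.raises(ValueError):
            dynamics_profile(run)
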