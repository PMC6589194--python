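import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semsharp import (
    combined_sparsity,
    detect_edges,
    directional_sparsity,
    edge_sparsity,
    edge_width,
    mlv_map,
)

from .oracles import mlv_brute


class TestMLVMap:
    def test_constant_image_zero(self):
        np.testing.assert_array_equal(mlv_map(np.full((8, 8), 3.0)).values, 0.0)

    def test_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 9.0
        out = mlv_map(img).values
        assert out[4, 4] == 9.0
        np.testing.assert_array_equal(out[3:6, 3:6], 9.0)
        mask = np.ones((9, 9), dtype=bool)
        mask[3:6, 3:6] = False
        np.testing.assert_array_equal(out[mask], 0.0)

    def test_checkerboard_all_ones(self):
        idx = np.add.outer(np.arange(8), np.arange(8))
        img = (idx % 2).astype(float)
        np.testing.assert_array_equal(mlv_map(img).values, 1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            img = rng.uniform(0, 255, (8, 8))
            np.testing.assert_allclose(mlv_map(img).values, mlv_brute(img),
                                       atol=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            mlv_map(np.zeros((2, 5)))


class TestDetectEdges:
    def test_constant_map_no_edges(self):
        mlv = mlv_map(np.full((16, 16), 5.0))
        assert not detect_edges(mlv, "vertical").any()

    def test_column_ridge_band(self):
        """Edges of a single-column ridge stay within 3 columns of it."""
        img = np.zeros((32, 32))
        img[:, 16] = 100.0
        mask = detect_edges(mlv_map(img), "vertical")
        cols = np.unique(np.nonzero(mask)[1])
        assert len(cols) > 0
        assert np.all(np.abs(cols - 16) <= 3)

    def test_threshold_monotonicity(self, rng):
        mlv = mlv_map(rng.uniform(0, 255, (32, 32)))
        strict = detect_edges(mlv, "horizontal", threshold_fraction=0.999)
        loose = detect_edges(mlv, "horizontal", threshold_fraction=0.1)
        assert np.all(loose[strict])

    def test_bad_threshold_rejected(self):
        mlv = mlv_map(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="threshold"):
            detect_edges(mlv, "vertical", threshold_fraction=1.5)


class TestEdgeWidth:
    def test_peak_between_minima(self):
        profile = np.array([0.0, 0.0, 2.0, 8.0, 2.0, 0.0, 0.0])
        width, truncated = edge_width(profile, 3)
        assert width == 4
        assert not truncated

    def test_blur_widens(self):
        profile = np.array([0.0, 0, 0, 0, 2, 8, 2, 0, 0, 0, 0.0])
        spread = np.convolve(profile, np.ones(3) / 3, mode="same")
        w0, _ = edge_width(profile, 5)
        w1, _ = edge_width(spread, 5)
        assert w1 > w0

    def test_monotone_ramp_spans_extrema(self):
        profile = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 4.0, 2.0])
        width, _ = edge_width(profile, 3)
        assert width == 5  # minimum at 0, maximum at index 5

    def test_boundary_truncation_flagged(self):
        profile = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        width, truncated = edge_width(profile, 2)
        assert truncated
        assert width == 4


class TestDirectionalSparsity:
    def test_no_edges_gives_zero(self):
        mlv = mlv_map(np.full((16, 16), 2.0))
        value, n = directional_sparsity(mlv, "vertical", mode="width")
        assert value == 0.0 and n == 0

    def test_width_mode_matches_manual_mean(self):
        """Width mode equals (sum of per-pixel widths) / (pixel count)."""
        img = np.zeros((16, 16))
        img[:, 8:] = 120.0
        mlv = mlv_map(img)
        mask = detect_edges(mlv, "vertical")
        total, count = 0, 0
        for r, c in np.argwhere(mask):
            w, _ = edge_width(mlv.values[r], c)
            total += w
            count += 1
        value, n = directional_sparsity(mlv, "vertical", mode="width")
        assert n == count > 0
        assert value == pytest.approx(total / count)

    def test_spacing_mode_is_inverse_density(self):
        """Spacing equals n_lines*length/(count+n_lines) on the edge mask."""
        img = np.zeros((16, 16))
        img[:, 5:] = 80.0
        img[:, 11:] = 200.0
        mlv = mlv_map(img)
        count = int(detect_edges(mlv, "vertical").sum())
        value, n = directional_sparsity(mlv, "vertical", mode="spacing")
        assert n == count > 0
        assert value == pytest.approx(16 * 16 / (count + 16))

    def test_transpose_swaps_directions(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        es = edge_sparsity(img)
        es_t = edge_sparsity(img.T)
        assert es_t.d_v == pytest.approx(es.d_h, abs=1e-12)
        assert es_t.d_h == pytest.approx(es.d_v, abs=1e-12)
        assert es_t.d == pytest.approx(es.d, abs=1e-12)


class TestCombinedSparsity:
    @pytest.mark.parametrize("dv,dh,expected", [
        (3.0, 4.0, 5.0),
        (0.0, 0.0, 0.0),
        (2.5, 2.5, 2.5 * np.sqrt(2)),
    ])
    def test_euclidean_combination(self, dv, dh, expected):
        assert combined_sparsity(dv, dh) == pytest.approx(expected)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_symmetry_and_bounds(self, dv, dh):
        d = combined_sparsity(dv, dh)
        assert d == combined_sparsity(dh, dv)
        assert max(dv, dh) <= d <= dv + dh + 1e-9

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            combined_sparsity(-1.0, 2.0)
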