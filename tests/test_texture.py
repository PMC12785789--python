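"""GLCM construction, texture metrics and the heterogeneity map.

The oracles here are deliberately naive: co-occurrence counts by explicit
pair enumeration, metrics by double loops over all (i, j) cells, and the
heterogeneity map by per-pixel windowed standard deviation on a padded
copy.  They validate both the displacement conventions and the metric
formulas of the fast implementations.
"""

import math

import numpy as np
import pytest

from ecikin.texture import (
    ANGLES,
    GLCMatrix,
    compute_glcm,
    direction_average,
    heterogeneity_map,
    quantize,
    texture_metrics,
    TextureMetrics,
)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(img: np.ndarray, angle: int, symmetric: bool = True) -> np.ndarray:
    """Pair-enumeration co-occurrence probabilities."""
    dr, dc = OFFSETS[angle]
    counts = np.zeros((256, 256))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def metrics_oracle(P: np.ndarray) -> dict:
    """Direct double-loop evaluation of the five metric definitions."""
    n = P.shape[0]
    ent = hom = ene = con = mi = mj = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            if p > 0:
                ent -= p * math.log2(p)
            hom += p / (1 + abs(i - j))
            ene += p * p
            con += p * (i - j) ** 2
            mi += i * p
            mj += j * p
    vi = vj = cov = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            vi += (i - mi) ** 2 * p
            vj += (j - mj) ** 2 * p
            cov += (i - mi) * (j - mj) * p
    corr = cov / math.sqrt(vi * vj) if vi > 0 and vj > 0 else float("nan")
    return {"contrast": con, "entropy": ent, "homogeneity": hom,
            "energy": ene, "correlation": corr}


class TestQuantize:
    def test_uint8_passes_through(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert quantize(img) is img

    def test_uint16_endpoints(self):
        img = np.array([[0, 65535]], dtype=np.uint16)
        assert quantize(img).tolist() == [[0, 255]]

    def test_uint16_midpoint_rounds_half_even(self):
        img = np.full((2, 2), 32768, dtype=np.uint16)  # maps to exactly 127.5
        assert np.all(quantize(img) == 128)

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="grayscale"):
            quantize(np.zeros((4, 4, 3), dtype=np.uint8))


class TestComputeGLCM:
    def test_constant_2x2_concentrates_at_origin(self):
        g = compute_glcm(np.zeros((2, 2), dtype=np.uint8), angle=0)
        assert g.probabilities[0, 0] == 1.0
        assert g.probabilities.sum() == 1.0

    def test_three_pixel_row_enumerated_by_hand(self):
        # pairs (0,1),(1,2) plus transposes after symmetrization: 4 cells of 1/4
        g = compute_glcm(np.array([[0, 1, 2]], dtype=np.uint8), angle=0)
        P = g.probabilities
        assert P[0, 1] == P[1, 0] == P[1, 2] == P[2, 1] == 0.25
        assert P.sum() == 1.0

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_pair_enumeration_oracle(self, angle, symmetric):
        rng = np.random.default_rng(42 + angle)
        img = rng.integers(0, 256, (12, 9), dtype=np.uint8)
        g = compute_glcm(img, angle=angle, symmetric=symmetric)
        assert np.allclose(g.probabilities, glcm_oracle(img, angle, symmetric),
                           atol=1e-12)

    def test_symmetrized_equals_transpose(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        for angle in ANGLES:
            P = compute_glcm(img, angle=angle).probabilities
            assert np.array_equal(P, P.T)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        for angle in ANGLES:
            assert compute_glcm(img, angle=angle).probabilities.sum() == pytest.approx(
                1.0, abs=1e-9)

    def test_unquantized_input_rejected(self):
        with pytest.raises(ValueError, match="quantize"):
            compute_glcm(np.zeros((4, 4)), angle=0)


class TestTextureMetrics:
    @staticmethod
    def _glcm_from(P):
        return GLCMatrix(probabilities=P, angle=0)

    def test_degenerate_single_cell(self):
        P = np.zeros((256, 256))
        P[7, 7] = 1.0
        with pytest.warns(RuntimeWarning, match="correlation undefined"):
            m = texture_metrics(self._glcm_from(P))
        assert m.entropy == 0.0
        assert m.energy == 1.0
        assert m.homogeneity == 1.0
        assert m.contrast == 0.0
        assert math.isnan(m.correlation)

    def test_uniform_distribution(self):
        P = np.full((256, 256), 1.0 / 256**2)
        m = texture_metrics(self._glcm_from(P))
        assert m.entropy == pytest.approx(16.0, abs=1e-9)   # log2(256²)
        assert m.energy == pytest.approx(256.0**-2, rel=1e-12)

    def test_hand_evaluated_three_level_glcm(self):
        g = compute_glcm(np.array([[0, 1, 2]], dtype=np.uint8), angle=0)
        m = texture_metrics(g)
        assert m.contrast == pytest.approx(1.0)
        assert m.homogeneity == pytest.approx(0.5)
        assert m.energy == pytest.approx(0.25)
        assert m.entropy == pytest.approx(2.0)

    def test_matches_double_loop_oracle_on_random_images(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            for angle in ANGLES:
                g = compute_glcm(img, angle=angle)
                m = texture_metrics(g)
                o = metrics_oracle(g.probabilities)
                for name, val in o.items():
                    assert getattr(m, name) == pytest.approx(val, abs=1e-10), name

    def test_transpose_invariance_of_direction_average(self):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)

        def avg_contrast(im):
            return direction_average(
                [texture_metrics(compute_glcm(im, a)) for a in ANGLES]).contrast

        assert avg_contrast(img) == pytest.approx(avg_contrast(img.T), rel=1e-12)


class TestDirectionAverage:
    def _m(self, c=1.0, corr=0.5):
        return TextureMetrics(contrast=c, entropy=2.0, homogeneity=0.5,
                              energy=0.25, correlation=corr)

    def test_identical_sets_unchanged(self):
        m = direction_average([self._m()] * 4)
        assert m == self._m()

    def test_mean_per_metric(self):
        ms = [self._m(c=v) for v in (1, 2, 3, 4)]
        assert direction_average(ms).contrast == pytest.approx(2.5)

    def test_undefined_correlation_contaminates_average(self):
        ms = [self._m(), self._m(), self._m(corr=float("nan")), self._m()]
        assert math.isnan(direction_average(ms).correlation)

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="4 directions"):
            direction_average([self._m()] * 3)


class TestHeterogeneityMap:
    def test_constant_image_all_zero(self):
        assert np.all(heterogeneity_map(np.full((32, 32), 9.0), window=5) == 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            heterogeneity_map(np.zeros((16, 16)), window=4)

    def test_step_edge_against_brute_force(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        window = 7
        got = heterogeneity_map(img, window=window)
        # brute force: windowed population std on a reflect-padded copy
        half = window // 2
        pad = np.pad(img, half, mode="reflect")
        want = np.empty_like(img)
        for r in range(32):
            for c in range(32):
                want[r, c] = pad[r:r + window, c:c + window].std()
        assert np.allclose(got, want, atol=1e-8)
        # the map peaks along the step edge and is non-negative everywhere
        assert got[:, 14:18].max() == got.max()
        assert (got >= 0).all()
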