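import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mptexture.imaging_io import Channel
from conftest import make_fov
from mptexture.texture_features import (ORIENTATION_OFFSETS, TextureConfig,
                                        TextureError, channel_texture_vector,
                                        combine_vectors, first_order_features,
                                        glcm, glcm_properties, minmax_normalize,
                                        quantize)


def brute_force_glcm(img, distance, orientation, levels=None):
    """Independent oracle: explicit pair enumeration, one direction per pair."""
    dr0, dc0 = ORIENTATION_OFFSETS[orientation]
    dr, dc = dr0 * distance, dc0 * distance
    L = levels if levels is not None else int(img.max()) + 1
    counts = np.zeros((max(L, 2), max(L, 2)))
    R, C = img.shape
    for r in range(R):
        for c in range(C):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < R and 0 <= c2 < C:
                counts[img[r, c], img[r2, c2]] += 1
    return counts


class TestMinMaxNormalize:
    def test_simple_rescale(self, fov_factory):
        out = minmax_normalize(fov_factory([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out.pixels, [[0, 0.5, 1], [0, 0.5, 1]])
        assert not out.degenerate

    def test_constant_is_degenerate(self, fov_factory):
        out = minmax_normalize(fov_factory(np.full((4, 4), 9.0)))
        assert out.degenerate
        np.testing.assert_array_equal(out.pixels, np.zeros((4, 4)))

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(0, 100), seed=st.integers(0, 100))
    def test_positive_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random((6, 8)) * 10
        n1 = minmax_normalize(make_fov(x))
        n2 = minmax_normalize(make_fov(a * x + b))
        np.testing.assert_allclose(n1.pixels, n2.pixels, atol=1e-9)


class TestFirstOrder:
    def test_constant_fov(self, fov_factory):
        fo = first_order_features(minmax_normalize(fov_factory(np.full((4, 4), 3.0))))
        assert fo.sd == 0 and fo.entropy_bits == 0
        assert fo.skewness == 0 and fo.kurtosis == 0

    def test_two_point_symmetric(self, fov_factory):
        board = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        fo = first_order_features(minmax_normalize(fov_factory(board)))
        assert fo.mean == pytest.approx(0.5)
        assert fo.skewness == pytest.approx(0.0, abs=1e-12)
        assert fo.kurtosis == pytest.approx(1.0)
        assert fo.entropy_bits == pytest.approx(1.0)

    def test_four_equal_bins_entropy_two(self, fov_factory):
        # values centered in 4 distinct bins of the 256-bin histogram, equal counts
        vals = np.repeat([0.1, 0.3, 0.6, 0.9], 16).reshape(8, 8)
        norm = minmax_normalize(fov_factory(vals))
        fo = first_order_features(norm)
        assert fo.entropy_bits == pytest.approx(2.0)

    def test_sample_sd_uses_n_minus_1(self, fov_factory):
        norm = minmax_normalize(fov_factory([[0.0, 1.0], [0.0, 1.0]]))
        assert first_order_features(norm).sd == pytest.approx(np.std([0, 1, 0, 1], ddof=1))


class TestQuantize:
    def test_two_levels(self, fov_factory):
        norm = minmax_normalize(fov_factory([[0.0, 0.49, 0.51, 1.0]] * 2))
        np.testing.assert_array_equal(quantize(norm, 2), [[0, 0, 1, 1]] * 2)

    def test_four_levels_thirds(self, fov_factory):
        norm = minmax_normalize(fov_factory([[0.0, 1 / 3, 2 / 3, 1.0]] * 2))
        np.testing.assert_array_equal(quantize(norm, 4), [[0, 1, 2, 3]] * 2)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 200))
    def test_range_contract(self, seed):
        x = np.random.default_rng(seed).random((5, 7))
        q = quantize(minmax_normalize(make_fov(x)), 8)
        assert q.min() >= 0 and q.max() <= 7

    def test_levels_below_two_rejected(self, fov_factory):
        norm = minmax_normalize(fov_factory([[0.0, 1.0]] * 2))
        with pytest.raises(TextureError):
            quantize(norm, 1)


class TestGLCM:
    def test_two_row_example(self):
        g = glcm(np.array([[0, 0], [1, 1]]), 1, 0)
        np.testing.assert_allclose(g.counts, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_entry(self):
        g = glcm(np.zeros((4, 4), dtype=int), 1, 45, levels=8)
        assert g.counts[0, 0] == pytest.approx(1.0)
        assert g.counts.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 300), d=st.integers(1, 3),
           orient=st.sampled_from([0, 45, 90, 135]))
    def test_normalization_contract(self, seed, d, orient):
        img = np.random.default_rng(seed).integers(0, 8, (10, 12))
        g = glcm(img, d, orient, levels=8)
        assert g.counts.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 10_000), d=st.integers(1, 3),
           orient=st.sampled_from([0, 45, 90, 135]),
           rows=st.integers(4, 12), cols=st.integers(4, 12),
           levels=st.integers(2, 8))
    def test_matches_brute_force_enumeration(self, seed, d, orient, rows, cols, levels):
        img = np.random.default_rng(seed).integers(0, levels, (rows, cols))
        mine = glcm(img, d, orient, levels=levels, normalize=False).counts
        oracle = brute_force_glcm(img, d, orient, levels=levels)
        np.testing.assert_array_equal(mine, oracle)

    def test_distance_too_large(self):
        with pytest.raises(TextureError, match="no co-occurring pairs"):
            glcm(np.zeros((3, 3), dtype=int), 3, 0, levels=2)


class TestGLCMProperties:
    def test_diagonal_half_half(self):
        g = glcm(np.array([[0, 0], [1, 1]]), 1, 0)
        props = glcm_properties(g)
        assert props.contrast == pytest.approx(0.0)
        assert props.correlation == pytest.approx(1.0)
        assert props.energy == pytest.approx(0.5)
        assert props.homogeneity == pytest.approx(1.0)

    def test_single_entry_mass(self):
        g = glcm(np.zeros((3, 3), dtype=int), 1, 0, levels=4)
        props = glcm_properties(g)
        assert (props.contrast, props.correlation, props.energy,
                props.homogeneity) == (0.0, 1.0, 1.0, 1.0)

    def test_uniform_energy_closed_form(self):
        from mptexture.texture_features import GLCMatrix
        L = 4
        g = GLCMatrix(counts=np.full((L, L), 1 / L ** 2), levels=L, distance_px=1,
                      orientation_deg=0, normalized=True)
        assert glcm_properties(g).energy == pytest.approx(1 / L ** 2)

    def test_unnormalized_rejected(self):
        g = glcm(np.array([[0, 1], [1, 0]]), 1, 0, normalize=False)
        with pytest.raises(TextureError, match="normalized"):
            glcm_properties(g)

    def test_cross_check_against_skimage_graycoprops(self, rng):
        """Orientation-averaged properties agree with scikit-image.

        At distance 1 both offset conventions visit the same pixel pairs up to
        matrix transposition, which leaves every property invariant.  (At
        larger distances skimage rounds diagonal offsets to Euclidean length
        while this package steps d pixels along each axis.)  Naming maps:
        this package's energy Σp² is skimage's "ASM" (skimage's "energy" is
        √ASM), and its homogeneity 1/(1+|i−j|) has no skimage equivalent
        (skimage divides by 1+(i−j)²).
        """
        skimage_feature = pytest.importorskip("skimage.feature")
        img = rng.integers(0, 8, (24, 30)).astype(np.uint8)
        angles = [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
        sk = skimage_feature.graycomatrix(img, [1], angles, levels=8, symmetric=False,
                                          normed=True)
        for mine_name, sk_name in (("contrast", "contrast"),
                                   ("correlation", "correlation"),
                                   ("energy", "ASM")):
            sk_avg = skimage_feature.graycoprops(sk, sk_name)[0].mean()
            mine = np.mean([getattr(glcm_properties(glcm(img, 1, o, levels=8)),
                                    mine_name)
                            for o in (0, 45, 90, 135)])
            assert mine == pytest.approx(sk_avg, abs=1e-10)


class TestChannelVector:
    def test_thirteen_parameters(self, fov_factory, rng):
        fov = fov_factory(rng.random((104, 208)))
        vec = channel_texture_vector(fov)
        assert len(vec.values) == 13
        assert vec.names[:5] == ("mean", "sd", "kurtosis", "skewness", "entropy_bits")
        assert vec.names[5] == "contrast_d6" and vec.names[-1] == "homogeneity_d40"

    def test_affine_invariance(self, fov_factory, rng, small_config):
        x = rng.random((32, 48))
        v1 = channel_texture_vector(fov_factory(x), small_config)
        v2 = channel_texture_vector(fov_factory(3.7 * x + 11.0), small_config)
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-9)

    def test_quarter_turn_invariance_of_glcm_features(self, fov_factory, rng):
        """The 4-orientation offset set maps onto itself under 90° rotation."""
        cfg = TextureConfig(distances_um=(2.0, 5.0), fov_rows=40, fov_cols=40)
        x = rng.random((40, 40))
        v1 = channel_texture_vector(fov_factory(x), cfg)
        v2 = channel_texture_vector(fov_factory(np.rot90(x)), cfg)
        np.testing.assert_allclose(v1.values[5:], v2.values[5:], atol=1e-9)

    def test_fov_smaller_than_distance_errors(self, fov_factory, rng):
        fov = fov_factory(rng.random((20, 30)))
        with pytest.raises(TextureError, match="40"):
            channel_texture_vector(fov, TextureConfig())

    def test_degenerate_fov_is_finite_and_flagged(self, fov_factory):
        fov = fov_factory(np.full((32, 48), 5.0), channel=Channel.SHG)
        vec = channel_texture_vector(fov, TextureConfig(distances_um=(2.0, 5.0)))
        assert vec.degenerate
        assert np.all(np.isfinite(vec.values))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 500))
    def test_feature_bounds(self, seed):
        cfg = TextureConfig(distances_um=(2.0, 5.0), fov_rows=32, fov_cols=48)
        x = np.random.default_rng(seed).random((32, 48))
        vec = channel_texture_vector(make_fov(x), cfg)
        f = dict(zip(vec.names, vec.values))
        assert 0 <= f["entropy_bits"] <= 8
        for d in ("2", "5"):
            assert 0 < f[f"energy_d{d}"] <= 1
            assert 0 < f[f"homogeneity_d{d}"] <= 1
            assert -1 <= f[f"correlation_d{d}"] <= 1
            assert 0 <= f[f"contrast_d{d}"] <= 49  # (L-1)^2 with L=8


class TestCombineVectors:
    def _vec(self, fov_factory, rng, channel, sample="s1"):
        cfg = TextureConfig(distances_um=(2.0, 5.0))
        return channel_texture_vector(
            fov_factory(rng.random((32, 48)), channel=channel, sample_id=sample), cfg)

    def test_cars_tpef_gives_26(self, fov_factory, rng):
        combined = combine_vectors([self._vec(fov_factory, rng, Channel.CARS),
                                    self._vec(fov_factory, rng, Channel.TPEF)])
        assert len(combined.values) == 26
        assert combined.names[0] == "CARS_mean" and combined.names[13] == "TPEF_mean"

    def test_single_channel_identity(self, fov_factory, rng):
        v = self._vec(fov_factory, rng, Channel.CARS)
        combined = combine_vectors([v])
        np.testing.assert_array_equal(combined.values, v.values)
        assert len(combined.values) == 13

    def test_three_channels_gives_39(self, fov_factory, rng):
        combined = combine_vectors([self._vec(fov_factory, rng, c)
                                    for c in (Channel.CARS, Channel.TPEF, Channel.SHG)])
        assert len(combined.values) == 39

    def test_mixed_provenance_rejected(self, fov_factory, rng):
        with pytest.raises(TextureError, match="provenance"):
            combine_vectors([self._vec(fov_factory, rng, Channel.CARS, sample="a"),
                             self._vec(fov_factory, rng, Channel.TPEF, sample="b")])
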