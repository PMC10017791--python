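"""Texture feature correctness: closed forms, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from helpers import brute_force_glcm
from mpmtex.features import (
    FIRST_ORDER,
    ORIENTATION_OFFSETS,
    FeatureSpec,
    extract_features,
    first_order_features,
    glcm,
    glcm_features,
    normalize_channel,
)
from mpmtex.types import FovImage


class TestNormalize:
    def test_affine_closed_form(self):
        x = np.array([[2.0, 6.0], [10.0, 2.0]])
        out = normalize_channel(x)
        assert out[0, 1] == 0.5
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_raster_flagged_zero(self):
        out, degenerate = normalize_channel(np.full((4, 4), 7.0), return_degenerate=True)
        assert degenerate
        assert np.all(out == 0.0)

    def test_unit_range_identity(self):
        x = np.array([[0.0, 0.25], [0.75, 1.0]])
        assert np.array_equal(normalize_channel(x), x)

    def test_gain_invariance(self, rng):
        x = rng.random((20, 30))
        assert np.allclose(normalize_channel(x), normalize_channel(3.7 * x))


class TestFirstOrder:
    def test_constant_degenerate_convention(self):
        fo = first_order_features(np.zeros((8, 8)))
        assert fo.sd == 0 and fo.skewness == 0 and fo.kurtosis == 0 and fo.entropy == 0

    def test_two_point_symmetric_distribution(self):
        # half zeros, half ones: mean .5, sd .5, skew 0, kurtosis m4/m2^2 = 1,
        # entropy of a fair coin = 1 bit
        x = np.concatenate([np.zeros(50), np.ones(50)]).reshape(10, 10)
        fo = first_order_features(x)
        assert fo.mean == 0.5
        assert fo.sd == 0.5
        assert fo.skewness == pytest.approx(0, abs=1e-12)
        assert fo.kurtosis == pytest.approx(1, abs=1e-12)
        assert fo.entropy == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_kurtosis_near_three(self, rng):
        x = np.clip(rng.normal(0.5, 0.07, size=(400, 400)), 0, 1)
        assert first_order_features(x).kurtosis == pytest.approx(3.0, abs=0.1)

    def test_matches_scipy_moment_conventions(self, rng):
        from scipy import stats

        x = rng.random((30, 40))
        fo = first_order_features(x)
        flat = x.ravel()
        assert fo.skewness == pytest.approx(stats.skew(flat, bias=True), abs=1e-12)
        assert fo.kurtosis == pytest.approx(
            stats.kurtosis(flat, fisher=False, bias=True), abs=1e-12
        )


class TestGlcm:
    two_band = np.array([[0.0, 0.0], [1.0, 1.0]])

    def test_horizontal_pairs_hand_enumerated(self):
        P = glcm(self.two_band, distance=1, orientation=0, levels=2)
        assert P[0, 0] == 0.5 and P[1, 1] == 0.5 and P.sum() == 1.0

    def test_vertical_pairs_asymmetric_and_symmetric(self):
        P = glcm(self.two_band, distance=1, orientation=90, levels=2)
        assert P[1, 0] == 1.0
        Ps = glcm(self.two_band, distance=1, orientation=90, levels=2, symmetric=True)
        assert Ps[1, 0] == 0.5 and Ps[0, 1] == 0.5

    def test_normalized(self, rng):
        P = glcm(rng.random((9, 7)), distance=2, orientation=45, levels=4)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_distance_beyond_extent_errors(self):
        with pytest.raises(ValueError, match="no valid pairs"):
            glcm(np.zeros((3, 3)), distance=5, orientation=90, levels=2)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        raster=hnp.arrays(
            np.float64,
            st.tuples(st.integers(2, 16), st.integers(2, 16)),
            elements=st.floats(0, 1, allow_nan=False),
        ),
        distance=st.integers(1, 3),
        orientation=st.sampled_from([0, 45, 90, 135]),
        levels=st.integers(2, 4),
        symmetric=st.booleans(),
    )
    def test_equals_brute_force_enumeration(
        self, raster, distance, orientation, levels, symmetric
    ):
        R, C = raster.shape
        dr, dc = ORIENTATION_OFFSETS[orientation]
        no_pairs = abs(dr) * distance >= R or abs(dc) * distance >= C
        if no_pairs:
            with pytest.raises(ValueError, match="no valid pairs"):
                glcm(raster, distance, orientation, levels, symmetric)
            return
        ours = glcm(raster, distance, orientation, levels, symmetric)
        oracle = brute_force_glcm(raster, distance, orientation, levels, symmetric)
        assert np.array_equal(ours, oracle)


class TestGlcmFeatures:
    def test_diagonal_matrix(self):
        P = np.diag([0.25, 0.25, 0.5])
        f = glcm_features(P)
        assert f.contrast == 0.0 and f.homogeneity == 1.0

    def test_uniform_two_by_two(self):
        f = glcm_features(np.full((2, 2), 0.25))
        assert f.energy == 0.25
        assert f.contrast == 0.5
        assert f.homogeneity == 0.75
        assert f.correlation == 0.0

    def test_single_cell_degenerate(self):
        P = np.zeros((3, 3))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f.energy == 1.0 and f.correlation == 0.0

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="not normalized"):
            glcm_features(np.full((2, 2), 0.5))

    def test_ranges_on_random_rasters(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(4, 20, 2))
            P = glcm(rng.random(shape), 1, int(rng.choice([0, 45, 90, 135])), 8)
            f = glcm_features(P)
            assert f.contrast >= 0
            assert 0 < f.energy <= 1
            assert 0 < f.homogeneity <= 1
            assert abs(f.correlation) <= 1 + 1e-9


def _fov_from(cars, tpef=None, shg=None):
    cars = np.asarray(cars, dtype=np.float64)
    tpef = cars.copy() if tpef is None else tpef
    shg = cars.copy() if shg is None else shg
    return FovImage(cars=cars, tpef=tpef, shg=shg, tile_row=0, tile_col=0, fov_id="f")


class TestExtraction:
    def test_full_spec_channel_and_total_counts(self, rng):
        fov = _fov_from(rng.random((40, 40)))
        full = FeatureSpec.full()
        assert len(full.channel_features("cars")) == 17
        assert len(extract_features(fov, full)) == 51
        reduced = FeatureSpec.reduced_shg()
        assert len(reduced.channel_features("shg")) == 8
        assert len(extract_features(fov, reduced)) == 42

    def test_feature_names_match_values_order(self, rng):
        spec = FeatureSpec.reduced_shg(distances=(1, 2))
        fov = _fov_from(rng.random((20, 20)))
        fv = extract_features(fov, spec)
        assert len(fv.names) == len(fv.values) == spec.n_features()
        assert fv.names[:5] == tuple(f"cars_{f}" for f in FIRST_ORDER)
        assert fv.names[-1] == "shg_contrast_d2"

    def test_gain_invariance_before_normalization(self, rng):
        x = rng.random((30, 30))
        spec = FeatureSpec.cars_only(distances=(1, 3))
        a = extract_features(_fov_from(x), spec)
        b = extract_features(_fov_from(9.25 * x), spec)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_rotation_invariance_with_symmetric_glcm(self, rng):
        # rotating a square raster by 90 deg permutes the orientation set,
        # so orientation-averaged symmetric-GLCM features are unchanged
        x = rng.random((24, 24))
        spec = FeatureSpec.cars_only(distances=(1, 2), glcm_symmetric=True)
        a = extract_features(_fov_from(x), spec)
        b = extract_features(_fov_from(np.rot90(x).copy()), spec)
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_orientation_average_matches_skimage(self, rng):
        # independent route: skimage co-occurrence on the same quantized image
        from skimage.feature import graycomatrix, graycoprops

        from mpmtex.features import quantize

        # distance 1 only: at larger distances skimage rounds the diagonal
        # offsets to d/sqrt(2) per axis, whereas here the exact (-d, +d)
        # convention applies; axial orientations are covered by the
        # brute-force enumeration oracle for all distances
        x = rng.random((31, 43))
        levels = 8
        spec = FeatureSpec.cars_only(distances=(1,))
        fv = extract_features(_fov_from(x), spec)
        q = quantize(normalize_channel(x), levels).astype(np.uint8)
        P = graycomatrix(
            q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=levels, normed=True
        )
        names = dict(zip(fv.names, fv.values))
        for ours, theirs in [
            ("contrast", "contrast"),
            ("correlation", "correlation"),
            ("energy", "ASM"),
        ]:
            skim = graycoprops(P, theirs)[0].mean()
            assert names[f"cars_{ours}_d1"] == pytest.approx(skim, abs=1e-10)
        # skimage's 'homogeneity' is the inverse *squared* difference
        # moment; recompute sum P/(1+|i-j|) on skimage's matrices instead
        idx = np.arange(levels, dtype=float)
        inv_abs_diff = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
        homog = np.mean([(P[:, :, 0, a] * inv_abs_diff).sum() for a in range(4)])
        assert names["cars_homogeneity_d1"] == pytest.approx(homog, abs=1e-10)
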