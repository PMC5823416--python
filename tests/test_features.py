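"""Texture and colour descriptor components: PC, moments, GLCM, histograms."""

import dataclasses

import numpy as np
import pytest
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops

from pyloruskit.features import (
    CTVP_LAYOUT,
    GLCMParams,
    PCParams,
    PCResult,
    ctvp,
    glcm,
    glcm_features,
    hs_histogram,
    log_gabor_bank,
    max_moment,
    phase_congruency,
    quantize,
    rgb_to_hsi,
)
from pyloruskit.synthetic import INTESTINE, STOMACH, generate_frame
from pyloruskit.csd import compute_vrof
from conftest import full_mask, mask_from


def glcm_oracle(q, levels, distance, angle_deg, symmetric=True):
    """Exhaustive pair enumeration at one displacement (independent oracle)."""
    offsets = {0: (0, distance), 45: (-distance, distance),
               90: (-distance, 0), 135: (-distance, -distance)}
    dr, dc = offsets[angle_deg % 180]
    rows, cols = q.shape
    mat = np.zeros((levels, levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                mat[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    mat[q[r2, c2], q[r, c]] += 1
    return mat / mat.sum()


class TestLogGaborBank:
    def test_dc_gain_is_zero_for_every_filter(self):
        bank = log_gabor_bank(PCParams(), (32, 32))
        assert (bank[:, :, 0, 0] == 0).all()

    def test_orientation_count_and_spacing(self):
        params = PCParams(n_orientations=6)
        assert params.orientation_angles == pytest.approx(np.arange(6) * np.pi / 6)

    def test_white_noise_response_positive_and_finite(self, rng):
        params = PCParams(n_scales=3)
        bank = log_gabor_bank(params, (64, 64))
        noise_fft = np.fft.fft2(rng.standard_normal((64, 64)))
        for s in range(3):
            for o in range(params.n_orientations):
                out = np.fft.ifft2(noise_fft * bank[s, o])
                v = np.abs(out).var()
                assert np.isfinite(v) and v > 0

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            log_gabor_bank(PCParams(), (1, 64))


class TestPhaseCongruency:
    def test_constant_image_has_zero_pc(self):
        pc = phase_congruency(np.full((48, 48), 7.5))
        assert pc.pc_maps.max() == 0.0

    def test_values_bounded_in_unit_interval(self, rng):
        pc = phase_congruency(rng.standard_normal((48, 48)))
        assert pc.pc_maps.min() >= 0.0
        assert pc.pc_maps.max() <= 1.0

    def test_invariant_under_intensity_rescaling(self, rng):
        img = rng.standard_normal((64, 64)).cumsum(axis=1)  # correlated field
        pc1 = phase_congruency(img)
        pc2 = phase_congruency(img * 2.0)
        assert np.abs(pc1.pc_maps - pc2.pc_maps).mean() < 1e-3

    def test_step_edge_localization(self):
        img = np.zeros((128, 128))
        img[:, 64:] = 1.0
        pc = phase_congruency(img).pc_maps.max(axis=0)
        edge = pc[:, 63:65].mean()
        # background away from the edge and from the periodic wrap column
        background = pc[:, 16:48].mean()
        assert edge - background >= 0.5


class TestMaxMoment:
    def test_zero_maps_give_zero_moment(self):
        pc = PCResult(pc_maps=np.zeros((3, 4, 4)),
                      orientations=np.arange(3) * np.pi / 3)
        assert max_moment(pc).max() == 0.0

    def test_single_orientation_moment_is_pc_squared(self):
        p = 0.6
        pc = PCResult(pc_maps=np.full((1, 2, 2), p), orientations=np.array([0.0]))
        np.testing.assert_allclose(max_moment(pc), p**2)

    def test_orthogonal_equal_orientations_moment_is_pc_squared(self):
        p = 0.6
        pc = PCResult(
            pc_maps=np.full((2, 2, 2), p), orientations=np.array([0.0, np.pi / 2])
        )
        np.testing.assert_allclose(max_moment(pc), p**2)
        np.testing.assert_allclose(pc.moment_b, 0.0, atol=1e-15)

    def test_moment_nonnegative_on_random_maps(self, rng):
        pc = PCResult(
            pc_maps=rng.uniform(0, 1, (6, 8, 8)),
            orientations=np.arange(6) * np.pi / 6,
        )
        assert max_moment(pc).min() >= 0.0


class TestGLCM:
    def test_two_by_two_hand_example(self):
        c = glcm(
            np.array([[0, 0], [1, 1]]),
            GLCMParams(distance=1, orientations=(0,), levels=2),
            quantized=True,
        )
        np.testing.assert_allclose(c[0], [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_map_concentrates_on_one_diagonal_cell(self):
        c = glcm(np.zeros((5, 5)), GLCMParams(orientations=(0, 90), levels=4))
        for mat in c:
            assert mat[0, 0] == pytest.approx(1.0)
            assert mat.sum() == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_random_maps(self, rng):
        for _ in range(10):
            q = rng.integers(0, 8, size=(8, 8))
            for ang in (0, 45, 90, 135):
                got = glcm(
                    q, GLCMParams(distance=1, orientations=(ang,), levels=8),
                    quantized=True,
                )[0]
                np.testing.assert_array_equal(got, glcm_oracle(q, 8, 1, ang))

    def test_matches_skimage_at_distance_one(self, rng):
        # skimage's angle convention mirrors ours up to pair direction, which
        # symmetric accumulation cancels
        q = rng.integers(0, 6, size=(12, 12))
        ours = glcm(
            q, GLCMParams(distance=1, orientations=(0, 90), levels=6), quantized=True
        )
        theirs = graycomatrix(
            q.astype(np.uint8), [1], [0, np.pi / 2], levels=6,
            symmetric=True, normed=True,
        )
        np.testing.assert_allclose(ours[0], theirs[:, :, 0, 0])
        np.testing.assert_allclose(ours[1], theirs[:, :, 0, 1])

    def test_masked_pairs_are_excluded(self):
        q = np.array([[0, 1, 1], [0, 1, 1], [0, 1, 1]])
        valid = np.ones((3, 3), dtype=bool)
        valid[:, 0] = False  # drop every pair touching column 0
        c = glcm(
            q, GLCMParams(distance=1, orientations=(0,), levels=2),
            quantized=True, valid=valid,
        )[0]
        np.testing.assert_allclose(c, [[0.0, 0.0], [0.0, 1.0]])

    def test_displacement_larger_than_map_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((3, 3)), GLCMParams(distance=4, orientations=(0,)))

    def test_quantize_uses_observed_range(self):
        q = quantize(np.array([[0.0, 1.0], [2.0, 4.0]]), 4)
        assert q.tolist() == [[0, 1], [2, 3]]


class TestGLCMFeatures:
    def test_antidiagonal_free_hand_example(self):
        f = glcm_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert f.contrast == 0.0
        assert f.energy == 0.5
        assert f.homogeneity == 1.0
        assert f.correlation == pytest.approx(1.0)

    def test_uniform_matrix_energy_is_inverse_cell_count(self):
        g = 4
        f = glcm_features(np.full((g, g), 1 / g**2))
        assert f.energy == pytest.approx(1 / g**2)

    def test_constant_image_features(self):
        c = glcm(np.zeros((6, 6)), GLCMParams(orientations=(0,), levels=4))
        f = glcm_features(c)
        assert f.contrast == 0.0
        assert f.homogeneity == pytest.approx(1.0)
        assert f.energy == pytest.approx(1.0)
        assert not f.correlation_defined

    def test_printed_homogeneity_variant(self):
        c = np.array([[0.5, 0.0], [0.0, 0.5]])
        # ux = uy = 0.5; sum (i-.5)(j-.5) C / (1+|i-j|) = 0.25*0.5 + 0.25*0.5
        f = glcm_features(c, homogeneity_variant="printed")
        assert f.homogeneity == pytest.approx(0.25)

    def test_cross_check_against_skimage_graycoprops(self, rng):
        q = rng.integers(0, 8, size=(16, 16))
        ours = glcm(
            q, GLCMParams(distance=1, orientations=(0,), levels=8), quantized=True
        )
        theirs = graycomatrix(
            q.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True
        )
        f = glcm_features(ours[0])
        # homogeneity is omitted: skimage divides by 1+(i-j)^2, this package
        # by 1+|i-j| (the inverse-difference form)
        for name, val in [
            ("contrast", f.contrast),
            ("correlation", f.correlation),
            ("energy", np.sqrt(f.energy)),  # skimage energy = sqrt(sum C^2)
        ]:
            assert val == pytest.approx(float(graycoprops(theirs, name)[0, 0]), abs=1e-10)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((2, 2)))


class TestHSHistogram:
    def test_uniform_hue_image_fills_single_bin(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[...] = (200, 40, 40)  # pure-ish red, hue near 0
        h = hs_histogram(img, full_mask((8, 8)))
        assert h.hist_h.max() == pytest.approx(1.0)
        assert h.hist_h.sum() == pytest.approx(1.0)

    def test_two_tone_halves_give_half_mass_each(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:4] = (200, 40, 40)  # hue bin near 0
        img[4:] = (40, 200, 40)  # green, hue ~1/3
        h = hs_histogram(img, full_mask((8, 8)))
        assert sorted(h.hist_h[h.hist_h > 0].tolist()) == [0.5, 0.5]

    def test_histograms_normalize_to_one(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        h = hs_histogram(img, full_mask((16, 16)))
        assert h.hist_h.sum() == pytest.approx(1.0, abs=1e-9)
        assert h.hist_s.sum() == pytest.approx(1.0, abs=1e-9)

    def test_masked_histogram_equals_cropped_region_histogram(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        m = np.zeros((16, 16), dtype=bool)
        m[4:10, 2:12] = True
        masked = hs_histogram(img, mask_from(m))
        crop = img[4:10, 2:12]
        cropped = hs_histogram(crop, full_mask(crop.shape[:2]))
        np.testing.assert_allclose(masked.hist_h, cropped.hist_h)
        np.testing.assert_allclose(masked.hist_s, cropped.hist_s)

    def test_achromatic_pixels_have_zero_saturation(self):
        img = np.full((4, 4, 3), 128, dtype=np.uint8)
        _, s, _ = rgb_to_hsi(img)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)


class TestCTVP:
    def test_layout_length_36(self):
        assert len(CTVP_LAYOUT) == 36

    def test_identical_frames_give_identical_vectors(self, small_cfg):
        frame = generate_frame(STOMACH, small_cfg, np.random.default_rng(2))
        _, mask = compute_vrof(frame)
        v1 = ctvp(frame, mask)
        v2 = ctvp(frame.copy(), mask)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert len(v1.values) == 36

    def test_intestine_texture_raises_contrast_component(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, color_noise_sd=0.0)
        stomach = generate_frame(STOMACH, cfg, np.random.default_rng(4))
        intestine = generate_frame(INTESTINE, cfg, np.random.default_rng(4))
        vs = ctvp(stomach, compute_vrof(stomach)[1])
        vi = ctvp(intestine, compute_vrof(intestine)[1])
        idx = CTVP_LAYOUT.index("glcm_contrast")
        assert vi.values[idx] > vs.values[idx]

    def test_linear_probe_separates_synthetic_classes(self, small_cfg):
        from sklearn.linear_model import LogisticRegression

        feats, labels = [], []
        for j in range(30):
            for lab_val, organ in ((0, STOMACH), (1, INTESTINE)):
                rng = np.random.default_rng(1000 + 2 * j + lab_val)
                frame = generate_frame(organ, small_cfg, rng)
                feats.append(ctvp(frame, compute_vrof(frame)[1]).values)
                labels.append(lab_val)
        x, y = np.stack(feats), np.array(labels)
        probe = LogisticRegression(max_iter=2000).fit(x, y)
        assert probe.score(x, y) > 0.9
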