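"""HOG/LBP descriptors: analytic examples, brute-force small-patch oracles,
invariances and the subject-level texture vector."""

import dataclasses
import math

import numpy as np
import pytest

from facescreen.errors import DegenerateGeometryError
from facescreen.facenorm import normalize
from facescreen.synthcohort import (CohortConfig, generate_cohort,
                                    landmarks_from_params, render_face)
from facescreen.texfeat import (EYES_LBP, EYES_ROI, MOUTH_LBP, MOUTH_ROI,
                                HogParams, LbpParams, RoiSpec, extract_roi,
                                hog_descriptor, hog_length, lbp_codes,
                                lbp_descriptor, lbp_length, _uniform_lookup,
                                texture_feature_vector)


def normalized_face(params, phase=1.0, seed=0):
    lm = landmarks_from_params(params, phase)
    img = render_face(lm, params, np.random.default_rng(seed))
    return normalize(img, lm)


# ---------------------------------------------------------------------------
# brute-force reference implementations (independent of the library path)
# ---------------------------------------------------------------------------

def hog_reference(patch, params: HogParams):
    """Naive per-pixel HOG with explicit loops."""
    img = np.asarray(patch, float)
    h, w = img.shape
    gy, gx = np.gradient(img)
    ncy, ncx = h // params.cell, w // params.cell
    cells = np.zeros((ncy, ncx, params.bins))
    span = 180.0
    binw = span / params.bins
    for r in range(h):
        for c in range(w):
            mag = math.hypot(gx[r, c], gy[r, c])
            ang = math.degrees(math.atan2(gy[r, c], gx[r, c])) % span
            pos = ang / binw - 0.5
            lo = math.floor(pos)
            frac = pos - lo
            cells[r // params.cell, c // params.cell, lo % params.bins] += mag * (1 - frac)
            cells[r // params.cell, c // params.cell, (lo + 1) % params.bins] += mag * frac
    out = []
    b = params.block
    for by in range(ncy - b + 1):
        for bx in range(ncx - b + 1):
            v = cells[by:by + b, bx:bx + b].ravel()
            v = v / math.sqrt((v ** 2).sum() + 1e-12)
            v = np.minimum(v, params.clip)
            n2 = math.sqrt((v ** 2).sum())
            if n2 > 1e-12:
                v = v / n2
            out.append(v)
    return np.concatenate(out)


def lbp_reference(patch, params: LbpParams):
    """Pixel-by-pixel LBP histogram for a single-cell grid."""
    img = np.asarray(patch, float)
    h, w = img.shape
    lut = _uniform_lookup(params.neighbors)
    hist = np.zeros(params.n_codes)
    r = int(np.ceil(params.radius))
    for row in range(r, h - r):
        for col in range(r, w - r):
            code = 0
            for k in range(params.neighbors):
                ang = 2 * math.pi * k / params.neighbors
                dx = params.radius * math.cos(ang)
                dy = -params.radius * math.sin(ang)
                if abs(dx - round(dx)) < 1e-9:
                    dx = round(dx)
                if abs(dy - round(dy)) < 1e-9:
                    dy = round(dy)
                yy, xx = row + dy, col + dx
                y0, x0 = int(math.floor(yy)), int(math.floor(xx))
                fy, fx = yy - y0, xx - x0
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                val = (img[y0, x0] * (1 - fy) * (1 - fx)
                       + img[y0, x1] * (1 - fy) * fx
                       + img[y1, x0] * fy * (1 - fx)
                       + img[y1, x1] * fy * fx)
                if val - img[row, col] >= -1e-9 * (1.0 + abs(img[row, col])):
                    code |= 1 << k
            hist[lut[code]] += 1
    return hist / hist.sum()


class TestHog:
    def test_constant_patch_all_zero(self):
        d = hog_descriptor(np.full((32, 32), 57.0))
        assert np.all(d == 0.0)

    def test_descriptor_length_64x32(self):
        d = hog_descriptor(np.random.default_rng(0).normal(size=(32, 64)))
        assert d.shape == (756,)
        assert hog_length((32, 64), HogParams()) == 756

    def test_vertical_step_edge_mass_in_horizontal_gradient_bin(self):
        patch = np.zeros((32, 32))
        patch[:, 16:] = 100.0
        d = hog_descriptor(patch)
        per_bin = d.reshape(-1, 9).sum(axis=0)
        # gradient points along +x -> orientation 0 deg, shared between the
        # two bins adjacent to 0 (circular soft binning)
        wrap = per_bin[[0, -1]].sum()
        assert wrap == pytest.approx(per_bin.sum(), rel=1e-9)
        assert per_bin[0] == pytest.approx(per_bin[-1], rel=1e-9)

    def test_nonnegative_and_blocks_normalized(self):
        rng = np.random.default_rng(3)
        d = hog_descriptor(rng.uniform(0, 255, (32, 64)))
        assert np.all(d >= 0)
        blocks = d.reshape(-1, 4 * 9)
        norms = np.linalg.norm(blocks, axis=1)
        assert np.all(norms <= 1.0 + 1e-9)

    def test_invariant_to_additive_intensity_shift(self):
        rng = np.random.default_rng(4)
        patch = rng.uniform(0, 200, (24, 24))
        a = hog_descriptor(patch)
        b = hog_descriptor(patch + 55.0)
        assert np.allclose(a, b, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hog_descriptor(np.zeros((30, 31)))

    def test_matches_bruteforce_reference(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            patch = rng.uniform(0, 255, (16, 24))
            got = hog_descriptor(patch)
            want = hog_reference(patch, HogParams())
            assert np.allclose(got, want, atol=1e-10)


class TestLbp:
    def test_flat_patch_single_uniform_code(self):
        params = LbpParams(cell_grid=(1, 1))
        d = lbp_descriptor(np.full((9, 9), 42.0), params)
        lut = _uniform_lookup(8)
        assert d[lut[255]] == pytest.approx(1.0)
        assert d.sum() == pytest.approx(1.0)

    def test_cell_histograms_sum_to_one(self):
        rng = np.random.default_rng(2)
        params = LbpParams(cell_grid=(2, 3))
        d = lbp_descriptor(rng.uniform(0, 255, (20, 30)), params)
        sums = d.reshape(6, -1).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_code_count_is_59_for_p8(self):
        assert LbpParams().n_codes == 59
        lut = _uniform_lookup(8)
        assert lut.max() == 58

    def test_bright_center_5x5_matches_hand_reference(self):
        patch = np.zeros((5, 5))
        patch[2, 2] = 100.0
        params = LbpParams(cell_grid=(1, 1))
        assert np.allclose(lbp_descriptor(patch, params),
                           lbp_reference(patch, params), atol=1e-12)

    def test_random_patches_match_reference(self):
        rng = np.random.default_rng(21)
        params = LbpParams(cell_grid=(1, 1))
        for _ in range(5):
            patch = rng.integers(0, 255, (7, 9)).astype(float)
            assert np.allclose(lbp_descriptor(patch, params),
                               lbp_reference(patch, params), atol=1e-12)

    def test_invariant_to_positive_affine_intensity_transform(self):
        """Bilinear neighbor sampling commutes with affine intensity maps,
        so LBP codes are exactly invariant to gain/offset changes (nonlinear
        monotone maps are only approximately invariant, since interpolation
        does not commute with them)."""
        rng = np.random.default_rng(9)
        patch = rng.uniform(1, 250, (12, 12))
        a = lbp_codes(patch)
        b = lbp_codes(patch * 3.7 + 12.0)
        assert np.array_equal(a, b)
        # nonlinear monotone map: near-exact agreement
        c = lbp_codes(np.sqrt(patch) * 10 + 3)
        assert np.mean(a == c) > 0.9

    def test_patch_too_small_rejected(self):
        with pytest.raises(ValueError):
            lbp_codes(np.zeros((2, 2)))


class TestExtractRoi:
    def test_target_size_exact(self, default_params):
        face = normalized_face(default_params)
        patch = extract_roi(face, MOUTH_ROI)
        assert patch.shape == (32, 64)  # (rows, cols) = reversed target

    def test_eye_roi_contains_both_eye_centers(self, default_params):
        face = normalized_face(default_params)
        pts = face.landmarks.points[list(EYES_ROI.landmark_indices)]
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        for c in (face.landmarks.right_eye_center(),
                  face.landmarks.left_eye_center()):
            assert x0 <= c[0] <= x1 and y0 - 3 <= c[1] <= y1 + 3

    def test_deterministic(self, default_params):
        face = normalized_face(default_params)
        assert np.array_equal(extract_roi(face, EYES_ROI),
                              extract_roi(face, EYES_ROI))

    def test_degenerate_box_rejected(self, default_params):
        face = normalized_face(default_params)
        spec = RoiSpec("point", (30, 30), 0.1, (8, 8))
        with pytest.raises(DegenerateGeometryError):
            extract_roi(face, spec)


class TestTextureFeatureVector:
    def test_layout_lengths_sum_to_total(self, default_params):
        tf = texture_feature_vector(normalized_face(default_params))
        total = sum(sl.stop - sl.start for sl in tf.layout.values())
        assert total == len(tf.vector)
        assert len(tf.vector) == (2 * hog_length((32, 64), HogParams())
                                  - hog_length((32, 64), HogParams())
                                  + hog_length((32, 128), HogParams())
                                  + lbp_length(MOUTH_LBP) + lbp_length(EYES_LBP))

    def test_deterministic_across_identical_renders(self, default_params):
        a = texture_feature_vector(normalized_face(default_params, seed=5))
        b = texture_feature_vector(normalized_face(default_params, seed=5))
        assert np.array_equal(a.vector, b.vector)

    def test_region_subsets_partition_vector(self, default_params):
        tf = texture_feature_vector(normalized_face(default_params))
        assert len(tf.subset("mouth")) + len(tf.subset("eyes")) == len(tf.vector)

    def test_reduced_texture_raises_flat_code_mass_in_eye_roi(self):
        """Patients with effect_texture=0.6 show weaker fine detail around
        the eyes, so the flat (all-ones) LBP code carries more mass."""
        cfg = CohortConfig(n_patient=25, n_control=25, effect_angle=0,
                           effect_asym=0, effect_texture=0.6, n_frames=3,
                           rng_seed=3)
        cohort = generate_cohort(cfg)
        lut = _uniform_lookup(8)
        flat_bin = lut[255]

        def flat_mass(subject):
            lm = subject.landmark_sequence[-1]
            face = normalize(subject.frame(len(subject.landmark_sequence) - 1), lm)
            tf = texture_feature_vector(face)
            eye = tf.vector[tf.layout["lbp_eyes"]]
            return eye.reshape(-1, 59)[:, flat_bin].mean()

        pat = np.mean([flat_mass(s) for s in cohort.patients()])
        con = np.mean([flat_mass(s) for s in cohort.controls()])
        assert pat > con
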