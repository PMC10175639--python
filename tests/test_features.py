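import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sonolbp import (
    assemble_subject_vector,
    extract_roi_features,
    fos_features,
    galloway_features,
    glcm,
    glrlm,
    haralick_features,
    lbp_features,
    mfaf,
    quantize,
    thickness_feature,
)
from sonolbp.cohort import AcquisitionRecord, ROISample
from sonolbp.features import _OFFSETS, GLRLM, burg_coefficients, lbp_codes
from sonolbp.protocol import PROTOCOL_KEYS, DIRECTIONS, ProtocolError

DIRS = list(_OFFSETS)


# ---------------------------------------------------------------------------
# Independent oracles

def fos_oracle(pixels):
    """First-order statistics recomputed from the raw pixel list."""
    x = [float(v) for v in np.ravel(pixels)]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = var**0.5
    skew = sum((v - mean) ** 3 for v in x) / n / std**3 if std > 0 else 0.0
    kurt = sum((v - mean) ** 4 for v in x) / n / std**4 if std > 0 else 0.0
    counts = [0] * 256
    for v in np.ravel(pixels):
        counts[int(v)] += 1
    energy = sum((c / n) ** 2 for c in counts)
    return {"IOD": sum(x), "Mean": mean, "Std": std, "Variance": var,
            "Skewness": skew, "Kurtosis": kurt, "Energy": energy}


def glcm_oracle(img, direction, levels):
    """Pair enumeration by explicit double loop."""
    dr, dc = _OFFSETS[direction]
    h, w = img.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
    return counts / counts.sum()


def haralick_oracle(p):
    q = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(q) for j in range(q))
    mu_j = sum(j * p[i, j] for i in range(q) for j in range(q))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(q) for j in range(q))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(q) for j in range(q))
    out = {
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(q) for j in range(q)),
        "Energy": sum(p[i, j] ** 2 for i in range(q) for j in range(q)),
        "Entropy": -sum(p[i, j] * np.log(p[i, j]) for i in range(q) for j in range(q) if p[i, j] > 0),
        "Homogeneity": sum(p[i, j] / (1 + abs(i - j)) for i in range(q) for j in range(q)),
        "Symmetry": 1 - 0.5 * sum(abs(p[i, j] - p[j, i]) for i in range(q) for j in range(q)),
    }
    if var_i > 0 and var_j > 0:
        out["Correlation"] = sum((i - mu_i) * (j - mu_j) * p[i, j]
                                 for i in range(q) for j in range(q)) / (var_i * var_j) ** 0.5
    else:
        out["Correlation"] = 0.0
    return out


def runs_oracle(img, direction):
    """Maximal constant-gray runs enumerated line by line."""
    h, w = img.shape
    if direction == "0°":
        lines = [list(img[r]) for r in range(h)]
    elif direction == "90°":
        lines = [list(img[:, c]) for c in range(w)]
    elif direction == "45°":
        lines = [[img[r, c] for r in range(h) for c in range(w) if r + c == s]
                 for s in range(h + w - 1)]
    else:
        lines = [[img[r, c] for r in range(h) for c in range(w) if r - c == d]
                 for d in range(-(w - 1), h)]
    runs = []
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs.append((int(line[i]), j - i))
            i = j
    return runs


def galloway_oracle(runs, n_pixels):
    nr = len(runs)
    return {
        "SRE": sum(1 / l**2 for _, l in runs) / nr,
        "LRE": sum(l**2 for _, l in runs) / nr,
        "GLNU": sum(c**2 for c in
                    [sum(1 for g2, _ in runs if g2 == g) for g in {g for g, _ in runs}]) / nr,
        "RLNU": sum(c**2 for c in
                    [sum(1 for _, l2 in runs if l2 == l) for l in {l for _, l in runs}]) / nr,
        "RP": nr / n_pixels,
    }


def all_binary_3x3():
    for bits in itertools.product((0, 1), repeat=9):
        yield np.array(bits, dtype=np.int64).reshape(3, 3)


# ---------------------------------------------------------------------------

class TestQuantize:
    @pytest.mark.parametrize("values,levels,expected", [
        ([0, 255], 2, [0, 1]),
        ([0, 100, 200, 255], 4, [0, 1, 3, 3]),
        ([7, 7, 7], 16, [0, 0, 0]),
    ])
    def test_uniform_binning(self, values, levels, expected):
        assert quantize(np.array(values, dtype=np.uint8), levels).tolist() == expected

    def test_constant_image_stays_constant(self):
        out = quantize(np.full((5, 5), 130, np.uint8), 32)
        assert np.unique(out).size == 1

    def test_levels_below_two_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2), np.uint8), 1)


class TestFOS:
    def test_degenerate_constant_image(self):
        out = fos_features(np.full((2, 2), 7, np.uint8))
        assert out == {"IOD": 28.0, "Mean": 7.0, "Std": 0.0, "Variance": 0.0,
                       "Skewness": 0.0, "Kurtosis": 0.0, "Energy": 1.0}

    def test_two_value_image_by_hand(self):
        out = fos_features(np.array([0, 0, 255, 255], dtype=np.uint8))
        assert out["Mean"] == pytest.approx(127.5)
        assert out["Variance"] == pytest.approx(16256.25)
        assert out["Energy"] == pytest.approx(0.5)
        assert out["Skewness"] == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, st.tuples(st.integers(1, 8), st.integers(1, 8))))
    def test_matches_brute_force_oracle(self, img):
        out = fos_features(img)
        ref = fos_oracle(img)
        for k in ref:
            assert out[k] == pytest.approx(ref[k], abs=1e-9)


class TestGLCM:
    def test_two_horizontal_pairs(self):
        g = glcm(np.array([[0, 0], [1, 1]]), "0°", 2)
        assert np.allclose(g.matrix, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_cell(self):
        for d in DIRS:
            g = glcm(np.zeros((4, 4), dtype=int), d, 4)
            assert g.matrix[0, 0] == 1.0 and g.matrix.sum() == pytest.approx(1.0)

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.array([[0, 1]]), "90°", 2)

    def test_exhaustive_binary_3x3_matches_enumeration(self):
        for img in all_binary_3x3():
            for d in DIRS:
                assert np.array_equal(glcm(img, d, 2).matrix, glcm_oracle(img, d, 2))

    def test_matches_skimage_horizontal(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(0)
        img = rng.integers(0, 8, size=(16, 16))
        ours = glcm(img, "0°", 8).matrix
        ref = graycomatrix(img.astype(np.uint8), [1], [0], levels=8, normed=True)[:, :, 0, 0]
        assert np.allclose(ours, ref)


class TestHaralick:
    def test_diagonal_glcm_by_hand(self):
        g = glcm(np.array([[0, 0], [1, 1]]), "0°", 2)
        out = haralick_features(g)
        assert out["Contrast"] == pytest.approx(0.0)
        assert out["Energy"] == pytest.approx(0.5)
        assert out["Entropy"] == pytest.approx(np.log(2))
        assert out["Homogeneity"] == pytest.approx(1.0)
        assert out["Symmetry"] == pytest.approx(1.0)
        assert out["Correlation"] == pytest.approx(1.0)

    def test_uniform_matrix_energy_and_symmetry(self):
        from sonolbp.features import GLCM

        q = 4
        g = GLCM(levels=q, matrix=np.full((q, q), 1 / q**2), direction="0°")
        out = haralick_features(g)
        assert out["Symmetry"] == pytest.approx(1.0)
        assert out["Energy"] == pytest.approx(1 / q**2)

    def test_constant_image_correlation_convention(self):
        out = haralick_features(glcm(np.zeros((4, 4), dtype=int), "0°", 4))
        assert out["Correlation"] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            img = rng.integers(0, 6, size=(10, 12))
            for d in DIRS:
                g = glcm(img, d, 6)
                ref = haralick_oracle(g.matrix)
                out = haralick_features(g)
                for k in ref:
                    assert out[k] == pytest.approx(ref[k], abs=1e-9)


class TestGLRLM:
    def test_single_row_runs(self):
        r = glrlm(np.array([[0, 0, 1]]), "0°", 2)
        assert r.n_runs == 2 and r.n_pixels == 3
        assert r.matrix[0, 1] == 1 and r.matrix[1, 0] == 1

    def test_constant_row_single_run(self):
        r = glrlm(np.zeros((1, 7), dtype=int), "0°", 2)
        assert r.n_runs == 1 and r.matrix[0, 6] == 1

    @pytest.mark.parametrize("direction", DIRS)
    def test_run_length_conservation(self, direction):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 4, size=(9, 13))
        r = glrlm(img, direction, 4)
        lengths = np.arange(1, r.max_run + 1)
        assert (r.matrix * lengths[None, :]).sum() == img.size
        assert r.matrix.sum() == r.n_runs

    def test_exhaustive_binary_3x3_matches_enumeration(self):
        for img in all_binary_3x3():
            for d in DIRS:
                r = glrlm(img, d, 2)
                ref = runs_oracle(img, d)
                got = np.zeros_like(r.matrix)
                for g, l in ref:
                    got[g, l - 1] += 1
                assert np.array_equal(r.matrix, got)
                assert r.n_runs == len(ref)


class TestGalloway:
    def test_printed_toy_run_set(self):
        m = np.zeros((2, 2))
        m[0, 1] = 1  # gray 0, length 2
        m[1, 0] = 1  # gray 1, length 1
        out = galloway_features(GLRLM(levels=2, max_run=2, matrix=m, n_runs=2, n_pixels=3))
        assert out["SRE"] == pytest.approx(0.625)
        assert out["LRE"] == pytest.approx(2.5)
        assert out["GLNU"] == pytest.approx(1.0)
        assert out["RLNU"] == pytest.approx(1.0)
        assert out["RP"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("length", [1, 4, 9])
    def test_single_run_closed_form(self, length):
        out = galloway_features(glrlm(np.zeros((1, length), dtype=int), "0°", 2))
        assert out["SRE"] == pytest.approx(1 / length**2)
        assert out["LRE"] == pytest.approx(length**2)
        assert out["RP"] == pytest.approx(1 / length)

    def test_matches_run_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = rng.integers(0, 3, size=(7, 8))
            for d in DIRS:
                out = galloway_features(glrlm(img, d, 3))
                ref = galloway_oracle(runs_oracle(img, d), img.size)
                for k in ref:
                    assert out[k] == pytest.approx(ref[k], abs=1e-9)


class TestLBP:
    def test_constant_image_all_codes_255(self):
        codes = lbp_codes(np.full((5, 5), 9, np.uint8))
        assert (codes == 255).all()
        out = lbp_features(np.full((5, 5), 9, np.uint8))
        assert out["Energy"] == 1.0 and out["Entropy"] == 0.0

    def test_ramp_codes_by_hand(self):
        # Row-major ramp: for every interior pixel the E, SW, S, SE neighbors
        # (bits 0, 5, 6, 7) are >= center -> code 1+32+64+128 = 225.
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert (lbp_codes(img) == 225).all()

    def test_energy_entropy_bounds(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        out = lbp_features(img)
        assert 0 < out["Energy"] <= 1
        assert 0 <= out["Entropy"] <= np.log(256)

    def test_image_below_3x3_rejected(self):
        with pytest.raises(ValueError):
            lbp_features(np.zeros((2, 5), np.uint8))


class TestMFAF:
    def test_pure_tone_recovered_by_both_methods(self):
        img = (127.5 + 100 * np.cos(2 * np.pi * 0.25 * np.arange(64))[:, None]
               * np.ones((1, 64))).round().astype(np.uint8)
        assert mfaf(img, "maxent") == pytest.approx(0.25, abs=0.02)
        assert mfaf(img, "multiwindow") == pytest.approx(0.25, abs=0.02)

    def test_white_noise_multiwindow_near_flat_spectrum_mean(self):
        rng = np.random.default_rng(5)
        values = [mfaf(rng.integers(0, 256, size=(64, 64)).astype(np.uint8), "multiwindow")
                  for _ in range(50)]
        assert np.mean(values) == pytest.approx(0.25, abs=0.02)

    def test_smoothing_decreases_multiwindow_mfaf(self):
        from scipy import ndimage

        rng = np.random.default_rng(6)
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        smoothed = ndimage.gaussian_filter(img.astype(float), 2.0).astype(np.uint8)
        assert mfaf(smoothed, "multiwindow") < mfaf(img, "multiwindow")

    def test_constant_image_flat_spectrum_convention(self):
        img = np.full((32, 32), 100, np.uint8)
        assert mfaf(img, "maxent") == pytest.approx(0.25, abs=1e-6)
        assert mfaf(img, "multiwindow") == pytest.approx(0.25, abs=1e-12)

    def test_burg_matches_statsmodels(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(7)
        x = np.convolve(rng.normal(size=200), np.ones(3) / 3, mode="same")
        x -= x.mean()
        rho, _ = sm_burg(x, order=8)
        a = burg_coefficients(x[None, :], 8)[0]
        assert np.allclose(a, -rho, atol=1e-10)

    def test_too_short_image_rejected(self):
        with pytest.raises(ValueError):
            mfaf(np.zeros((8, 32), np.uint8), "maxent")


class TestThickness:
    def test_mean_of_sides(self):
        assert thickness_feature(4.0, 6.0) == 5.0
        assert thickness_feature(3.3, 3.3) == 3.3
        assert thickness_feature(2.0, 5.0) == thickness_feature(5.0, 2.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            thickness_feature(0.0, 4.0)


class TestAssembly:
    def test_roi_yields_57_features_with_family_counts(self, default_record):
        roi = default_record.rois[PROTOCOL_KEYS[0]]
        feats = extract_roi_features(roi)
        assert len(feats) == 57
        fams = {}
        for name in feats:
            fams[name.family] = fams.get(name.family, 0) + 1
        assert fams["haralick"] == 24 and fams["galloway"] == 20
        assert fams["mfaf"] == 2 and fams["fos"] == 7 and fams["lbp"] == 2 and fams["swe"] == 2

    def test_swe_values_passed_through(self, default_record):
        roi = default_record.rois[PROTOCOL_KEYS[0]]
        feats = {n.serialize(): v for n, v in extract_roi_features(roi).items()}
        key = PROTOCOL_KEYS[0]
        base = f"{key.level}_{key.side}_{key.muscle}_SWE"
        assert feats[f"{base}.Mean ({key.position} position)"] == roi.swe_mean_kpa
        assert feats[f"{base}.Std ({key.position} position)"] == roi.swe_std_kpa

    def test_subject_vector_has_800_canonical_features(self, default_record):
        vec = assemble_subject_vector(default_record)
        assert len(vec) == 800
        assert all(np.isfinite(v) for v in vec.values())

    def test_missing_roi_names_absent_key(self, default_record):
        rois = dict(default_record.rois)
        missing = PROTOCOL_KEYS[3]
        del rois[missing]
        with pytest.raises(ProtocolError, match=missing.site_label()):
            AcquisitionRecord(meta=default_record.meta, rois=rois,
                              tlf_thickness_mm=1.0, tra_thickness_mm=1.0)

    def test_rotation_permutes_direction_qualified_features(self, default_record):
        """Rotating a square ROI by 90 degrees swaps the 0/90 and 45/135
        direction qualifiers of Haralick and Galloway features."""
        roi = default_record.rois[PROTOCOL_KEYS[0]]
        rotated = ROISample(key=roi.key, image=np.ascontiguousarray(np.rot90(roi.image)),
                            swe_mean_kpa=roi.swe_mean_kpa, swe_std_kpa=roi.swe_std_kpa)
        orig = extract_roi_features(roi)
        rot = extract_roi_features(rotated)
        perm = {"0°": "90°", "90°": "0°", "45°": "135°", "135°": "45°"}
        for name, value in orig.items():
            if name.family in ("haralick", "galloway"):
                partner = next(n for n in rot
                               if n.family == name.family and n.statistic == name.statistic
                               and n.qualifier == perm[name.qualifier])
                assert rot[partner] == pytest.approx(value, abs=1e-9)

    def test_degenerate_constant_rois_stay_finite(self):
        rec_src = None
        from sonolbp import CohortConfig, generate_subject

        rec_src = generate_subject("mild", CohortConfig(roi_size=(32, 32)),
                                   np.random.default_rng(8))
        rois = {
            k: ROISample(key=k, image=np.full((32, 32), 42, np.uint8),
                         swe_mean_kpa=r.swe_mean_kpa, swe_std_kpa=r.swe_std_kpa)
            for k, r in rec_src.rois.items()
        }
        rec = AcquisitionRecord(meta=rec_src.meta, rois=rois,
                                tlf_thickness_mm=1.0, tra_thickness_mm=2.0)
        vec = assemble_subject_vector(rec)
        assert all(np.isfinite(v) for v in vec.values())
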