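"""Radiomics feature engine: catalog structure, quantization, first-order,
GLCM, GLRLM and full-volume extraction, each validated against independent
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from r2sn import (DIRECTIONS_13, ExtractionParams, LabeledVolume,
                  extract_region_features, first_order_features, full_catalog,
                  quantize_region, reserved25_catalog)
from r2sn.features import (FIRST_ORDER_FEATURES, GLCM_FEATURES, GLRLM_FEATURES,
                           GLCMatrix, GLRLMatrix, compute_glcm, compute_glrlm,
                           glcm_features, glrlm_features)

from oracles import (first_order_oracle, glcm_counts_oracle,
                     glcm_features_oracle, glrlm_counts_oracle,
                     glrlm_features_oracle, quantize_oracle)


class TestCatalog:
    def test_family_sizes(self):
        cat = full_catalog()
        assert len(cat) == 47
        counts = cat.counts_by_family()
        assert counts == {"intensity": 14, "glcm": 22, "glrlm": 11}

    def test_reserved_subset(self):
        cat = reserved25_catalog()
        assert len(cat) == 25
        counts = cat.counts_by_family()
        assert counts["intensity"] == 7
        assert counts["glcm"] + counts["glrlm"] == 18
        assert set(cat.feature_ids) <= set(full_catalog().feature_ids)

    def test_ids_unique(self):
        cat = full_catalog()
        assert len(set(cat.feature_ids)) == 47


class TestQuantize:
    @pytest.mark.parametrize("values,n,expected", [
        ([0.0, 0.5, 1.0], 2, [1, 2, 2]),
        ([7.0, 7.0, 7.0], 4, [1, 1, 1]),
        ([7.0, 7.0, 7.0], 32, [1, 1, 1]),
    ])
    def test_stated_cases(self, values, n, expected):
        assert quantize_region(np.array(values), n).tolist() == expected

    def test_matches_exhaustive_binning(self, rng):
        values = rng.uniform(size=100)
        got = quantize_region(values, 32)
        assert got.tolist() == quantize_oracle(values.tolist(), 32)
        assert got.min() >= 1 and got.max() == 32

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty region"):
            quantize_region(np.array([]), 8)


class TestFirstOrder:
    def test_forced_arithmetic(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0]))
        assert f["firstorder_energy"] == 14
        assert f["firstorder_mean"] == 2
        assert f["firstorder_mad"] == pytest.approx(2 / 3)
        assert f["firstorder_range"] == 2
        assert f["firstorder_median"] == 2

    def test_constant_region(self):
        f = first_order_features(np.array([5.0] * 4))
        assert f["firstorder_entropy"] == 0
        assert f["firstorder_uniformity"] == 1
        assert f["firstorder_variance"] == 0
        assert f["firstorder_skewness"] == 0
        assert f["firstorder_kurtosis"] == 0

    def test_matches_formula_oracle(self, rng):
        x = rng.normal(10, 3, size=500)
        got = first_order_features(x, n_bins=32)
        want = first_order_oracle(x.tolist(), n_bins=32)
        for k in FIRST_ORDER_FEATURES:
            assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k

    def test_permutation_invariant(self, rng):
        x = rng.normal(size=200)
        a = first_order_features(x)
        b = first_order_features(rng.permutation(x))
        for k in FIRST_ORDER_FEATURES:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_affine_scaling_behavior(self, rng):
        x = rng.uniform(1, 5, size=100)
        base = first_order_features(x)
        scaled = first_order_features(3.0 * x)
        assert scaled["firstorder_energy"] == pytest.approx(9 * base["firstorder_energy"])
        assert scaled["firstorder_maximum"] == pytest.approx(3 * base["firstorder_maximum"])
        assert scaled["firstorder_minimum"] == pytest.approx(3 * base["firstorder_minimum"])
        assert scaled["firstorder_range"] == pytest.approx(3 * base["firstorder_range"])
        shifted = first_order_features(x + 7.0)
        assert shifted["firstorder_range"] == pytest.approx(base["firstorder_range"])
        assert shifted["firstorder_maximum"] == pytest.approx(base["firstorder_maximum"] + 7)


class TestGLCM:
    def test_constant_region_single_cell(self):
        lev = np.ones((3, 3, 3), dtype=int)
        mask = np.ones((3, 3, 3), bool)
        g = compute_glcm(lev, mask, np.array([0, 0, 1]), n_levels=1)
        assert g.probabilities[0, 0] == 1.0

    def test_counts_match_pair_enumeration(self, rng):
        lev3 = rng.integers(1, 5, size=(4, 4, 1))
        mask = np.ones_like(lev3, bool)
        g = compute_glcm(lev3, mask, np.array([0, 1, 0]), n_levels=4)
        want = glcm_counts_oracle(lev3, mask, (0, 1, 0), 4)
        np.testing.assert_allclose(g.probabilities * want.sum(), want)

    def test_counts_match_on_irregular_mask(self, rng):
        lev = rng.integers(1, 7, size=(5, 6, 4))
        mask = rng.uniform(size=lev.shape) < 0.6
        mask[0, 0, 0] = True
        for direction in DIRECTIONS_13[::4]:
            g = compute_glcm(lev, mask, direction, n_levels=6)
            want = glcm_counts_oracle(lev, mask, tuple(direction), 6)
            if want.sum() == 0:
                assert not g.valid
            else:
                np.testing.assert_allclose(g.probabilities, want / want.sum())

    def test_single_voxel_has_no_pairs(self):
        lev = np.ones((1, 1, 1), dtype=int)
        mask = np.ones((1, 1, 1), bool)
        for direction in DIRECTIONS_13:
            g = compute_glcm(lev, mask, direction, n_levels=1)
            assert not g.valid

    def test_probabilities_sum_to_one(self, rng):
        lev = rng.integers(1, 9, size=(6, 6, 6))
        mask = rng.uniform(size=lev.shape) < 0.7
        mask[2, 2, 2] = True
        for direction in DIRECTIONS_13:
            g = compute_glcm(lev, mask, direction, n_levels=8)
            if g.valid:
                assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(g.probabilities, g.probabilities.T)


class TestGLCMFeatures:
    def test_degenerate_single_cell(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = glcm_features(GLCMatrix(p, 4))
        assert f["glcm_contrast"] == 0
        assert f["glcm_energy"] == 1
        assert f["glcm_maximum_probability"] == 1
        assert f["glcm_entropy"] == 0
        assert f["glcm_correlation"] == 0  # 0/0 convention
        assert f["glcm_imc1"] == 0

    def test_uniform_2x2(self):
        f = glcm_features(GLCMatrix(np.full((2, 2), 0.25), 2))
        assert f["glcm_contrast"] == pytest.approx(0.5)
        assert f["glcm_maximum_probability"] == 0.25

    def test_matches_double_loop_oracle(self, rng):
        raw = rng.uniform(size=(8, 8))
        p = raw + raw.T
        p /= p.sum()
        got = glcm_features(GLCMatrix(p, 8))
        want = glcm_features_oracle(p)
        for k in GLCM_FEATURES:
            assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k


class TestGLRLM:
    def test_single_long_run(self):
        lev = np.full((5, 1, 1), 3)
        mask = np.ones_like(lev, bool)
        r = compute_glrlm(lev, mask, np.array([1, 0, 0]))
        assert r.counts[2, 4] == 1
        assert r.counts.sum() == 1

    def test_maximal_run_definition(self):
        lev = np.array([1, 1, 2, 1]).reshape(4, 1, 1)
        mask = np.ones_like(lev, bool)
        r = compute_glrlm(lev, mask, np.array([1, 0, 0]))
        assert r.counts[0, 1] == 1  # (level 1, length 2)
        assert r.counts[1, 0] == 1  # (level 2, length 1)
        assert r.counts[0, 0] == 1  # (level 1, length 1)

    @pytest.mark.parametrize("didx", range(13))
    def test_matches_run_scanning_oracle(self, didx, rng):
        lev = rng.integers(1, 4, size=(5, 4, 6))
        mask = rng.uniform(size=lev.shape) < 0.7
        mask[0, 0, 0] = True
        direction = DIRECTIONS_13[didx]
        r = compute_glrlm(lev, mask, direction, n_levels=3)
        want = glrlm_counts_oracle(lev, mask, direction)
        got = {(g + 1, l + 1): int(r.counts[g, l])
               for g in range(r.counts.shape[0])
               for l in range(r.counts.shape[1])
               if r.counts[g, l] > 0}
        assert got == want

    def test_voxel_conservation(self, rng):
        """Every in-region voxel belongs to exactly one run per direction."""
        lev = rng.integers(1, 5, size=(6, 5, 4))
        mask = rng.uniform(size=lev.shape) < 0.8
        mask[1, 1, 1] = True
        n_vox = int(mask.sum())
        for direction in DIRECTIONS_13:
            r = compute_glrlm(lev, mask, direction)
            lengths = np.arange(1, r.counts.shape[1] + 1)
            assert int((r.counts * lengths).sum()) == n_vox


class TestGLRLMFeatures:
    def test_single_run_algebra(self):
        counts = np.zeros((4, 7))
        counts[2, 6] = 1  # one run of length 7 at level 3
        f = glrlm_features(GLRLMatrix(counts, np.array([1, 0, 0]), 4), n_voxels=7)
        assert f["glrlm_sre"] == pytest.approx(1 / 49)
        assert f["glrlm_lre"] == pytest.approx(49)
        assert f["glrlm_rp"] == pytest.approx(1 / 7)

    def test_all_runs_length_one(self):
        counts = np.zeros((3, 1))
        counts[:, 0] = [4, 5, 6]
        f = glrlm_features(GLRLMatrix(counts, np.array([1, 0, 0]), 3), n_voxels=15)
        assert f["glrlm_sre"] == 1
        assert f["glrlm_lre"] == 1

    def test_matches_direct_summation(self, rng):
        counts = rng.integers(0, 5, size=(6, 8)).astype(float)
        counts[0, 0] += 1
        n_vox = int((counts * np.arange(1, 9)).sum())
        got = glrlm_features(GLRLMatrix(counts, np.array([0, 1, 0]), 6), n_vox)
        want = glrlm_features_oracle(counts, n_vox)
        for k in GLRLM_FEATURES:
            assert got[k] == pytest.approx(want[k], rel=1e-10), k

    def test_zero_runs_error(self):
        with pytest.raises(ValueError, match="zero runs"):
            glrlm_features(GLRLMatrix(np.zeros((2, 2)), np.array([1, 0, 0]), 2), 4)


class TestExtraction:
    def test_identical_regions_identical_rows(self):
        intens = np.zeros((8, 4, 4))
        pattern = np.arange(64, dtype=float).reshape(4, 4, 4) % 7
        intens[:4] = pattern
        intens[4:] = pattern
        labels = np.zeros((8, 4, 4), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        vol = LabeledVolume(intens, labels)
        table = extract_region_features(vol, full_catalog())
        np.testing.assert_allclose(table.matrix[0], table.matrix[1])

    def test_full_atlas_shape(self, rng):
        from r2sn import PhantomSpec, make_phantom
        vol, _ = make_phantom(PhantomSpec(seed=2))
        table = extract_region_features(vol, full_catalog())
        assert table.matrix.shape == (90, 47)

    def test_composes_per_feature_oracles(self, rng):
        """Full extraction on a 2-region phantom equals recomputation from
        the individual per-feature oracles."""
        intens = rng.normal(100, 10, size=(8, 5, 5))
        labels = np.zeros((8, 5, 5), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        vol = LabeledVolume(intens, labels)
        params = ExtractionParams(n_levels=8, n_bins=8, min_region_voxels=1)
        table = extract_region_features(vol, full_catalog(), params)
        for ridx, lab in enumerate((1, 2)):
            mask = labels == lab
            vals = intens[mask]
            want_fo = first_order_oracle(vals.tolist(), n_bins=8)
            lev = np.zeros_like(labels)
            lev[mask] = quantize_oracle(vals.tolist(), 8)
            glcm_acc = {k: [] for k in GLCM_FEATURES}
            glrlm_acc = {k: [] for k in GLRLM_FEATURES}
            for direction in DIRECTIONS_13:
                cnt = glcm_counts_oracle(lev, mask, tuple(direction), 8)
                if cnt.sum() > 0:
                    for k, v in glcm_features_oracle(cnt / cnt.sum()).items():
                        glcm_acc[k].append(v)
                runs = glrlm_counts_oracle(lev, mask, direction)
                rc = np.zeros((8, max(l for (_, l) in runs)))
                for (g, l), c in runs.items():
                    rc[g - 1, l - 1] = c
                for k, v in glrlm_features_oracle(rc, int(mask.sum())).items():
                    glrlm_acc[k].append(v)
            want = dict(want_fo)
            want.update({k: np.mean(v) for k, v in glcm_acc.items()})
            want.update({k: np.mean(v) for k, v in glrlm_acc.items()})
            for cidx, fid in enumerate(table.feature_ids):
                assert table.matrix[ridx, cidx] == pytest.approx(
                    want[fid], rel=1e-10, abs=1e-12), fid

    def test_texture_invariant_to_monotone_intensity_scaling(self, small_phantom):
        """Positive affine intensity transforms preserve the quantization and
        hence every texture feature."""
        vol, _ = small_phantom
        scaled = LabeledVolume(2.5 * vol.intensities + 40.0, vol.labels,
                               vol.affine)
        cat = full_catalog()
        a = extract_region_features(vol, cat)
        b = extract_region_features(scaled, cat)
        texture_cols = [k for k, f in enumerate(cat.feature_ids)
                        if not f.startswith("firstorder")]
        np.testing.assert_allclose(a.matrix[:, texture_cols],
                                   b.matrix[:, texture_cols], rtol=1e-9)

    def test_bit_reproducible(self):
        from r2sn import PhantomSpec, make_phantom
        spec = PhantomSpec(shape=(12, 12, 12), n_regions=8, seed=9)
        v1, _ = make_phantom(spec)
        v2, _ = make_phantom(spec)
        t1 = extract_region_features(v1, reserved25_catalog())
        t2 = extract_region_features(v2, reserved25_catalog())
        assert (t1.matrix == t2.matrix).all()

    def test_small_region_strict_mode(self):
        intens = np.random.default_rng(0).normal(size=(4, 4, 4))
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[:2] = 1
        labels[3, 3, 3] = 2
        vol = LabeledVolume(intens, labels)
        with pytest.raises(ValueError, match="region 2"):
            extract_region_features(vol, full_catalog(),
                                    ExtractionParams(strict=True))
        with pytest.warns(UserWarning):
            table = extract_region_features(vol, full_catalog(),
                                            ExtractionParams(strict=False))
        assert 2 in table.flags


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3,
                          allow_nan=False), min_size=2, max_size=50),
       st.integers(min_value=2, max_value=16))
def test_quantize_property(values, n_levels):
    """Levels stay within [1, n_levels], respect ordering, and the maximum
    lands in the top bin for non-constant input."""
    got = quantize_region(np.array(values), n_levels)
    assert got.min() >= 1 and got.max() <= n_levels
    order = np.argsort(values)
    assert (np.diff(got[order]) >= 0).all()
    if max(values) > min(values):
        assert got[int(np.argmax(values))] == n_levels
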