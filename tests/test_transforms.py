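import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nganet import transforms as T


def brute_force_cooccurrence(vol, offset, levels, symmetric, normalize):
    """Independent oracle: explicit double loop over all voxel pairs."""
    mat = np.zeros((levels, levels))
    shape = vol.shape
    for p in itertools.product(*[range(s) for s in shape]):
        q = tuple(pi + oi for pi, oi in zip(p, offset))
        if all(0 <= qi < si for qi, si in zip(q, shape)):
            mat[vol[p], vol[q]] += 1
    if symmetric:
        mat = mat + mat.T
    if normalize:
        mat = mat / mat.sum()
    return mat


class TestDirections:
    def test_thirteen_unique(self):
        dirs = T.unique_directions_3d()
        assert len(dirs) == 13

    def test_antipodal_dedup(self):
        dirs = set(T.unique_directions_3d())
        for d in dirs:
            assert tuple(-c for c in d) not in dirs

    def test_union_with_negations_covers_neighbourhood(self):
        dirs = T.unique_directions_3d()
        full = set(dirs) | {tuple(-c for c in d) for d in dirs}
        assert len(full) == 26


class TestCooccurrence:
    def test_corner_voxel_example(self):
        vol = np.zeros((2, 2, 2), dtype=int)
        vol[1, 1, 1] = 1
        cfg = T.GLCMConfig(levels=2, symmetric=True, normalize=False)
        mat = T.cooccurrence_3d(vol, (1, 0, 0), cfg)
        np.testing.assert_array_equal(mat, [[6, 1], [1, 0]])

    def test_constant_volume_single_entry(self):
        vol = np.full((3, 3, 3), 4, dtype=int)
        cfg = T.GLCMConfig(levels=8, normalize=True)
        mat = T.cooccurrence_3d(vol, (0, 1, 0), cfg)
        assert mat[4, 4] == pytest.approx(1.0)
        assert mat.sum() == pytest.approx(1.0)

    def test_symmetric_output_is_symmetric(self, rng):
        vol = rng.integers(0, 4, size=(5, 5, 5))
        cfg = T.GLCMConfig(levels=4)
        mat = T.cooccurrence_3d(vol, (1, -1, 0), cfg)
        np.testing.assert_allclose(mat, mat.T)

    def test_offset_out_of_range(self):
        cfg = T.GLCMConfig(levels=2)
        with pytest.raises(ValueError):
            T.cooccurrence_3d(np.zeros((2, 2, 2), dtype=int), (3, 0, 0), cfg)

    @pytest.mark.parametrize("distance", [1, 2, 3])
    def test_matches_brute_force_all_directions(self, rng, distance):
        """Oracle equivalence on small volumes for the full default config."""
        vol = rng.integers(0, 4, size=(6, 5, 6))
        cfg = T.GLCMConfig(levels=4, symmetric=True, normalize=True)
        for d in T.unique_directions_3d():
            off = tuple(distance * c for c in d)
            got = T.cooccurrence_3d(vol, off, cfg)
            want = brute_force_cooccurrence(vol, off, 4, True, True)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestHaralick:
    def test_contrast_hand_value(self):
        mat = np.array([[0.75, 0.125], [0.125, 0.0]])
        feats = dict(zip(T.HARALICK_FEATURES, T.haralick(mat)))
        assert feats["contrast"] == pytest.approx(0.25)

    def test_diagonal_mass_zero_contrast(self):
        feats = dict(zip(T.HARALICK_FEATURES, T.haralick(np.diag([0.5, 0.3, 0.2]))))
        assert feats["contrast"] == pytest.approx(0.0)

    def test_uniform_asm(self):
        feats = dict(zip(T.HARALICK_FEATURES, T.haralick(np.full((2, 2), 0.25))))
        assert feats["angular_second_moment"] == pytest.approx(0.25)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            T.haralick(np.array([[2.0, 0.0], [0.0, 0.0]]))

    def test_permutation_invariant_descriptors(self, rng):
        """Contrast/entropy/ASM are invariant to simultaneous row+col permutation
        only when index distances are preserved; reversal is such a map."""
        p = rng.random((5, 5))
        p = (p + p.T) / 2
        p /= p.sum()
        rev = p[::-1, ::-1]
        a = dict(zip(T.HARALICK_FEATURES, T.haralick(p)))
        b = dict(zip(T.HARALICK_FEATURES, T.haralick(rev)))
        for name in ("contrast", "entropy", "angular_second_moment"):
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_against_scikit_image_2d(self, rng):
        """Independent oracle: skimage.graycoprops on an equivalent 2-D GLCM."""
        from skimage.feature import graycomatrix, graycoprops

        img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        sk = graycomatrix(img, distances=[1], angles=[0], levels=8,
                          symmetric=True, normed=True)[:, :, 0, 0]
        ours = T.cooccurrence_3d(img[..., None].astype(int), (0, 1, 0),
                                 T.GLCMConfig(levels=8))
        np.testing.assert_allclose(ours, sk, atol=1e-12)
        feats = dict(zip(T.HARALICK_FEATURES, T.haralick(ours)))
        assert feats["contrast"] == pytest.approx(
            graycoprops(sk[:, :, None, None], "contrast")[0, 0])
        assert feats["angular_second_moment"] == pytest.approx(
            graycoprops(sk[:, :, None, None], "ASM")[0, 0])
        assert feats["inverse_difference_moment"] == pytest.approx(
            graycoprops(sk[:, :, None, None], "homogeneity")[0, 0])
        assert feats["correlation"] == pytest.approx(
            graycoprops(sk[:, :, None, None], "correlation")[0, 0], abs=1e-10)


class TestBlockFeatures:
    def test_default_block_yields_429(self, rng):
        tv = T.glcm_block_features(rng.random((10, 10, 10)))
        assert len(tv) == 429

    def test_single_cell_schema(self, rng):
        cfg = T.GLCMConfig(levels=4, distances=(1,), directions=((1, 0, 0),))
        tv = T.glcm_block_features(rng.random((6, 6, 6)), cfg,
                                   feature_set=("contrast",))
        assert len(tv) == 1
        assert tv.schema == ["contrast_d1_o(1, 0, 0)"]

    @given(st.integers(1, 11), st.integers(1, 13), st.integers(1, 3))
    @settings(max_examples=20, deadline=None)
    def test_length_accounting(self, nf, nd, ndist):
        cfg = T.GLCMConfig(levels=4,
                           distances=tuple(range(1, ndist + 1)),
                           directions=tuple(T.unique_directions_3d()[:nd]))
        tv = T.glcm_block_features(np.random.default_rng(0).random((8, 8, 8)),
                                   cfg, feature_set=T.HARALICK_FEATURES[:nf])
        assert len(tv) == nf * nd * ndist

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            T.glcm_block_features(np.ones((1, 1, 1)))


class TestRROI:
    def test_30x30_b15_four_blocks(self):
        blocks = T.rroi_blocks(np.arange(900.0).reshape(30, 30), 15)
        assert len(blocks) == 4
        assert all(b.shape == (15, 15) for b in blocks)

    def test_exact_single_block(self):
        img = np.arange(441.0).reshape(21, 21)
        blocks = T.rroi_blocks(img, 21)
        assert len(blocks) == 1
        np.testing.assert_array_equal(blocks[0], img)

    def test_disjoint_cover(self):
        img = np.arange(33 * 47, dtype=float).reshape(33, 47)
        blocks = T.rroi_blocks(img, 15)
        assert len(blocks) == (33 // 15) * (47 // 15)
        seen = np.concatenate([b.ravel() for b in blocks])
        assert len(seen) == len(set(seen))  # disjoint tiles

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            T.rroi_blocks(np.ones((10, 30)), 15)

    def test_block_stats_schema(self, rng):
        tv = T.rroi_block_features(rng.random((15, 15)))
        assert tv.schema == list(T.RROI_BLOCK_FEATURES)
        feats = dict(zip(tv.schema, tv.values))
        assert feats["central_moment_2"] >= 0
        assert feats["entropy"] >= 0


class TestDWT3D:
    def test_one_level_shapes(self, rng):
        sb = T.dwt3d(rng.standard_normal((16, 16, 16)), levels=1)
        assert sb.approximation.shape == (8, 8, 8)
        assert set(sb.details[0]) == set(T.DETAIL_ORIENTATIONS)
        assert all(d.shape == (8, 8, 8) for d in sb.details[0].values())

    @pytest.mark.parametrize("wavelet", ["haar", "db2"])
    @pytest.mark.parametrize("levels", [1, 2])
    def test_reconstruction_and_energy_20_seeds(self, wavelet, levels):
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((8, 8, 8))
            sb = T.dwt3d(x, levels=levels, wavelet=wavelet)
            rec = T.idwt3d(sb)
            assert np.abs(rec - x).max() / np.abs(x).max() < 1e-8
            e_in = (x ** 2).sum()
            e_out = (sb.approximation ** 2).sum() + sum(
                (d ** 2).sum() for lev in sb.details for d in lev.values())
            assert abs(e_in - e_out) / e_in < 1e-8

    def test_haar_approximation_hand_value(self):
        """1-level Haar LLL of a 2x2x2 block is its sum / (2*sqrt(2))."""
        x = np.arange(8.0).reshape(2, 2, 2)
        sb = T.dwt3d(x, levels=1, wavelet="haar")
        assert sb.approximation[0, 0, 0] == pytest.approx(x.sum() / (2 * np.sqrt(2)))

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            T.dwt3d(np.zeros((6, 6, 6)), levels=2)


class TestScattering:
    def test_constant_input(self):
        s = T.scattering(np.full((32, 32), 3.0), J=3, L=4)
        assert s[0] == pytest.approx(3.0, rel=1e-6)
        assert np.abs(s[1:]).max() < 1e-8

    def test_nonnegative_higher_orders(self, rng):
        s = T.scattering(rng.random((32, 32)), J=3, L=4, order=2)
        assert np.all(s[1:] >= 0)

    def test_small_input_rejected(self):
        with pytest.raises(ValueError):
            T.scattering(np.ones((6, 6)), J=3)

    def test_shift_stability_beats_permutation(self, rng):
        """One-pixel shift perturbs the descriptor far less than scrambling."""
        x = rng.random((32, 32))
        base = T.scattering(x, J=3, L=4)
        shifted = T.scattering(np.roll(x, 1, axis=0), J=3, L=4)
        permuted = T.scattering(rng.permutation(x.ravel()).reshape(32, 32), J=3, L=4)
        d_shift = np.linalg.norm(base - shifted) / np.linalg.norm(base)
        d_perm = np.linalg.norm(base - permuted) / np.linalg.norm(base)
        assert d_shift < d_perm
        assert d_shift < 0.05

    def test_3d_input_supported(self, rng):
        s = T.scattering(rng.random((8, 8, 8)), J=2, L=3, order=1)
        assert np.all(np.isfinite(s))


class TestPluginRegistry:
    def test_identity_plugin_equals_nt(self, rng):
        T.register_transform("ident_test", lambda a: np.asarray(a, dtype=float),
                             overwrite=True)
        arr = rng.random((4, 4, 4))
        np.testing.assert_array_equal(T.get_transform("ident_test")(arr),
                                      T.get_transform("NT")(arr))

    def test_unknown_stage_lists_available(self):
        with pytest.raises(KeyError, match="NT"):
            T.get_transform("nonexistent")

    def test_name_collision(self):
        with pytest.raises(ValueError, match="registered"):
            T.register_transform("NT", lambda a: a)

    def test_called_once_per_input(self, rng):
        calls = []

        def counting(a):
            calls.append(1)
            return np.asarray(a)

        T.register_transform("count_test", counting, overwrite=True)
        fn = T.get_transform("count_test")
        fn(rng.random((3, 3, 3)))
        assert len(calls) == 1
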