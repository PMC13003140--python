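import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import segnew as sn
from segnew.anomaly import anomaly_map, bank_hash, load_bank, save_bank
from segnew.features import PatchFeatureGrid


def oracle_farthest_point(points, n, start):
    """Independent greedy k-center: plain loops, no shared code with the package."""
    pts = [np.asarray(p, float) for p in points]
    chosen = [start]
    while len(chosen) < n:
        best_i, best_d = -1, -1.0
        for i in range(len(pts)):
            d = min(float(np.linalg.norm(pts[i] - pts[j])) for j in chosen)
            if d > best_d:
                best_i, best_d = i, d
        chosen.append(best_i)
    return chosen


def oracle_nn_scores(bank_vectors, queries):
    """Brute-force all-pairs nearest-neighbor scan."""
    out = []
    for q in queries:
        out.append(min(float(np.sqrt(((q - b) ** 2).sum())) for b in bank_vectors))
    return np.array(out)


def make_grid(features):
    f = np.asarray(features, float)
    return PatchFeatureGrid(features=f, stride=1, source_shape=f.shape[:2])


class TestCoresetSelect:
    def test_full_ratio_returns_all_indices(self, rng):
        X = rng.random((10, 3))
        assert sorted(sn.coreset_select(X, 1.0)) == list(range(10))

    def test_farthest_point_by_hand(self):
        X = np.array([[0.0], [1.0], [10.0]])
        assert sn.coreset_select(X, 2 / 3, start_index=0) == [0, 2]

    def test_seeded_determinism(self, rng):
        X = rng.random((30, 4))
        assert sn.coreset_select(X, 0.3, seed=5) == sn.coreset_select(X, 0.3, seed=5)

    def test_invalid_ratio_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError):
            sn.coreset_select(X, 0.0)
        with pytest.raises(ValueError):
            sn.coreset_select(X, 1.5)

    def test_matches_independent_oracle(self, rng):
        X = rng.random((50, 3))
        n = 12
        got = sn.coreset_select(X, n / 50, start_index=4)
        assert got == oracle_farthest_point(X, n, start=4)

    def test_selected_count_and_distinctness(self, rng):
        X = rng.random((37, 2))
        idx = sn.coreset_select(X, 0.25, seed=1)
        assert len(idx) == max(1, round(0.25 * 37))
        assert len(set(idx)) == len(idx)


class TestBuildBank:
    def test_empty_list_rejected(self, small_spec):
        with pytest.raises(ValueError, match="no nominal data"):
            sn.build_memory_bank([], small_spec)

    def test_constant_image_full_ratio_bank(self, small_spec):
        img = np.full((16, 16), 0.3)
        bank = sn.build_memory_bank([img], small_spec, ratio=1.0)
        assert bank.vectors.shape[0] == 16  # 4x4 grid
        assert np.allclose(bank.vectors, bank.vectors[0])

    def test_self_match_scores_zero(self, small_spec, rng):
        img = rng.random((16, 16))
        bank = sn.build_memory_bank([img, img.copy()], small_spec, ratio=1.0)
        grid = sn.aggregate_neighborhood(
            sn.extract_features(img, small_spec), small_spec.window
        )
        scores = sn.score_patches(bank, grid)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_coreset_size_follows_ratio(self, small_spec, rng):
        imgs = [rng.random((16, 16)) for _ in range(10)]
        bank = sn.build_memory_bank(imgs, small_spec, ratio=0.1)
        assert bank.vectors.shape[0] == max(1, round(0.1 * 10 * 16))


class TestScorePatches:
    def test_hand_distance(self, small_spec):
        bank = sn.MemoryBank(
            vectors=np.array([[0.0, 0.0], [1.0, 0.0]]),
            extractor=small_spec, coreset_ratio=1.0, seed=0,
        )
        grid = make_grid(np.array([[[3.0, 0.0]]]))
        assert sn.score_patches(bank, grid)[0, 0] == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self, small_spec):
        bank = sn.MemoryBank(
            vectors=np.zeros((2, 3)), extractor=small_spec, coreset_ratio=1.0, seed=0
        )
        grid = make_grid(np.zeros((1, 1, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            sn.score_patches(bank, grid)

    def test_matches_bruteforce_oracle(self, small_spec, rng):
        bank_vecs = rng.random((150, 6))
        queries = rng.random((200, 6))
        bank = sn.MemoryBank(
            vectors=bank_vecs, extractor=small_spec, coreset_ratio=1.0, seed=0
        )
        grid = make_grid(queries.reshape(20, 10, 6))
        got = sn.score_patches(bank, grid).ravel()
        np.testing.assert_allclose(got, oracle_nn_scores(bank_vecs, queries), atol=1e-12)

    def test_superset_bank_never_scores_higher(self, small_spec, rng):
        big = rng.random((40, 4))
        sub = big[:15]
        grid = make_grid(rng.random((6, 6, 4)))
        bank_big = sn.MemoryBank(vectors=big, extractor=small_spec, coreset_ratio=1.0, seed=0)
        bank_sub = sn.MemoryBank(vectors=sub, extractor=small_spec, coreset_ratio=1.0, seed=0)
        assert np.all(sn.score_patches(bank_big, grid) <= sn.score_patches(bank_sub, grid) + 1e-12)

    def test_kmean_mode_averages_k_nearest(self, small_spec):
        bank = sn.MemoryBank(
            vectors=np.array([[0.0], [1.0], [10.0]]),
            extractor=small_spec, coreset_ratio=1.0, seed=0,
        )
        grid = make_grid(np.array([[[0.0]]]))
        assert sn.score_patches(bank, grid, k=2)[0, 0] == pytest.approx(0.5)


class TestAnomalyMap:
    def test_identity_when_shapes_match_and_sigma_zero(self, rng):
        g = rng.random((8, 8))
        out = anomaly_map(g, (8, 8), smoothing_sigma=0.0)
        assert np.array_equal(out.values, g)

    def test_constant_grid_gives_constant_map(self):
        out = anomaly_map(np.full((4, 4), 0.7), (16, 16), smoothing_sigma=2.0)
        np.testing.assert_allclose(out.values, 0.7, atol=1e-12)

    def test_gaussian_wrap_preserves_total_mass(self):
        g = np.zeros((16, 16))
        g[5, 9] = 3.0
        out = anomaly_map(g, (16, 16), smoothing_sigma=2.0, pad_mode="wrap")
        assert abs(out.values.sum() - 3.0) < 1e-6

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            anomaly_map(np.ones((2, 2)), (4, 4), smoothing_sigma=-1)


class TestCalibration:
    def test_nominal_calibration_gives_zero_floor(self, small_spec, rng):
        img = rng.random((16, 16))
        bank = sn.build_memory_bank([img], small_spec, ratio=1.0)
        bank = sn.calibrate_normalization(bank, [img], smoothing_sigma=0.0)
        assert bank.norm_lo == 0.0
        assert bank.norm_hi > bank.norm_lo

    def test_minmax_bounds_span_observed_scores(self, small_spec, rng):
        nominal = rng.random((16, 16))
        probe = rng.random((16, 16)) * 3.0
        bank = sn.build_memory_bank([nominal], small_spec, ratio=1.0)
        bank = sn.calibrate_normalization(bank, [probe], smoothing_sigma=0.0)
        amap = sn.raw_anomaly_map(bank, probe, smoothing_sigma=0.0)
        assert bank.norm_lo == pytest.approx(float(amap.values.min()))
        assert bank.norm_hi == pytest.approx(float(amap.values.max()))
        normed = sn.normalize_map(amap, bank)
        assert normed.values.min() == pytest.approx(0.0)
        assert normed.values.max() == pytest.approx(1.0)

    def test_normalize_affine_and_clipping(self, small_spec):
        bank = sn.MemoryBank(
            vectors=np.zeros((1, 1)), extractor=small_spec, coreset_ratio=1.0,
            seed=0, norm_lo=0.2, norm_hi=5.0,
        )
        m = sn.ScoreMap(values=np.array([[0.2, 5.0], [7.0, 2.6]]), kind="anomaly")
        out = sn.normalize_map(m, bank)
        np.testing.assert_allclose(
            out.values, [[0.0, 1.0], [1.0, (2.6 - 0.2) / 4.8]]
        )

    def test_uncalibrated_bank_rejected(self, small_spec):
        bank = sn.MemoryBank(
            vectors=np.zeros((1, 1)), extractor=small_spec, coreset_ratio=1.0, seed=0
        )
        with pytest.raises(ValueError, match="not calibrated"):
            sn.normalize_map(sn.ScoreMap(values=np.ones((2, 2)), kind="anomaly"), bank)


class TestBankPersistence:
    def test_roundtrip_preserves_bank(self, small_spec, rng, tmp_path):
        bank = sn.build_memory_bank([rng.random((16, 16))], small_spec, ratio=0.5, seed=3)
        bank = sn.calibrate_normalization(bank, [rng.random((16, 16))], smoothing_sigma=0.0)
        path = tmp_path / "bank.npz"
        save_bank(bank, path)
        loaded = load_bank(path)
        assert np.array_equal(bank.vectors, loaded.vectors)
        assert loaded.extractor == bank.extractor
        assert bank_hash(loaded) == bank_hash(bank)
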