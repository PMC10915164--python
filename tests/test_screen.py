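"""Screening cascade: scaling, DBSCAN denoise/discovery, novelty split."""

import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_blob_matrix
from porescreen.classify import train_bagged_trees
from porescreen.features import FEATURE_COLUMNS, FeatureMatrix
from porescreen.screen import (
    SCREENING_PRESETS,
    FeatureScaler,
    ScreeningParams,
    dbscan_denoise,
    discover_unknowns,
    fit_novelty,
    match_cluster,
    scale_features,
    screen_sample,
    split_inliers,
)
from porescreen.synth import BACKGROUND, simulate_features


def brute_force_dbscan(X, eps, min_samples):
    """Reference DBSCAN oracle: O(n^2) neighborhoods + BFS expansion."""
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    neigh = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(v) >= min_samples for v in neigh])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    return labels


class TestScaling:
    def test_reference_maps_itself_into_unit_box(self, small_features):
        scaled = scale_features(small_features, small_features)
        assert scaled.min().min() >= 0.0 and scaled.max().max() <= 1.0

    def test_constant_feature_rejected(self):
        df = pd.DataFrame([[0.1, 2.0, 3.0, 0.0, 40.0]] * 5, columns=FEATURE_COLUMNS)
        fm = FeatureMatrix(df)
        with pytest.raises(ValueError):
            scale_features(fm, fm)

    def test_probe_outside_reference_not_clipped(self, rng):
        ref = gaussian_blob_matrix(rng, 100, np.zeros(5), spread=1.0)
        probe = gaussian_blob_matrix(rng, 10, np.full(5, 50.0), spread=0.1)
        scaled = scale_features(probe, ref)
        assert (scaled > 1.0).all().all()


class TestDenoise:
    def test_isolated_points_removed_and_matches_reference_oracle(self, rng):
        pts = np.vstack([
            rng.normal(0.2, 0.005, (20, 2)),
            rng.normal(0.8, 0.005, (20, 2)),
            np.array([[0.5, 0.5], [0.05, 0.9], [0.95, 0.1]]),
        ])
        df = pd.DataFrame(
            {"ratio": pts[:, 0], "std": pts[:, 1], "kurt": 3.0, "skew": 0.0, "dwell": 40.0}
        )
        params = ScreeningParams(dbscan_eps=0.05, dbscan_min_samples=5)
        kept, noise = dbscan_denoise(df, params)
        assert noise.sum() == 3 and set(np.flatnonzero(noise)) == {40, 41, 42}
        ref = brute_force_dbscan(pts, eps=0.05, min_samples=5)
        assert np.array_equal(noise, ref == -1)

    def test_identical_points_all_kept(self):
        df = pd.DataFrame(
            {"ratio": [0.3] * 10, "std": [0.5] * 10, "kurt": 3.0, "skew": 0.0, "dwell": 40.0}
        )
        kept, noise = dbscan_denoise(df, ScreeningParams(dbscan_min_samples=10))
        assert kept.all() and not noise.any()

    def test_min_samples_above_n_removes_everything(self):
        df = pd.DataFrame(
            {"ratio": [0.3] * 5, "std": [0.5] * 5, "kurt": 3.0, "skew": 0.0, "dwell": 40.0}
        )
        kept, noise = dbscan_denoise(df, ScreeningParams(dbscan_min_samples=50))
        assert noise.all()

    def test_presets_match_protocol(self):
        assert SCREENING_PRESETS["fresh_juice"].dbscan_eps == 0.17
        assert SCREENING_PRESETS["fresh_juice"].dbscan_min_samples == 18
        assert SCREENING_PRESETS["kiwifruit"].dbscan_eps == 0.10
        assert SCREENING_PRESETS["kiwifruit"].dbscan_min_samples == 10
        assert SCREENING_PRESETS["commercial"].dbscan_eps == 0.30
        assert SCREENING_PRESETS["commercial"].dbscan_min_samples == 30
        for p in SCREENING_PRESETS.values():
            assert p.ocsvm_nu == 0.05


class TestNovelty:
    def test_nu_property_on_gaussian_blob(self, rng):
        train = gaussian_blob_matrix(rng, 2000, np.array([0.5, 0.5, 0.5, 0.5, 0.5]), spread=0.1)
        model = fit_novelty(train, nu=0.05)
        _, outlier = split_inliers(model, train)
        assert 0.5 * 0.05 <= outlier.mean() <= 2 * 0.05

    def test_centroid_is_inlier_far_probe_is_outlier(self, rng):
        center = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        train = gaussian_blob_matrix(rng, 500, center, spread=0.1)
        model = fit_novelty(train)
        centroid = FeatureMatrix(
            pd.DataFrame([train.data.mean().to_numpy()], columns=FEATURE_COLUMNS)
        )
        far = FeatureMatrix(
            pd.DataFrame([center + 10 * 0.1], columns=FEATURE_COLUMNS)
        )
        inl_c, _ = split_inliers(model, centroid)
        _, out_f = split_inliers(model, far)
        assert inl_c[0] and out_f[0]

    def test_tiny_training_set_rejected(self, rng):
        train = gaussian_blob_matrix(rng, 20, np.zeros(5))
        with pytest.raises(ValueError):
            fit_novelty(train)

    def test_split_masks_partition(self, panel, rng):
        train = simulate_features(panel, {"CAT": 200, "L-MA": 200}, seed=1)
        model = fit_novelty(train)
        probe = simulate_features(panel, {"CAT": 100, "D-FRU": 100}, seed=2)
        inlier, outlier = split_inliers(model, probe)
        assert (inlier ^ outlier).all()

    def test_known_law_mostly_inliers_unknown_mostly_outliers(self, panel_with_unknowns):
        known = ["3-CQA", "D-SOR", "L-MA", "D-GLC", "D-FRU"]
        train = simulate_features(panel_with_unknowns, {c: 300 for c in known}, seed=3)
        model = fit_novelty(train)
        same = simulate_features(panel_with_unknowns, {"L-MA": 300}, seed=4)
        novel = simulate_features(panel_with_unknowns, {"U1": 300}, seed=5)
        inl, _ = split_inliers(model, same)
        _, out = split_inliers(model, novel)
        assert inl.mean() >= 0.90
        assert out.mean() >= 0.90

    def test_empty_matrix_empty_masks(self, panel):
        train = simulate_features(panel, {"CAT": 200}, seed=1)
        model = fit_novelty(train)
        empty = train.subset(np.zeros(len(train), dtype=bool))
        inl, out = split_inliers(model, empty)
        assert inl.size == 0 and out.size == 0


class TestDiscoverUnknowns:
    def _scaler(self, fm):
        return FeatureScaler.fit(fm, tuple(FEATURE_COLUMNS))

    def test_injected_cluster_registered(self, rng):
        cluster = gaussian_blob_matrix(rng, 100, np.full(5, 0.8), spread=0.01)
        scatter = gaussian_blob_matrix(rng, 10, np.full(5, 0.4), spread=0.3)
        outliers = FeatureMatrix.concat([cluster, scatter])
        ref = gaussian_blob_matrix(rng, 200, np.full(5, 0.5), spread=0.3)
        registry = discover_unknowns(
            outliers, ScreeningParams(dbscan_eps=0.05, dbscan_min_samples=18), self._scaler(ref)
        )
        assert list(registry) == ["U1"]
        assert np.isin(np.arange(100), registry["U1"]).sum() >= 90

    def test_empty_outliers_empty_registry(self, rng):
        ref = gaussian_blob_matrix(rng, 100, np.full(5, 0.5), spread=0.3)
        empty = ref.subset(np.zeros(len(ref), dtype=bool))
        assert discover_unknowns(empty, ScreeningParams(), self._scaler(ref)) == {}

    def test_clusters_ordered_by_size(self, rng):
        big = gaussian_blob_matrix(rng, 80, np.array([0.9, 0.9, 0.5, 0.5, 0.5]), spread=0.005)
        small = gaussian_blob_matrix(rng, 40, np.array([0.1, 0.1, 0.5, 0.5, 0.5]), spread=0.005)
        outliers = FeatureMatrix.concat([small, big])  # deliberately reversed
        ref = gaussian_blob_matrix(rng, 100, np.full(5, 0.5), spread=0.3)
        registry = discover_unknowns(
            outliers, ScreeningParams(dbscan_eps=0.05, dbscan_min_samples=20), self._scaler(ref)
        )
        assert len(registry["U1"]) == 80 and len(registry["U2"]) == 40


class TestMatchCluster:
    def test_same_law_matches_distant_does_not(self, panel_with_unknowns):
        ref = simulate_features(panel_with_unknowns, {"sucrose": 500}, seed=1)
        same = simulate_features(panel_with_unknowns, {"sucrose": 80}, seed=2)
        far = simulate_features(panel_with_unknowns, {"U1": 80}, seed=3)
        assert match_cluster(same, ref) is True
        assert match_cluster(far, ref) is False

    def test_zero_accept_fraction_always_matches(self, panel):
        ref = simulate_features(panel, {"CAT": 200}, seed=1)
        probe = simulate_features(panel, {"L-TA": 50}, seed=2)
        assert match_cluster(probe, ref, accept_fraction=0.0) is True

    def test_empty_cluster_rejected(self, panel):
        ref = simulate_features(panel, {"CAT": 200}, seed=1)
        empty = ref.subset(np.zeros(len(ref), dtype=bool))
        with pytest.raises(ValueError):
            match_cluster(empty, ref)


KNOWN_SCREEN_CLASSES = ["CAT", "D-SOR", "L-TA", "D-FRU"]


@pytest.fixture(scope="module")
def models(panel_with_unknowns):
    train = simulate_features(
        panel_with_unknowns, {c: 400 for c in KNOWN_SCREEN_CLASSES}, seed=10
    )
    clf = train_bagged_trees(train, seed=10)
    nov = fit_novelty(train)
    return clf, nov


class TestScreenSample:
    KNOWN = KNOWN_SCREEN_CLASSES

    def test_known_classes_only(self, panel_with_unknowns, models):
        clf, nov = models
        counts = {"CAT": 300, "D-SOR": 250, "L-TA": 250, "D-FRU": 200}
        sample = simulate_features(panel_with_unknowns, counts, seed=11)
        result = screen_sample(sample, clf, nov)
        total = sum(counts.values())
        for c, n in counts.items():
            assert abs(result.proportions.get(c, 0.0) - n / total) < 0.03
        assert result.unknown_registry == {}

    def test_injected_unknown_cluster_found(self, panel_with_unknowns, models):
        clf, nov = models
        counts = {"CAT": 300, "D-SOR": 300, "L-TA": 300, "D-FRU": 250, "U2": 150}
        sample = simulate_features(panel_with_unknowns, counts, seed=12)
        result = screen_sample(sample, clf, nov)
        assert len(result.unknown_registry) >= 1
        u1 = result.unknown_registry["U1"]  # largest cluster
        injected = np.flatnonzero(sample.labels == "U2")
        assert np.isin(u1, injected).mean() > 0.9
        assert abs(result.proportions["U1"] - 150 / 1300) < 0.03

    def test_background_noise_removed(self, panel_with_unknowns, models):
        clf, nov = models
        counts = {"CAT": 300, "D-SOR": 300, "L-TA": 300, "D-FRU": 250, BACKGROUND: 80}
        sample = simulate_features(panel_with_unknowns, counts, seed=13)
        result = screen_sample(sample, clf, nov)
        bg_idx = sample.labels == BACKGROUND
        assert result.noise_mask[bg_idx].mean() > 0.5  # most background is non-clustered

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_conservation_and_proportions_sum(self, panel_with_unknowns, models, seed):
        clf, nov = models
        counts = {"CAT": 200, "D-SOR": 150, "L-TA": 100, "D-FRU": 120,
                  "U1": 60, BACKGROUND: 40}
        sample = simulate_features(panel_with_unknowns, counts, seed=seed)
        result = screen_sample(sample, clf, nov)
        assert result.conservation_ok()
        n_clustered = sum(len(v) for v in result.unknown_registry.values())
        assert result.n_input == (
            result.noise_mask.sum() + result.inlier_mask.sum()
            + n_clustered + (result.outlier_mask.sum() - n_clustered)
        )
        assert sum(result.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert not (result.inlier_mask & result.outlier_mask).any()
        assert not (result.kept_mask & result.noise_mask).any()

    def test_deterministic(self, panel_with_unknowns, models):
        clf, nov = models
        counts = {"CAT": 200, "D-SOR": 200, "L-TA": 200, "D-FRU": 200, "U1": 80}
        sample = simulate_features(panel_with_unknowns, counts, seed=30)
        r1 = screen_sample(sample, clf, nov)
        r2 = screen_sample(sample, clf, nov)
        assert np.array_equal(r1.inlier_mask, r2.inlier_mask)
        assert np.array_equal(r1.inlier_labels, r2.inlier_labels)
        assert r1.proportions == r2.proportions
        assert set(r1.unknown_registry) == set(r2.unknown_registry)
        for k in r1.unknown_registry:
            assert np.array_equal(r1.unknown_registry[k], r2.unknown_registry[k])
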