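"""Normalization, clustering, cluster labelling, tree training, scene classification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from kelpcanopy.classify import (
    TrainedClassifier,
    assign_cluster_classes,
    build_training_set,
    classify_scene,
    cluster_training_spectra,
    normalize_bands,
    train_decision_tree,
)
from kelpcanopy.masking import cloud_mask_from_qa
from kelpcanopy.scene import CLOUD, KELP, LAND, OLI, SEAWATER, TM_ETM
from kelpcanopy.simulate import generate_scene

from conftest import make_truth


class TestNormalizeBands:
    def test_flat_spectrum_maps_to_ones(self):
        np.testing.assert_allclose(normalize_bands(np.full(6, 0.1)), np.ones(6))

    def test_scale_invariance(self, rng):
        x = rng.random(6) + 0.01
        np.testing.assert_allclose(normalize_bands(x), normalize_bands(3 * x))

    def test_hand_value(self):
        x = np.array([0.06, 0.04, 0.02, 0.20, 0.04, 0.00])
        np.testing.assert_allclose(normalize_bands(x), x / 0.06)

    def test_idempotent(self, rng):
        x = rng.random(6) + 0.01
        once = normalize_bands(x)
        np.testing.assert_allclose(normalize_bands(once), once)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            normalize_bands(np.zeros(6))


class TestClustering:
    def test_well_separated_blobs_recovered(self, rng):
        k = 4
        centers = rng.random((k, 6)) * 10
        truth, X = [], []
        for i, c in enumerate(centers):
            X.append(c + rng.normal(0, 0.01, size=(30, 6)))
            truth += [i] * 30
        labels = cluster_training_spectra(np.vstack(X), k=k, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicates_get_identical_labels(self, rng):
        X = np.repeat(rng.random((20, 6)), 2, axis=0)
        labels = cluster_training_spectra(X, k=15, seed=0)
        assert np.all(labels[0::2] == labels[1::2])

    def test_assignment_is_a_fixed_point(self, rng):
        X = rng.random((60, 6))
        labels = cluster_training_spectra(X, k=5, seed=1)
        centroids = np.stack([X[labels == c].mean(axis=0) for c in range(5)])
        d = np.linalg.norm(X[:, None, :] - centroids[None], axis=2)
        np.testing.assert_array_equal(np.argmin(d, axis=1), labels)

    def test_fewer_spectra_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            cluster_training_spectra(rng.random((10, 6)), k=15)

    def test_seeded_determinism(self, rng):
        X = rng.random((100, 6))
        a = cluster_training_spectra(X, k=15, seed=3)
        b = cluster_training_spectra(X, k=15, seed=3)
        np.testing.assert_array_equal(a, b)


class TestClusterClassAssignment:
    def test_pure_clusters_reproduce_truth(self):
        labels = np.array([0, 0, 1, 1, 2])
        truth = np.array([KELP, KELP, SEAWATER, SEAWATER, LAND])
        classes, _ = assign_cluster_classes(labels, truth_classes=truth)
        np.testing.assert_array_equal(classes, truth)

    def test_mixed_cluster_takes_majority(self):
        labels = np.zeros(5, dtype=int)
        truth = np.array([KELP, KELP, KELP, SEAWATER, SEAWATER])
        classes, mapping = assign_cluster_classes(labels, truth_classes=truth)
        assert mapping[0] == KELP and np.all(classes == KELP)

    def test_unmapped_cluster_rejected(self):
        with pytest.raises(ValueError, match="without a class"):
            assign_cluster_classes(np.array([0, 1]), mapping={0: KELP})

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            assign_cluster_classes(np.array([0, 1]))


class TestDecisionTree:
    def test_nir_separable_classes_solved_at_depth_one(self, rng):
        # kelp: high normalized NIR; seawater: low -- one split suffices
        water = normalize_bands(np.abs(rng.normal(0.05, 0.01, size=(50, 6))) + 0.01)
        kelp = water.copy()
        kelp[:, 3] += 2.0
        X = np.vstack([water, kelp])
        y = np.array([SEAWATER] * 50 + [KELP] * 50)
        clf = train_decision_tree(X, y, TM_ETM, max_depth=1)
        assert clf.training_accuracy == 1.0
        # exhaustive single-split oracle: some threshold on some band separates
        found = any(
            len(np.unique(y[X[:, b] <= t])) == 1 and len(np.unique(y[X[:, b] > t])) == 1
            for b in range(6)
            for t in np.unique(X[:, b])[:-1]
        )
        assert found

    def test_conflicting_labels_yield_majority_accuracy(self):
        X = np.ones((10, 6))
        y = np.array([KELP] * 7 + [SEAWATER] * 3)
        clf = train_decision_tree(X, y, TM_ETM)
        assert clf.training_accuracy == pytest.approx(0.7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_decision_tree(np.ones((5, 6)), np.full(5, KELP), TM_ETM)

    def test_json_round_trip_predicts_identically(self, rng):
        X = rng.random((80, 6))
        y = rng.integers(0, 3, size=80)
        clf = train_decision_tree(X, y, OLI, seed=1)
        clf2 = TrainedClassifier.from_json(clf.to_json())
        np.testing.assert_array_equal(clf.predict(X), clf2.predict(X))
        assert clf2.sensor_generation == OLI


@pytest.fixture(scope="module")
def trained(library):
    # several scenes so the per-scene seawater draws are represented
    truth = make_truth(
        np.where(np.arange(100).reshape(10, 10) % 3 == 0, 0.6, 0.0)
    )
    truth.class_map[0, :3] = CLOUD
    truth.kelp_fraction[0, :3] = 0.0
    scenes = [
        generate_scene(truth, library, noise_sd=0.002, seed=s)
        for s in range(11, 23)
    ]
    X, y = build_training_set(
        scenes, [truth] * len(scenes), n_samples=1200, k=10, seed=0
    )
    return train_decision_tree(X, y, TM_ETM, seed=0)


class TestClassifyScene:
    def test_pure_seawater_scene_has_no_kelp(self, library, trained):
        truth = make_truth(np.zeros((8, 8)))
        scene = generate_scene(truth, library, noise_sd=0.0, seed=2)
        classes = classify_scene(scene, trained)
        assert not np.any(classes == KELP)

    def test_noiseless_scene_matches_truth(self, library, trained):
        truth = make_truth(np.where(np.eye(8) > 0, 0.7, 0.0))
        scene = generate_scene(truth, library, noise_sd=0.0, seed=3)
        classes = classify_scene(scene, trained)
        agree = (classes == truth.class_map).mean()
        assert agree >= 0.99

    def test_masked_pixels_carry_mask_class(self, library, trained):
        truth = make_truth(np.zeros((6, 6)))
        scene = generate_scene(truth, library, noise_sd=0.0, seed=4)
        cloud = np.zeros((6, 6), dtype=bool)
        cloud[0] = True
        land = np.zeros((6, 6), dtype=bool)
        land[:, 0] = True
        classes = classify_scene(scene, trained, cloud_mask=cloud, land_mask=land)
        assert (classes[0] == CLOUD).all()
        assert (classes[1:, 0] == LAND).all()

    def test_generation_mismatch_rejected(self, library, trained):
        truth = make_truth(np.zeros((4, 4)))
        scene = generate_scene(
            truth, library, noise_sd=0.0, seed=5, sensor_generation=OLI
        )
        with pytest.raises(ValueError, match="generation"):
            classify_scene(scene, trained)

    def test_sensor_generations_trained_independently(self, rng):
        X = rng.random((60, 6))
        y = rng.integers(0, 2, size=60)
        a = train_decision_tree(X, y, TM_ETM, seed=0)
        b = train_decision_tree(X[::-1], y[::-1], OLI, seed=0)
        assert a.sensor_generation != b.sensor_generation
        assert a.threshold is not b.threshold


def test_end_to_end_noiseless_classification_on_simulated_scene(library, pipeline_run):
    """Classes from the pipeline's tree match truth on a noiseless scene."""
    from kelpcanopy.simulate import generate_spectral_library

    res = pipeline_run
    acq = res.acquisitions[10]
    truth = acq.truth
    noiseless = generate_scene(
        truth, generate_spectral_library(res.config.seed),
        noise_sd=0.0, seed=1, sensor_generation=acq.scene.sensor_generation,
    )
    from kelpcanopy.pipeline import _train_classifiers
    clfs = _train_classifiers(res.acquisitions, res.config)
    cloud = cloud_mask_from_qa(noiseless.qa)
    classes = classify_scene(noiseless, clfs[acq.scene.sensor_generation], cloud_mask=cloud)
    free = ~cloud & (truth.class_map != 4)  # intertidal handled by its own mask
    assert (classes[free] == truth.class_map[free]).mean() >= 0.99
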