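"""Band normalization, k-means-seeded training sets, and the 4-class tree.

Pixels are classified into kelp canopy / seawater / cloud / land from
brightness-normalized six-band spectra.  Training spectra are grouped by
unsupervised k-means (15 clusters) and each cluster is assigned a class —
in the original workflow by an analyst, here either from a user mapping or
automatically by the majority ground-truth class per cluster.  A separate
binary decision tree (CART, Gini impurity) is trained per sensor generation
because the band response functions differ between instrument families.

Band normalization is division by the mean of the six bands, making the
classifier invariant to overall brightness (sun glint, haze): the exact
normalization used operationally is not published, so this is an explicit
package choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeClassifier

from .scene import CLOUD, INTERTIDAL, LAND, N_BANDS, Scene

__all__ = [
    "normalize_bands",
    "cluster_training_spectra",
    "assign_cluster_classes",
    "TrainedClassifier",
    "train_decision_tree",
    "classify_scene",
    "build_training_set",
]

DEFAULT_K = 15
DEFAULT_MAX_DEPTH = 8


def normalize_bands(spectra: np.ndarray) -> np.ndarray:
    """Divide each spectrum by its six-band mean (scale-invariant, idempotent
    up to the mean being 1 afterwards).

    Accepts a single spectrum ``(6,)`` or a stack ``(..., 6)``.  All-zero
    spectra are rejected: brightness normalization is undefined for them.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != N_BANDS:
        raise ValueError(f"expected {N_BANDS} bands on the last axis")
    mean = spectra.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("all-zero (or negative-mean) spectrum cannot be normalized")
    return spectra / mean


def cluster_training_spectra(
    spectra: np.ndarray, k: int = DEFAULT_K, seed: int = 0
) -> np.ndarray:
    """k-means cluster labels for normalized training spectra.

    Euclidean distance, 10 seeded restarts keeping the best inertia.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be a 2-D (n, bands) array")
    if len(spectra) < k:
        raise ValueError(f"need at least k={k} spectra, got {len(spectra)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(spectra)


def assign_cluster_classes(
    labels: np.ndarray,
    truth_classes: np.ndarray | None = None,
    mapping: Mapping[int, int] | None = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Turn cluster labels into per-spectrum class labels.

    Either pass an explicit ``mapping`` cluster -> class (the manual route:
    every cluster must be mapped), or ``truth_classes`` from which each
    cluster takes its majority class (the automated route used in tests and
    the synthetic pipeline).  Returns (per-spectrum classes, mapping used).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if mapping is not None:
        missing = [int(c) for c in clusters if int(c) not in mapping]
        if missing:
            raise ValueError(f"clusters without a class assignment: {missing}")
        used = {int(c): int(mapping[int(c)]) for c in clusters}
    elif truth_classes is not None:
        truth_classes = np.asarray(truth_classes)
        used = {}
        for c in clusters:
            members = truth_classes[labels == c]
            vals, counts = np.unique(members, return_counts=True)
            used[int(c)] = int(vals[np.argmax(counts)])
    else:
        raise ValueError("either truth_classes or mapping is required")
    out = np.array([used[int(c)] for c in labels])
    return out, used


@dataclass
class TrainedClassifier:
    """A trained 4-class decision tree tied to one sensor generation.

    Stores the tree as plain arrays so it serializes to portable JSON text
    and predicts identically after a save/load round trip.
    """

    sensor_generation: str
    classes: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class_index: np.ndarray
    max_depth: int = DEFAULT_MAX_DEPTH
    training_accuracy: float = field(default=np.nan)

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Classes for normalized spectra ``(..., 6)``."""
        X = np.asarray(spectra, dtype=float)
        flat = X.reshape(-1, X.shape[-1])
        node = np.zeros(len(flat), dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            nd = node[active]
            go_left = flat[active, self.feature[nd]] <= self.threshold[nd]
            node[active] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.feature[node] >= 0
        out = self.classes[self.leaf_class_index[node]]
        return out.reshape(X.shape[:-1])

    def to_json(self) -> str:
        payload = {
            "sensor_generation": self.sensor_generation,
            "classes": self.classes.tolist(),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class_index": self.leaf_class_index.tolist(),
            "max_depth": self.max_depth,
            "training_accuracy": float(self.training_accuracy),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        return cls(
            sensor_generation=d["sensor_generation"],
            classes=np.asarray(d["classes"]),
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            leaf_class_index=np.asarray(d["leaf_class_index"], dtype=np.int64),
            max_depth=int(d["max_depth"]),
            training_accuracy=float(d["training_accuracy"]),
        )


def train_decision_tree(
    spectra: np.ndarray,
    labels: np.ndarray,
    sensor_generation: str,
    max_depth: int = DEFAULT_MAX_DEPTH,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a CART tree (Gini, axis-aligned splits, no pruning) on normalized
    spectra; at least two classes must be present."""
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, random_state=seed
    ).fit(spectra, labels)
    t = tree.tree_
    leaf_class_index = np.argmax(t.value[:, 0, :], axis=1).astype(np.int64)
    clf = TrainedClassifier(
        sensor_generation=sensor_generation,
        classes=tree.classes_,
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(float),
        leaf_class_index=leaf_class_index,
        max_depth=max_depth,
    )
    clf.training_accuracy = float(np.mean(clf.predict(spectra) == labels))
    return clf


def classify_scene(
    scene: Scene,
    classifier: TrainedClassifier,
    cloud_mask: np.ndarray | None = None,
    land_mask: np.ndarray | None = None,
    intertidal: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel class raster for one scene.

    Masked pixels carry their mask class (cloud / land / intertidal) and are
    never sent to the tree; every unmasked pixel gets one of the four
    classes.  The classifier's sensor generation must match the scene's.
    """
    if classifier.sensor_generation != scene.sensor_generation:
        raise ValueError(
            f"classifier generation {classifier.sensor_generation!r} does not "
            f"match scene generation {scene.sensor_generation!r}"
        )
    shape = scene.shape
    excluded = np.zeros(shape, dtype=bool)
    out = np.empty(shape, dtype=np.int64)
    for mask, code in ((cloud_mask, CLOUD), (land_mask, LAND), (intertidal, INTERTIDAL)):
        if mask is not None:
            out[mask & ~excluded] = code
            excluded |= mask
    free = ~excluded
    if free.any():
        out[free] = classifier.predict(normalize_bands(scene.bands[free]))
    return out


def build_training_set(
    scenes: list[Scene],
    truths: list,
    n_samples: int = 4000,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pixels across scenes and label them via k-means + truth majority.

    Returns (normalized spectra, class labels) ready for
    :func:`train_decision_tree`.  Emulates the analyst-labelled training set
    with the cluster labelling automated from ground truth.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    per_scene = max(1, n_samples // max(1, len(scenes)))
    for scene, truth in zip(scenes, truths):
        H, W = scene.shape
        idx = rng.choice(H * W, size=min(per_scene, H * W), replace=False)
        r, c = np.unravel_index(idx, (H, W))
        X.append(scene.bands[r, c])
        y.append(truth.class_map[r, c])
    Xn = normalize_bands(np.concatenate(X))
    truth_cls = np.concatenate(y)
    # intertidal pixels flip between land-like and water-like with the tide;
    # they are handled by the intertidal mask, not the classifier
    keep = truth_cls != INTERTIDAL
    Xn, truth_cls = Xn[keep], truth_cls[keep]
    labels = cluster_training_spectra(Xn, k=min(k, len(Xn)), seed=seed)
    classes, _ = assign_cluster_classes(labels, truth_classes=truth_cls)
    return Xn, classes
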