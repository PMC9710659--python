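"""First-order-statistics (FOS) baseline.

The sequence-agnostic baseline the message-passing model is compared
against: for every residue, average the incident edge feature triples
(distance, cos phi, cos psi) over its graph neighborhood and classify the
resulting R^3 vector with a k-nearest-neighbor vote.  Along a strand the
backbone extends in a locally straight direction while a helix spirals,
so these neighborhood moments already separate the major classes; what
they lack is any learned interaction between neighboring residues.

A variant appends the per-channel variances (R^6); the default is the
plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .errors import ValidationError
from .graph_builder import ResidueGraph


def fos_features(g: ResidueGraph, with_variance: bool = False) -> np.ndarray:
    """Per-node neighborhood moments of the directed edge features.

    Means over unmasked incoming edge features per channel; isolated nodes
    (or fully masked channels) get zeros.  With ``with_variance`` the
    per-channel population variances are appended.
    """
    if g.edge_attr is None:
        raise ValidationError("graph has no edge features; run attach_edge_features")
    n, dim = g.n_nodes, g.edge_attr.shape[1]
    dst = g.edge_index[1]
    valid = g.edge_mask.astype(float)
    vals = np.where(g.edge_mask, g.edge_attr, 0.0)

    sums = np.zeros((n, dim))
    counts = np.zeros((n, dim))
    np.add.at(sums, dst, vals)
    np.add.at(counts, dst, valid)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    if not with_variance:
        return means
    sq = np.zeros((n, dim))
    np.add.at(sq, dst, vals ** 2)
    var = np.where(counts > 0, sq / np.maximum(counts, 1) - means ** 2, 0.0)
    return np.concatenate([means, np.maximum(var, 0.0)], axis=1)


@dataclass
class FosModel:
    """A fitted k-NN vote over FOS feature vectors."""

    classifier: KNeighborsClassifier
    k: int
    n_features: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValidationError(
                f"expected (n, {self.n_features}) features, got {features.shape}"
            )
        return self.classifier.predict(features)


def fos_fit(features: np.ndarray, labels: np.ndarray, k_classifier: int = 20) -> FosModel:
    """Fit the k-nearest-neighbor classifier on FOS features.

    Prediction is a majority vote among the ``k_classifier`` nearest
    training vectors (Euclidean metric); vote ties resolve to the
    smallest class id.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValidationError("features must be (n, d) aligned with labels")
    if k_classifier < 1:
        raise ValidationError("k_classifier must be >= 1")
    if len(features) < k_classifier:
        raise ValidationError(
            f"need at least k_classifier={k_classifier} training nodes, "
            f"got {len(features)}"
        )
    clf = KNeighborsClassifier(n_neighbors=k_classifier, algorithm="brute")
    clf.fit(features, labels)
    return FosModel(classifier=clf, k=k_classifier, n_features=features.shape[1])
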