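"""Baseline anomaly detectors behind a single scoring interface.

Every detector consumes an :class:`~planqa.schema.EncodedMatrix` and emits
one finite score per row with the orientation "higher = more anomalous",
so the same threshold-and-evaluate pipeline serves all of them.

LOF and OC-SVM are backed by scikit-learn; HDBSCAN scoring is derived from
``sklearn.cluster.HDBSCAN`` cluster-membership strengths; the PCA
reconstruction error (the linear analogue of the autoencoder score) is
computed directly from the spectral factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

from .autoencoder import AEConfig, fit_autoencoder, sample_errors
from .detection import (
    Metrics,
    classify,
    compute_metrics,
    roc_and_auc,
    select_threshold_tpr1,
)
from .schema import EncodedMatrix

__all__ = [
    "DetectorSpec",
    "GridResult",
    "pca_scores",
    "lof_scores",
    "ocsvm_scores",
    "hdbscan_scores",
    "detector_scores",
    "grid_search",
    "default_grids",
]

DETECTOR_KINDS = ("lof", "hdbscan", "ocsvm", "pca", "autoencoder")


@dataclass(frozen=True)
class DetectorSpec:
    """A detector kind plus its parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DETECTOR_KINDS:
            raise ValueError(f"unknown detector kind {self.kind!r}")

    def label(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.kind}({inner})"


@dataclass
class GridResult:
    """Per-candidate evaluation records and the winning spec."""

    records: list[dict]
    best: DetectorSpec
    objective: str


def _as_array(X) -> np.ndarray:
    if isinstance(X, EncodedMatrix):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def pca_scores(X, n_components: int) -> np.ndarray:
    """Squared residual norm after projecting onto the top principal components.

    The data is centered, the leading ``n_components`` right singular
    vectors span the model subspace, and each row's score is the squared
    distance to its projection — the reconstruction loss of the linear map.
    """
    A = _as_array(X)
    n, d = A.shape
    if not 1 <= n_components < d:
        raise ValueError(f"n_components must be in [1, {d - 1}]")
    mu = A.mean(axis=0)
    C = A - mu
    _, _, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt[:n_components].T  # (d, k)
    residual = C - (C @ V) @ V.T
    return np.sum(residual**2, axis=1)


def lof_scores(X, n_neighbors: int = 10) -> np.ndarray:
    """Local outlier factor; scores > 1 indicate lower-than-neighbors density."""
    A = _as_array(X)
    if A.shape[0] <= n_neighbors:
        raise ValueError("n_neighbors must be < number of plans")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(A)
    return -lof.negative_outlier_factor_


def ocsvm_scores(X, nu: float = 0.001, gamma: float = 0.1) -> np.ndarray:
    """One-class SVM: negated signed distance to the learned boundary."""
    A = _as_array(X)
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    model = OneClassSVM(nu=nu, gamma=gamma)
    model.fit(A)
    scores = -model.decision_function(A)
    if not np.all(np.isfinite(scores)):
        raise ValueError("degenerate kernel matrix: non-finite OC-SVM scores")
    return scores


def hdbscan_scores(X, min_cluster_size: int = 200) -> np.ndarray:
    """Hierarchy-derived outlier score in [0, 1], higher = more anomalous.

    Points assigned to a cluster score ``1 - membership_strength``; noise
    points score 1.  If every point is noise the scores are all maximal and
    a warning is emitted.
    """
    A = _as_array(X)
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if np.ptp(A, axis=0).max() == 0.0:
        return np.zeros(A.shape[0])  # identical points: maximally dense
    clusterer = HDBSCAN(
        min_cluster_size=min(min_cluster_size, max(2, A.shape[0] - 1)), copy=True
    )
    labels = clusterer.fit_predict(A)
    scores = 1.0 - np.asarray(clusterer.probabilities_, dtype=float)
    if np.all(labels == -1):
        warnings.warn("all points classified as noise by HDBSCAN", UserWarning)
        return np.ones(A.shape[0])
    return scores


def autoencoder_scores(data: EncodedMatrix, **params) -> np.ndarray:
    config = AEConfig(**params)
    result = fit_autoencoder(data, config)
    return sample_errors(result.model, data, config.lambda_weight)


def detector_scores(spec: DetectorSpec, data: EncodedMatrix) -> np.ndarray:
    """Dispatch a spec to its scoring routine on the shared interface."""
    if spec.kind == "pca":
        return pca_scores(data, **spec.params)
    if spec.kind == "lof":
        return lof_scores(data, **spec.params)
    if spec.kind == "ocsvm":
        return ocsvm_scores(data, **spec.params)
    if spec.kind == "hdbscan":
        return hdbscan_scores(data, **spec.params)
    if spec.kind == "autoencoder":
        return autoencoder_scores(data, **spec.params)
    raise ValueError(f"unknown detector kind {spec.kind!r}")


def evaluate_scores(scores: np.ndarray, labels) -> Metrics:
    """Shared scoring -> TPR==1 threshold -> metrics pipeline, with AUC."""
    threshold = select_threshold_tpr1(scores, labels)
    flags = classify(scores, threshold)
    metrics = compute_metrics(flags, labels)
    _, auc = roc_and_auc(scores, labels)
    return Metrics(
        accuracy=metrics.accuracy,
        precision=metrics.precision,
        recall=metrics.recall,
        fpr=metrics.fpr,
        f1=metrics.f1,
        anomalies=metrics.anomalies,
        confusion=metrics.confusion,
        auc=auc,
    )


def grid_search(
    spec_grid: list[DetectorSpec],
    data: EncodedMatrix,
    labels,
    objective: str = "auc",
) -> GridResult:
    """Evaluate every candidate and pick the best by the stated objective.

    Objectives: ``auc`` or ``precision_at_tpr1``.  Ties break toward the
    smaller "anomalies" count, then toward the earlier-listed candidate.
    """
    if not spec_grid:
        raise ValueError("empty parameter grid")
    if objective not in ("auc", "precision_at_tpr1"):
        raise ValueError(f"unknown objective {objective!r}")

    records = []
    for i, spec in enumerate(spec_grid):
        scores = detector_scores(spec, data)
        metrics = evaluate_scores(scores, labels)
        records.append(
            {
                "spec": spec,
                "order": i,
                "objective_value": (
                    metrics.auc if objective == "auc" else metrics.precision
                ),
                **metrics.to_dict(),
            }
        )
    best = min(
        records, key=lambda r: (-r["objective_value"], r["anomalies"], r["order"])
    )
    return GridResult(records=records, best=best["spec"], objective=objective)


def default_grids(n_dims: int) -> dict[str, list[DetectorSpec]]:
    """Default parameter grids centered on each baseline's usual optima."""
    pca_max = max(2, n_dims - 1)
    pca_candidates = sorted({4, 8, 16, 24, 36, pca_max} & set(range(1, n_dims)))
    return {
        "lof": [DetectorSpec("lof", {"n_neighbors": k}) for k in (5, 10, 20, 40)],
        "ocsvm": [
            DetectorSpec("ocsvm", {"nu": nu, "gamma": g})
            for nu in (1e-3, 1e-2, 0.1)
            for g in (0.01, 0.1, 1.0)
        ],
        "pca": [DetectorSpec("pca", {"n_components": k}) for k in pca_candidates],
        "hdbscan": [
            DetectorSpec("hdbscan", {"min_cluster_size": m}) for m in (25, 50, 100, 200)
        ],
    }
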