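"""Spectral-state abstraction across subjects: pool dB-deviation windows,
reduce with PCA, cluster with k-means, and validate against ground truth.

Because the dB-deviation normalization already removes per-subject offsets,
windows from different animals/sessions can be pooled into one feature
matrix and clustered jointly; per-condition analyses then reuse the global
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import IncompatibleGridError, InvalidParameterError
from .types import DbDeviationSpectrogram

__all__ = [
    "FeatureMatrix",
    "Labeling",
    "assemble_feature_matrix",
    "pca_project",
    "kmeans_cluster",
    "align_labels",
]

DEFAULT_N_COMPONENTS = 3
DEFAULT_K = 8
DEFAULT_RESTARTS = 20


@dataclass
class FeatureMatrix:
    """Pooled dB-deviation windows: one row per (subject, condition, window)."""

    values: np.ndarray
    index: pd.MultiIndex  # levels: subject_id, condition, window_index
    freqs_hz: np.ndarray
    window_duration_s: float

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.freqs_hz)


@dataclass
class Labeling:
    """k-means result: per-row cluster labels plus centroids and inertia."""

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    k: int


def assemble_feature_matrix(
    cohort: list[DbDeviationSpectrogram],
    band_hz: tuple[float, float] = (0.5, 120.0),
) -> FeatureMatrix:
    """Stack dB-deviation rows across the cohort, restricted to a band.

    Rows are ordered deterministically by (subject_id, condition) of each
    spectrogram in sorted order, then window index. All spectrograms must
    share the frequency grid and window duration.
    """
    if not cohort:
        raise InvalidParameterError("empty cohort")
    ordered = sorted(cohort, key=lambda s: (s.subject_id, s.condition))
    ref = ordered[0]
    lo, hi = band_hz
    mask = (ref.freqs_hz >= lo) & (ref.freqs_hz <= hi)
    if not mask.any():
        raise InvalidParameterError("feature band selects no frequency bins")
    blocks, tuples = [], []
    for s in ordered:
        if s.freqs_hz.shape != ref.freqs_hz.shape or not np.allclose(
            s.freqs_hz, ref.freqs_hz
        ):
            raise IncompatibleGridError("spectrograms have mismatched frequency grids")
        if abs(s.window_duration_s - ref.window_duration_s) > 1e-9:
            raise IncompatibleGridError("spectrograms have mismatched window durations")
        blocks.append(s.db[:, mask])
        tuples.extend((s.subject_id, s.condition, w) for w in range(s.n_windows))
    index = pd.MultiIndex.from_tuples(
        tuples, names=["subject_id", "condition", "window_index"]
    )
    return FeatureMatrix(
        np.vstack(blocks), index, ref.freqs_hz[mask], ref.window_duration_s
    )


def pca_project(
    F: FeatureMatrix | np.ndarray, n_components: int = DEFAULT_N_COMPONENTS
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and explained-variance fractions.

    Component signs are fixed by requiring the largest-magnitude loading of
    each component to be positive, so projections are reproducible across
    runs and platforms.
    """
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    if n_components > min(X.shape):
        raise InvalidParameterError(
            f"n_components={n_components} exceeds min(rows, columns)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return scores, pca.explained_variance_ratio_


def kmeans_cluster(
    scores: np.ndarray,
    k: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> Labeling:
    """Euclidean k-means, best of ``n_restarts`` k-means++ initializations."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < k:
        raise InvalidParameterError(f"need at least k={k} rows, got {scores.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(scores)
    return Labeling(labels.astype(np.int64), km.cluster_centers_, float(km.inertia_), k)


def align_labels(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[dict[int, int], float]:
    """Optimal one-to-one label matching and its agreement fraction.

    The mapping (predicted label -> truth label) maximizes the matched count
    on the confusion matrix via the Hungarian assignment; agreement is the
    matched fraction in [0, 1]. Used to validate clusterings against
    synthetic ground truth, where label identities are arbitrary.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise InvalidParameterError("label arrays must have the same length")
    pred_ids = np.unique(predicted)
    true_ids = np.unique(truth)
    C = np.zeros((pred_ids.size, true_ids.size), dtype=np.int64)
    pi = {p: i for i, p in enumerate(pred_ids)}
    ti = {t: j for j, t in enumerate(true_ids)}
    for p, t in zip(predicted, truth):
        C[pi[p], ti[t]] += 1
    rows, cols = linear_sum_assignment(-C)
    mapping = {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}
    agreement = C[rows, cols].sum() / predicted.size
    return mapping, float(agreement)
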