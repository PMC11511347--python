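"""K-means feature selection over Raman shifts.

Raman shifts are clustered by their standardized-intensity profiles across
the training spectra: each shift becomes a point in R^(n_train), k-means
partitions the shifts, the cluster count is chosen by the elbow of the
within-cluster sum-of-squares (WCSS) curve, and the least class-informative
cluster(s) — shifts whose group-mean intensities barely vary between mixing
groups, i.e. band-free noise regions — are removed.  The mask is always
fitted on training spectra only and then applied unchanged to held-out data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectrumSet


@dataclasses.dataclass
class ClusterAssignment:
    """K-means result over shifts: 0-based labels, centroids, total WCSS."""

    k: int
    labels: np.ndarray  # (n_shifts,) cluster id per shift
    centroids: np.ndarray  # (k, n_train)
    wcss: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")
        if self.wcss < -1e-9:
            raise ValueError("wcss must be non-negative")


@dataclasses.dataclass
class FeatureMask:
    """Retained-shift index set derived from a cluster assignment."""

    selected_idx: np.ndarray  # ascending indices into the fitted grid
    dropped_clusters: tuple[int, ...]
    assignment: ClusterAssignment
    shifts: np.ndarray  # the grid the mask was fitted on

    def __post_init__(self) -> None:
        self.selected_idx = np.asarray(self.selected_idx, int)
        self.shifts = np.asarray(self.shifts, float)
        if self.selected_idx.size == 0:
            raise ValueError("feature mask retains no shifts")

    @property
    def selected_shifts(self) -> np.ndarray:
        """Retained Raman shifts in cm^-1."""
        return self.shifts[self.selected_idx]

    def support(self) -> np.ndarray:
        mask = np.zeros(self.shifts.size, dtype=bool)
        mask[self.selected_idx] = True
        return mask

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.assignment.k,
            "labels": self.assignment.labels.tolist(),
            "wcss": self.assignment.wcss,
            "dropped_clusters": list(self.dropped_clusters),
            "selected_idx": self.selected_idx.tolist(),
            "shifts": self.shifts.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        d = json.loads(Path(path).read_text())
        labels = np.asarray(d["labels"], int)
        k = int(d["k"])
        # centroids are not serialized; rebuild a placeholder with correct k
        assignment = ClusterAssignment(
            k=k,
            labels=labels,
            centroids=np.zeros((k, 0)),
            wcss=float(d["wcss"]),
        )
        return cls(
            selected_idx=np.asarray(d["selected_idx"], int),
            dropped_clusters=tuple(d["dropped_clusters"]),
            assignment=assignment,
            shifts=np.asarray(d["shifts"], float),
        )


def build_shift_matrix(X_train: np.ndarray) -> np.ndarray:
    """Per-shift feature matrix: row j = intensities of shift j across spectra."""
    X_train = np.atleast_2d(np.asarray(X_train, float))
    if X_train.shape[0] == 0:
        raise ValueError("cannot build a shift matrix from an empty training set")
    return X_train.T.copy()


def kmeans_shifts(
    matrix: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts."""
    matrix = np.atleast_2d(np.asarray(matrix, float))
    if not 1 <= k <= matrix.shape[0]:
        raise ValueError(f"k={k} must be in [1, {matrix.shape[0]}] for {matrix.shape[0]} shifts")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix)
    centroids = km.cluster_centers_
    # duplicate rows can collapse centroids, leaving empty clusters; compact
    # the labelling so every reported cluster is non-empty
    occupied = np.unique(labels)
    if occupied.size < k:
        remap = {old: new for new, old in enumerate(occupied)}
        labels = np.array([remap[l] for l in labels])
        centroids = centroids[occupied]
        k = occupied.size
    return ClusterAssignment(
        k=k, labels=labels, centroids=centroids, wcss=float(km.inertia_)
    )


def elbow_select_k(
    matrix: np.ndarray,
    k_max: int = 10,
    seed: int | None = 0,
    n_init: int = 10,
) -> tuple[int, np.ndarray]:
    """Elbow-method cluster count: the knee of the WCSS curve over k=1..k_max.

    Both axes are normalized to [0, 1]; k* maximizes the perpendicular
    distance from (k, wcss(k)) to the chord joining the curve's endpoints.
    Ties (e.g. an exactly linear curve) resolve to the smallest k.
    """
    matrix = np.atleast_2d(np.asarray(matrix, float))
    if k_max < 2:
        raise ValueError("k_max must be >= 2 for an elbow sweep")
    if k_max > matrix.shape[0]:
        raise ValueError(f"k_max={k_max} exceeds the number of shifts ({matrix.shape[0]})")
    ks = np.arange(1, k_max + 1)
    wcss = np.array([kmeans_shifts(matrix, k, seed=seed, n_init=n_init).wcss for k in ks])

    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = wcss[0] - wcss[-1]
    if abs(span) < np.finfo(float).tiny:
        return int(ks[0]), wcss
    y = (wcss - wcss[-1]) / span
    # chord from (x0, y0) to (x1, y1); distance of each point to it
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * x - dx * y + x[-1] * y[0] - y[-1] * x[0]) / np.hypot(dx, dy)
    k_star = int(ks[int(np.argmax(dist))])  # argmax returns first max -> smallest k on ties
    return k_star, wcss


def between_group_shift_scores(X_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Per-shift between-group variance of group-mean intensities.

    High values mark shifts whose average intensity depends on the mixing
    group (characteristic bands); values near zero mark noise regions.
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    y_train = np.asarray(y_train)
    groups = np.unique(y_train)
    if groups.size < 2:
        raise ValueError("between-group variance needs at least 2 groups")
    means = np.vstack([X_train[y_train == g].mean(axis=0) for g in groups])
    return means.var(axis=0, ddof=1)


def identify_noise_clusters(
    assignment: ClusterAssignment,
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_drop: int = 1,
) -> tuple[int, ...]:
    """The ``n_drop`` least class-informative clusters.

    Each cluster is scored by the mean, over its shifts, of the
    between-group variance of group-mean intensities; the lowest-scoring
    clusters contain no characteristic bands and are judged noise.  Ties
    break toward the smaller cluster id.
    """
    if n_drop >= assignment.k:
        raise ValueError(f"n_drop={n_drop} must be < k={assignment.k}")
    if n_drop == 0:
        return ()
    shift_scores = between_group_shift_scores(X_train, y_train)
    cluster_scores = np.array(
        [shift_scores[assignment.labels == c].mean() for c in range(assignment.k)]
    )
    order = np.argsort(cluster_scores, kind="stable")
    return tuple(int(c) for c in order[:n_drop])


def select_features(
    X_train: np.ndarray,
    y_train: np.ndarray,
    shifts: np.ndarray,
    k_max: int = 10,
    n_drop: int = 1,
    seed: int | None = 0,
    n_init: int = 10,
    elbow_n_init: int = 10,
) -> FeatureMask:
    """Full selection chain: shift matrix -> elbow -> k-means -> drop noise."""
    matrix = build_shift_matrix(X_train)
    k_star, _ = elbow_select_k(matrix, k_max=k_max, seed=seed, n_init=elbow_n_init)
    assignment = kmeans_shifts(matrix, k_star, seed=seed, n_init=n_init)
    dropped = identify_noise_clusters(assignment, X_train, y_train, n_drop=n_drop)
    keep = ~np.isin(assignment.labels, dropped)
    return FeatureMask(
        selected_idx=np.nonzero(keep)[0],
        dropped_clusters=dropped,
        assignment=assignment,
        shifts=np.asarray(shifts, float),
    )


def apply_mask(sset: SpectrumSet, mask: FeatureMask) -> SpectrumSet:
    """Restrict a spectrum set to the mask's retained shifts.

    The set's grid must equal the grid the mask was fitted on; the mask is
    never refitted here, so the same mask serves train and test halves.
    """
    if sset.shifts.shape != mask.shifts.shape or not np.allclose(sset.shifts, mask.shifts):
        raise ValueError("spectrum set grid differs from the grid the mask was fitted on")
    return sset.select_shifts(mask.selected_idx)


class KMeansShiftSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn selector wrapping the k-means shift-clustering chain.

    ``fit(X, y)`` expects preprocessed training spectra (rows) and group
    labels; ``transform`` keeps the columns outside the dropped noise
    cluster(s).

    Parameters
    ----------
    k_max : elbow sweep upper bound.
    n_drop : number of lowest-scoring clusters to remove (0 disables).
    n_init, elbow_n_init : k-means restarts for the final fit and the sweep.
    random_state : seed for the k-means restarts.
    shifts : optional grid metadata, stored into the fitted mask.
    """

    def __init__(
        self,
        k_max: int = 10,
        n_drop: int = 1,
        n_init: int = 10,
        elbow_n_init: int = 10,
        random_state: int | None = 0,
        shifts=None,
    ):
        self.k_max = k_max
        self.n_drop = n_drop
        self.n_init = n_init
        self.elbow_n_init = elbow_n_init
        self.random_state = random_state
        self.shifts = shifts

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of spectra")
        shifts = (
            np.asarray(self.shifts, float)
            if self.shifts is not None
            else np.arange(X.shape[1], dtype=float)
        )
        if shifts.shape[0] != X.shape[1]:
            raise ValueError("shifts length must equal the number of features")
        self.mask_ = select_features(
            X,
            y,
            shifts,
            k_max=self.k_max,
            n_drop=self.n_drop,
            seed=self.random_state,
            n_init=self.n_init,
            elbow_n_init=self.elbow_n_init,
        )
        self.k_ = self.mask_.assignment.k
        self.labels_ = self.mask_.assignment.labels
        self.dropped_clusters_ = self.mask_.dropped_clusters
        self.selected_idx_ = self.mask_.selected_idx
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "mask_")
        return self.mask_.support()
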