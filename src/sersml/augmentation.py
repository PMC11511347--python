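"""Training-data augmentation: group-conditional noise injection and SMOTE.

Two independent augmentations, both fitted on (and sampling from) the
training half only:

* **Noise injection** — for group i and shift j, the per-shift sample
  standard deviation s_ij of the group's training spectra defines additive
  noise n_ij = s_ij * N(0, 1); each training spectrum spawns
  ``noise_factor`` noisy copies that inherit its labels.

* **SMOTE** — per group, synthetic points are drawn by picking a random
  member x, one of its k nearest same-group neighbours z (Euclidean), and
  emitting x + u (z - x) with u ~ U(0, 1).  Implemented natively because the
  balanced, fixed-count setting here (equal group sizes, an exact number of
  synthetics per group) is outside the imbalance-oriented API of the usual
  libraries.

With the study defaults — 70 training spectra, noise_factor 40, 100 SMOTE
points for each of the 7 groups — the training pool is
70 + 2800 + 700 = 3570 points.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectrumSet


@dataclasses.dataclass
class AugmentationConfig:
    noise_factor: int = 40
    smote_per_class: int = 100
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_factor < 0 or self.smote_per_class < 0:
            raise ValueError("augmentation counts must be non-negative")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclasses.dataclass
class GroupNoiseModel:
    """Per-group, per-shift standard deviations s_ij."""

    groups: np.ndarray  # (g,) group ids, ascending
    s: np.ndarray  # (g, n_shifts), s[i] for groups[i]

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.s = np.atleast_2d(np.asarray(self.s, float))
        if self.s.shape[0] != self.groups.shape[0]:
            raise ValueError("one sd row per group required")
        if (self.s < 0).any():
            raise ValueError("standard deviations must be non-negative")

    def row(self, group) -> np.ndarray:
        idx = np.nonzero(self.groups == group)[0]
        if idx.size == 0:
            raise KeyError(f"group {group} not covered by the noise model")
        return self.s[idx[0]]


def estimate_group_noise(X: np.ndarray, y: np.ndarray) -> GroupNoiseModel:
    """Sample sd (n-1 denominator) of each group's spectra at every shift."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    groups = np.unique(y)
    rows = []
    for g in groups:
        block = X[y == g]
        if block.shape[0] < 2:
            raise ValueError(f"group {g} has {block.shape[0]} spectrum; need >= 2 to estimate sd")
        rows.append(block.std(axis=0, ddof=1))
    return GroupNoiseModel(groups=groups, s=np.vstack(rows))


def augment_noise(
    X: np.ndarray,
    y: np.ndarray,
    model: GroupNoiseModel,
    noise_factor: int = 40,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """``noise_factor`` noisy copies of every training spectrum.

    Returns (X_syn, y_syn, source_index); each copy adds fresh per-shift
    noise s_ij * N(0,1) for its source's group and inherits its labels.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    for g in np.unique(y):
        model.row(g)  # raises if a group is missing
    out_X, out_y, out_src = [], [], []
    for i in range(X.shape[0]):
        s = model.row(y[i])
        for _ in range(noise_factor):
            out_X.append(X[i] + s * rng.standard_normal(X.shape[1]))
            out_y.append(y[i])
            out_src.append(i)
    if not out_X:
        return np.empty((0, X.shape[1])), np.empty((0,), dtype=y.dtype), np.empty((0,), int)
    return np.vstack(out_X), np.asarray(out_y), np.asarray(out_src, int)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    per_class: int = 100,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exactly ``per_class`` SMOTE synthetics for every group.

    Neighbour ties resolve to the lower index (stable sort); returns
    (X_syn, y_syn, source_pairs) with source_pairs[(n, 2)] holding the
    row indices of x and its chosen neighbour z.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    out_X, out_y, pairs = [], [], []
    for g in np.unique(y):
        idx = np.nonzero(y == g)[0]
        if idx.size < 2:
            raise ValueError(f"group {g} has fewer than 2 members; SMOTE needs neighbours")
        if k_neighbors > idx.size - 1:
            raise ValueError(
                f"group {g}: smote_k={k_neighbors} exceeds available neighbours ({idx.size - 1})"
            )
        block = X[idx]
        dists = cdist(block, block)
        np.fill_diagonal(dists, np.inf)
        neighbour_order = np.argsort(dists, axis=1, kind="stable")[:, :k_neighbors]
        for _ in range(per_class):
            a = int(rng.integers(idx.size))
            z = int(neighbour_order[a, int(rng.integers(k_neighbors))])
            u = float(rng.uniform())
            out_X.append(block[a] + u * (block[z] - block[a]))
            out_y.append(g)
            pairs.append((idx[a], idx[z]))
    if not out_X:
        return np.empty((0, X.shape[1])), np.empty((0,), dtype=y.dtype), np.empty((0, 2), int)
    return np.vstack(out_X), np.asarray(out_y), np.asarray(pairs, int)


def build_training_pool(
    train: SpectrumSet, config: AugmentationConfig | None = None
) -> SpectrumSet:
    """Originals + noise synthetics + SMOTE synthetics as one labelled set.

    SMOTE interpolates between the *original* training points, independent
    of the noise augmentation.  Synthetic rows carry ``origin`` tags
    (``noise`` / ``smote``) and the ids of their source spectra.
    """
    config = config or AugmentationConfig()
    rng = np.random.default_rng(config.seed)
    X, y = train.intensities, train.y
    ids = train.labels["spectrum_id"].to_numpy()
    ratio_cols = train.labels[["ratio_amp", "ratio_adp", "ratio_atp"]].to_numpy()

    parts = [train]
    if config.noise_factor > 0:
        model = estimate_group_noise(X, y)
        Xn, _, src = augment_noise(X, y, model, config.noise_factor, rng)
        labels = _synthetic_labels(train, ratio_cols[src], src, ids, "noise", Xn.shape[0])
        parts.append(SpectrumSet(
            shifts=train.shifts.copy(), intensities=Xn, labels=labels, meta=dict(train.meta)
        ))
    if config.smote_per_class > 0:
        Xs, ys, pairs = smote(X, y, config.smote_per_class, config.smote_k, rng)
        # a SMOTE point inherits its group's ratio pattern (both parents share it)
        labels = _synthetic_labels(
            train, ratio_cols[pairs[:, 0]], pairs[:, 0], ids, "smote", Xs.shape[0],
            second_source=ids[pairs[:, 1]],
        )
        parts.append(SpectrumSet(
            shifts=train.shifts.copy(), intensities=Xs, labels=labels, meta=dict(train.meta)
        ))
    return SpectrumSet.concat(parts)


def _synthetic_labels(
    train: SpectrumSet,
    ratios: np.ndarray,
    source_rows: np.ndarray,
    ids: np.ndarray,
    tag: str,
    n: int,
    second_source: np.ndarray | None = None,
) -> pd.DataFrame:
    from .dataset import make_labels

    new_ids = [f"{tag}_{i}" for i in range(n)]
    sources = ids[source_rows]
    if second_source is not None:
        sources = [f"{a}+{b}" for a, b in zip(sources, second_source)]
    return make_labels(new_ids, ratios, origin=tag, source_ids=list(sources))


class GroupNoiseAugmenter(BaseEstimator):
    """Estimator wrapper for the group-conditional noise augmentation.

    ``fit(X, y)`` estimates the per-group noise model from training data;
    ``fit_resample(X, y)`` returns originals followed by the noisy copies.
    """

    def __init__(self, noise_factor: int = 40, random_state: int | None = 0):
        self.noise_factor = noise_factor
        self.random_state = random_state

    def fit(self, X, y):
        self.noise_model_ = estimate_group_noise(X, y)
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def fit_resample(self, X, y):
        self.fit(X, y)
        Xn, yn, _ = augment_noise(
            X, y, self.noise_model_, self.noise_factor, self.random_state
        )
        return np.vstack([X, Xn]), np.concatenate([np.asarray(y), yn])


class GroupSMOTE(BaseEstimator):
    """Estimator wrapper for the fixed-count, per-group SMOTE."""

    def __init__(self, per_class: int = 100, k_neighbors: int = 5, random_state: int | None = 0):
        self.per_class = per_class
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        check = np.atleast_2d(np.asarray(X))
        self.n_features_in_ = check.shape[1]
        Xs, ys, _ = smote(X, y, self.per_class, self.k_neighbors, self.random_state)
        return np.vstack([X, Xs]), np.concatenate([np.asarray(y), ys])
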