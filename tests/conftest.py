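import itertools

import numpy as np
import pytest

from sersml import SyntheticConfig, generate_dataset, preprocess_set


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Reduced-size generator config for fast unit tests: coarser grid,
    fewer replicates, otherwise the default band structure."""
    kwargs = dict(grid_step=5.0, replicates_per_ratio=4, seed=seed)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-scale dataset: 7 groups x 20 replicates, 1 cm^-1 grid."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=0))


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return preprocess_set(small_dataset)


def brute_force_kmeans(matrix: np.ndarray, k: int):
    """Exhaustive minimum-WCSS partition into exactly k non-empty clusters.

    Independent oracle for k-means on tiny instances: enumerates every
    assignment, returns (labels, wcss) of the global optimum.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    best_labels, best_wcss = None, np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        labels = np.asarray(assign)
        wcss = 0.0
        for c in range(k):
            pts = matrix[labels == c]
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wcss < best_wcss - 1e-12:
            best_wcss, best_labels = wcss, labels
    return best_labels, best_wcss


def canonical_partition(labels: np.ndarray) -> tuple:
    """Relabel clusters by first occurrence so partitions compare directly."""
    mapping: dict = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def banded_shift_matrix(seed: int, n_reps: int = 4, noise: float = 0.05) -> np.ndarray:
    """Shift matrix with three disjoint rectangular band regions plus noise.

    Band regions respond to the AMP/ADP/ATP fraction of each of the 7
    mixture groups respectively; everything else is band-free noise, so the
    shifts fall into exactly four profile classes (three band clusters and
    one noise cluster).
    """
    rng = np.random.default_rng(seed)
    shifts = np.arange(200.0, 1701.0, 5.0)
    fractions = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0.5, 0.5, 0],
            [0.5, 0, 0.5],
            [0, 0.5, 0.5],
            [1 / 3, 1 / 3, 1 / 3],
        ]
    )
    regions = [(300, 400), (700, 800), (1200, 1300)]
    rows = []
    for g in range(7):
        for _ in range(n_reps):
            y = np.zeros_like(shifts)
            for comp, (lo, hi) in enumerate(regions):
                y[(shifts >= lo) & (shifts <= hi)] = fractions[g, comp]
            y += rng.normal(0.0, noise, shifts.shape)
            rows.append(y)
    return np.array(rows).T
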