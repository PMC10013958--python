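"""Synthetic minority oversampling (SMOTE) for the colocalization task.

New minority samples are interpolated between a minority point and one of
its k nearest minority neighbours, raising the minority count to the
majority count (e.g. 85 weak-colocalization probes oversampled to match 811
good ones).  Distances are Euclidean on the feature matrix as given; for
binary fingerprints this is the square root of the Hamming distance.
Synthetic fingerprint bits are left fractional by default (classifier
friendly); ``round_bits=True`` snaps them back to hard bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .featurize import FeatureMatrix


class OversampleError(ValueError):
    pass


@dataclass
class OversampleResult:
    X_out: np.ndarray
    y_out: np.ndarray
    synthetic_index: list
    parent_pairs: list  # [(minority_row, neighbor_row)] in X_out coordinates
    seed: int
    k: int
    minority_label: object = None


def smote(
    X,
    y,
    k: int = 5,
    seed: int = 0,
    round_bits: bool = False,
) -> OversampleResult:
    """Oversample the minority class of a binary task to parity.

    For each synthetic sample a minority point ``x`` and one of its ``k``
    nearest minority neighbours ``x'`` (Euclidean, self excluded) are drawn,
    and ``x + u * (x' - x)`` emitted with ``u ~ Uniform[0, 1]``.  Majority
    rows are untouched; output is reproducible for a fixed seed.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise OversampleError("empty feature matrix")
    if X.shape[0] != y.shape[0]:
        raise OversampleError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise OversampleError("SMOTE needs two classes")
    if len(classes) > 2:
        raise OversampleError("SMOTE here is binary-only")
    if k < 1:
        raise OversampleError("k must be positive")

    order = np.argsort(counts)
    minority, majority = classes[order[0]], classes[order[1]]
    n_min, n_maj = counts[order[0]], counts[order[1]]
    n_needed = int(n_maj - n_min)
    if n_needed == 0:
        return OversampleResult(X.copy(), y.copy(), [], [], seed, k, minority)

    min_idx = np.flatnonzero(y == minority)
    if n_min <= k:
        warnings.warn(
            f"minority count {n_min} <= k={k}; reducing k to {n_min - 1}",
            stacklevel=2,
        )
        k = int(n_min) - 1
        if k < 1:
            raise OversampleError("minority class too small for interpolation")

    Xmin = X[min_idx]
    dist = cdist(Xmin, Xmin)
    np.fill_diagonal(dist, np.inf)
    # stable k-NN: ties broken by row index
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.random(n_needed)

    parents = nn[base, pick]
    synth = Xmin[base] + u[:, None] * (Xmin[parents] - Xmin[base])
    if round_bits:
        synth = np.rint(synth)

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    n = X.shape[0]
    synthetic_index = list(range(n, n + n_needed))
    parent_pairs = [
        (int(min_idx[b]), int(min_idx[p])) for b, p in zip(base, parents)
    ]
    return OversampleResult(X_out, y_out, synthetic_index, parent_pairs, seed, k, minority)
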