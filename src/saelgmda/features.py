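"""Per-pair feature construction.

Every (microbe, disease) pair becomes one record whose feature vector is the
concatenation of the microbe's full similarity row (length ``n_m``) and the
disease's full similarity row (length ``n_d``).  Records are enumerated
microbe-major, disease-minor, so record ``j * n_d + i`` is pair
(microbe ``j``, disease ``i``).  Labels are the association matrix entries:
a pair with no recorded association is unlabeled, and is treated as a
negative instance by the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix

__all__ = ["PairFeatureTable", "build_pair_features", "positive_unlabeled_split"]


@dataclass(frozen=True)
class PairFeatureTable:
    """Feature table over all n_d * n_m pairs.

    ``features`` has shape (n, n_m + n_d); ``pairs[k] = (microbe_index,
    disease_index)``; ``labels[k]`` mirrors the association matrix.
    """

    features: np.ndarray
    labels: np.ndarray
    pairs: np.ndarray
    n_diseases: int
    n_microbes: int

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


def build_pair_features(
    S_D: np.ndarray,
    S_M: np.ndarray,
    X: AssociationMatrix,
) -> PairFeatureTable:
    """Concatenate similarity rows into one record per (microbe, disease) pair."""
    S_D = np.asarray(S_D, dtype=float)
    S_M = np.asarray(S_M, dtype=float)
    n_d, n_m = X.n_diseases, X.n_microbes
    if S_D.shape != (n_d, n_d):
        raise ValueError(
            f"disease similarity shape {S_D.shape} does not match "
            f"{n_d} diseases in the association matrix"
        )
    if S_M.shape != (n_m, n_m):
        raise ValueError(
            f"microbe similarity shape {S_M.shape} does not match "
            f"{n_m} microbes in the association matrix"
        )
    # microbe-major enumeration: record j*n_d + i <-> (microbe j, disease i)
    m_idx = np.repeat(np.arange(n_m), n_d)
    d_idx = np.tile(np.arange(n_d), n_m)
    features = np.concatenate([S_M[m_idx], S_D[d_idx]], axis=1)
    labels = X.values[d_idx, m_idx].astype(np.int8)
    pairs = np.column_stack([m_idx, d_idx])
    return PairFeatureTable(features, labels, pairs, n_d, n_m)


def positive_unlabeled_split(table: PairFeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Return (positive record indices, unlabeled record indices)."""
    positives = np.flatnonzero(table.labels == 1)
    unlabeled = np.flatnonzero(table.labels == 0)
    return positives, unlabeled
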