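"""Candidate ranking: top microbes for a query disease, top novel pairs overall.

Given association scores for every (microbe, disease) pair, produce the
case-study style outputs: an ordered candidate-microbe list for one disease
(optionally excluding its already-known associations) and a global top-k list
over all pairs.  A pair's global rank is 1 plus the number of pairs with a
strictly greater score; ties are broken lexicographically by identifier so
output is deterministic across runs and platforms.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix

__all__ = ["RankedList", "rank_microbes_for_disease", "global_top_associations"]


@dataclass(frozen=True)
class RankedList:
    """Ordered candidates with scores, contiguous ranks and known flags."""

    query: str | None
    entries: tuple  # of (rank, identifier-or-pair, score, known_flag)

    def __len__(self) -> int:
        return len(self.entries)


def _score_matrix(scores: np.ndarray, pairs: np.ndarray, X: AssociationMatrix):
    """Scatter record scores into an (n_d, n_m) matrix."""
    S = np.full((X.n_diseases, X.n_microbes), np.nan)
    S[pairs[:, 1], pairs[:, 0]] = scores
    if np.isnan(S).any():
        raise ValueError("scores do not cover every (disease, microbe) pair")
    return S


def rank_microbes_for_disease(
    disease_id: str,
    scores: np.ndarray,
    pairs: np.ndarray,
    X: AssociationMatrix,
    exclude_known: bool = True,
    top: int | None = None,
) -> RankedList:
    """Rank candidate microbes for one disease by association score.

    ``scores``/``pairs`` are record-aligned as produced by the classifier
    (pairs columns: microbe_index, disease_index).  Known associations of the
    query disease are removed when ``exclude_known`` is set.
    """
    if disease_id not in X.disease_ids:
        near = difflib.get_close_matches(disease_id, X.disease_ids, n=3)
        hint = f"; similar known diseases: {near}" if near else ""
        raise KeyError(f"unknown disease {disease_id!r}{hint}")
    d = X.disease_index(disease_id)
    S = _score_matrix(np.asarray(scores, float), np.asarray(pairs, int), X)
    row = S[d]
    known = X.values[d].astype(bool)
    candidates = [
        (X.microbe_ids[j], float(row[j]), bool(known[j]))
        for j in range(X.n_microbes)
        if not (exclude_known and known[j])
    ]
    candidates.sort(key=lambda c: (-c[1], c[0]))
    if top is not None:
        candidates = candidates[:top]
    entries = tuple(
        (rank, mid, score, flag)
        for rank, (mid, score, flag) in enumerate(candidates, start=1)
    )
    return RankedList(query=disease_id, entries=entries)


def global_top_associations(
    scores: np.ndarray,
    pairs: np.ndarray,
    X: AssociationMatrix,
    k: int,
) -> RankedList:
    """Top-k (disease, microbe) pairs by score over the whole candidate universe.

    The reported rank of a pair is 1 + the number of pairs with a strictly
    greater score, so tied pairs share a rank.
    """
    scores = np.asarray(scores, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    n = len(scores)
    if k > n:
        raise ValueError(f"k={k} exceeds the candidate universe size {n}")
    records = [
        (
            X.disease_ids[d],
            X.microbe_ids[m],
            float(scores[i]),
            bool(X.values[d, m]),
        )
        for i, (m, d) in enumerate(pairs)
    ]
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    # rank by strict-majority count; computed from the sorted score sequence
    sorted_scores = np.array([r[2] for r in records])
    ranks = np.searchsorted(-sorted_scores, -sorted_scores, side="left") + 1
    entries = tuple(
        (int(ranks[i]), (rec[0], rec[1]), rec[2], rec[3])
        for i, rec in enumerate(records[:k])
    )
    return RankedList(query=None, entries=entries)
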