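"""Disease and microbe similarity matrices.

Two complementary similarity notions feed the pair features:

* **Functional similarity** between diseases, computed from disease-associated
  gene sets over a gene functional-linkage network.  Each gene's contribution
  is its best match into the other disease's gene set (1 for a shared gene,
  the min-max-normalised log-likelihood score otherwise), averaged over both
  directions.
* **Gaussian interaction profile kernel (GIPK) similarity**, an RBF kernel on
  an entity's binary association profile (matrix row for a disease, column
  for a microbe), with the bandwidth normalised by the mean squared profile
  norm so that the kernel adapts to overall network density.

The two are fused by averaging where functional similarity is defined
(non-zero) and falling back to the kernel similarity otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix, GeneNetwork

__all__ = [
    "GipkConfig",
    "normalize_lls",
    "gene_to_set_score",
    "disease_functional_similarity",
    "gipk_similarity",
    "fuse_similarity",
]


@dataclass(frozen=True)
class GipkConfig:
    """Raw (pre-normalisation) kernel bandwidth; 1.0 by convention."""

    raw_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.raw_bandwidth) and self.raw_bandwidth > 0):
            raise ValueError("raw_bandwidth must be finite and positive")


def normalize_lls(net: GeneNetwork) -> GeneNetwork:
    """Min-max normalise all log-likelihood scores to [0, 1]."""
    lo, hi = net.score_range()
    if hi == lo:
        raise ValueError("degenerate score range: all LLS scores are equal")
    return net.map_scores(lambda s: (s - lo) / (hi - lo))


def gene_to_set_score(gene: str, gene_set, net: GeneNetwork) -> float:
    """Best-match score of ``gene`` into ``gene_set``.

    A shared gene scores 1; otherwise the maximum normalised linkage score of
    ``gene`` to any member, with 0 for pairs absent from the network.
    """
    if not gene_set:
        raise ValueError("gene set must be nonempty")
    best = 0.0
    for other in gene_set:
        s = 1.0 if other == gene else net.score(gene, other, default=0.0)
        if s > best:
            best = s
    return best


def disease_functional_similarity(
    disease_gene_map: dict[str, set],
    net: GeneNetwork,
    disease_ids,
) -> np.ndarray:
    """Symmetric best-match gene-set similarity matrix over ``disease_ids``.

    For diseases with gene sets G_i (|G_i| = a) and G_j (|G_j| = b), the
    similarity is the two-directional best-match sum divided by a + b.  If
    either gene set is empty the similarity is 0 (no functional evidence).
    """
    disease_ids = list(disease_ids)
    n = len(disease_ids)
    sets = [frozenset(disease_gene_map.get(d, ())) for d in disease_ids]
    # cache per-(gene, set) best-match scores: sets repeat across pairs
    cache: dict[tuple[str, frozenset], float] = {}

    def fg(gene: str, gs: frozenset) -> float:
        key = (gene, gs)
        if key not in cache:
            cache[key] = gene_to_set_score(gene, gs, net)
        return cache[key]

    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            gi, gj = sets[i], sets[j]
            if not gi or not gj:
                continue
            total = sum(fg(g, gj) for g in gi) + sum(fg(g, gi) for g in gj)
            D[i, j] = D[j, i] = total / (len(gi) + len(gj))
    return D


def gipk_similarity(
    X: AssociationMatrix,
    axis: str,
    cfg: GipkConfig = GipkConfig(),
) -> np.ndarray:
    """Gaussian interaction profile kernel similarity along one axis.

    ``axis='disease'`` uses rows of the association matrix as profiles,
    ``axis='microbe'`` uses columns.  The effective bandwidth is
    ``raw_bandwidth / mean(||profile||^2)``.
    """
    if axis == "disease":
        profiles = X.values.astype(float)
    elif axis == "microbe":
        profiles = X.values.T.astype(float)
    else:
        raise ValueError(f"axis must be 'disease' or 'microbe', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("empty interaction profiles: association matrix is all-zero")
    gamma = cfg.raw_bandwidth / mean_sq
    # ||p_i - p_j||^2 via the Gram expansion
    gram = profiles @ profiles.T
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(sq_dist, 0.0, out=sq_dist)
    S = np.exp(-gamma * sq_dist)
    np.fill_diagonal(S, 1.0)
    return S


def fuse_similarity(
    functional: np.ndarray,
    gipk: np.ndarray,
    mode: str = "gipk_fallback",
) -> np.ndarray:
    """Fuse functional and kernel similarity matrices.

    Where the functional entry is non-zero the fused value is the mean of the
    two.  Where it is zero, ``mode='gipk_fallback'`` (default) uses the kernel
    value — the functional similarity being zero means no gene evidence, not
    dissimilarity — while ``mode='paper_literal'`` keeps the zero.
    """
    functional = np.asarray(functional, dtype=float)
    gipk = np.asarray(gipk, dtype=float)
    if functional.shape != gipk.shape:
        raise ValueError(
            f"shape mismatch: functional {functional.shape} vs gipk {gipk.shape}"
        )
    if mode not in ("gipk_fallback", "paper_literal"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    fused = 0.5 * (functional + gipk)
    if mode == "gipk_fallback":
        fused = np.where(functional != 0, fused, gipk)
    else:
        fused = np.where(functional != 0, fused, 0.0)
    return fused
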