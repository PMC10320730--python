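"""Synthetic microbe-disease data with planted block structure.

The generator emulates the scale and the structural assumption the whole
method rests on: similar diseases associate with similar microbes.  Diseases
and microbes are partitioned into co-association blocks; within-block pairs
associate with a high probability and background pairs with a low one, which
plants a recoverable bipartite community signal.  Disease gene sets overlap
within a block and gene pairs within a block's pool receive high-mean
log-likelihood scores, so the functional-similarity channel carries the same
block signal as the association matrix.

Defaults mirror a small curated association database: 39 diseases x 292
microbes with an expected ~450 positive associations (~4% density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix, GeneNetwork

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "fixture_truth_auc_bound",
           "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    n_diseases: int = 39
    n_microbes: int = 292
    n_blocks: int = 13
    within_block_density: float = 0.48
    background_density: float = 0.003
    genes_per_disease: int = 10
    gene_overlap_within_block: float = 0.5
    block_pool_genes: int = 30
    lls_signal_mean: float = 3.0
    lls_noise_mean: float = 0.5
    lls_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.within_block_density <= 1):
            raise ValueError("within_block_density must lie in (0, 1]")
        if not (0 <= self.background_density < 1):
            raise ValueError("background_density must lie in [0, 1)")
        if self.within_block_density <= self.background_density:
            raise ValueError(
                "within_block_density must exceed background_density "
                "(otherwise no planted signal)"
            )
        if not (0 <= self.gene_overlap_within_block <= 1):
            raise ValueError("gene_overlap_within_block must lie in [0, 1]")
        if min(self.n_diseases, self.n_microbes) < self.n_blocks:
            raise ValueError("need at least one disease and microbe per block")

    def expected_positives(self) -> float:
        """Expected number of planted associations under the block model."""
        d_sizes = _block_sizes(self.n_diseases, self.n_blocks)
        m_sizes = _block_sizes(self.n_microbes, self.n_blocks)
        within = sum(a * b for a, b in zip(d_sizes, m_sizes))
        total = self.n_diseases * self.n_microbes
        return (
            within * self.within_block_density
            + (total - within) * self.background_density
        )


@dataclass(frozen=True)
class Fixture:
    X: AssociationMatrix
    disease_gene_map: dict
    gene_network: GeneNetwork
    disease_blocks: np.ndarray
    microbe_blocks: np.ndarray


def _block_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _block_labels(n: int, k: int) -> np.ndarray:
    return np.repeat(np.arange(k), _block_sizes(n, k))


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Generate an association matrix, gene map and gene network with planted blocks.

    Fully seeded: the same spec yields a bitwise-identical fixture.
    """
    rng = np.random.default_rng(spec.seed)
    n_d, n_m, k = spec.n_diseases, spec.n_microbes, spec.n_blocks
    d_blocks = _block_labels(n_d, k)
    m_blocks = _block_labels(n_m, k)
    same_block = d_blocks[:, None] == m_blocks[None, :]
    prob = np.where(same_block, spec.within_block_density, spec.background_density)
    values = (rng.random((n_d, n_m)) < prob).astype(np.int8)
    disease_ids = tuple(f"d{i:03d}" for i in range(n_d))
    microbe_ids = tuple(f"m{j:04d}" for j in range(n_m))
    X = AssociationMatrix(values, disease_ids, microbe_ids)

    # per-block gene pool; every disease in a block carries the pool's shared
    # core (the overlap fraction of its genes) plus disease-private genes
    gene_map: dict[str, set] = {}
    pools = [
        [f"g_b{b}_{t}" for t in range(spec.block_pool_genes)] for b in range(k)
    ]
    n_shared = int(round(spec.gene_overlap_within_block * spec.genes_per_disease))
    for i, d in enumerate(disease_ids):
        b = d_blocks[i]
        shared = pools[b][: min(n_shared, len(pools[b]))]
        private = [f"g_{d}_{t}" for t in range(spec.genes_per_disease - len(shared))]
        gene_map[d] = set(shared) | set(private)

    net = GeneNetwork()
    # within-block pool pairs: high-mean scores; cross-block pool pairs: low-mean
    for b in range(k):
        pool = pools[b]
        for a_i in range(len(pool)):
            for b_i in range(a_i + 1, len(pool)):
                net.set_score(
                    pool[a_i], pool[b_i],
                    rng.normal(spec.lls_signal_mean, spec.lls_sd),
                )
    all_pool = [g for p in pools for g in p]
    n_cross = 4 * len(all_pool)
    for _ in range(n_cross):
        g1, g2 = rng.choice(all_pool, size=2, replace=False)
        if not net.has_edge(g1, g2):
            net.set_score(g1, g2, rng.normal(spec.lls_noise_mean, spec.lls_sd))
    return Fixture(X, gene_map, net, d_blocks, m_blocks)


def fixture_truth_auc_bound(fixture: Fixture) -> float:
    """AUC of the block-membership oracle scorer against the realised matrix.

    Scores 1 for within-block pairs and 0 otherwise; an upper-bound reference
    for what any method exploiting the planted structure could achieve.
    """
    from sklearn.metrics import roc_auc_score

    same_block = (
        fixture.disease_blocks[:, None] == fixture.microbe_blocks[None, :]
    ).astype(float)
    labels = fixture.X.values.ravel()
    if np.unique(labels).size < 2:
        raise ValueError("degenerate fixture: single-class association matrix")
    return float(roc_auc_score(labels, same_block.ravel()))


def write_fixture(fixture: Fixture, out_dir) -> dict:
    """Write the fixture's three TSV inputs plus a ground-truth JSON.

    Returns the mapping of artifact names to paths.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mda": out / "mda_edges.tsv",
        "disease_genes": out / "disease_genes.tsv",
        "gene_net": out / "gene_network.tsv",
        "truth": out / "truth.json",
    }
    X = fixture.X
    with open(paths["mda"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tmicrobe_id\n")
        for i, j in zip(*np.nonzero(X.values)):
            fh.write(f"{X.disease_ids[i]}\t{X.microbe_ids[j]}\n")
    with open(paths["disease_genes"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\n")
        for d in X.disease_ids:
            for g in sorted(fixture.disease_gene_map.get(d, ())):
                fh.write(f"{d}\t{g}\n")
    with open(paths["gene_net"], "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tlls_score\n")
        for g1, g2, s in sorted(fixture.gene_network.items()):
            fh.write(f"{g1}\t{g2}\t{s:.10g}\n")
    truth = {
        "disease_blocks": fixture.disease_blocks.tolist(),
        "microbe_blocks": fixture.microbe_blocks.tolist(),
        "n_associations": X.n_associations,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
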