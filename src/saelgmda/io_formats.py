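"""Readers, writers and core containers for microbe-disease association data.

The pipeline works from four plain-text inputs: a microbe-disease association
(MDA) edge list, a disease-to-gene table, a gene functional-linkage network
with log-likelihood scores (LLS), and an optional precomputed microbe
functional-similarity matrix.  Everything is TSV; matrices carry identifier
headers so that row/column indexing never leaks into files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "GeneNetwork",
    "load_association_edges",
    "load_disease_gene_map",
    "load_gene_network",
    "load_similarity_matrix",
    "write_similarity_matrix",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x microbe incidence matrix with identifier registries.

    ``values[i, j] == 1`` iff disease ``disease_ids[i]`` is associated with
    microbe ``microbe_ids[j]``.  Identifiers are deduplicated and sorted
    lexicographically so matrix coordinates are reproducible across runs.
    """

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        if v.shape != (len(self.disease_ids), len(self.microbe_ids)):
            raise ValueError("matrix shape does not match identifier registries")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if len(set(self.microbe_ids)) != len(self.microbe_ids):
            raise ValueError("duplicate microbe identifiers")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "microbe_ids", tuple(self.microbe_ids))

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_associations(self) -> int:
        """Number of distinct (disease, microbe) associations."""
        return int(self.values.sum())

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def microbe_index(self, microbe_id: str) -> int:
        return self.microbe_ids.index(microbe_id)


@dataclass
class GeneNetwork:
    """Undirected gene-gene functional linkage network with real-valued scores.

    Scores are HumanNet-style log-likelihood scores (LLS): unbounded reals
    where larger means stronger evidence of functional linkage.  A pair is
    stored once regardless of orientation.
    """

    _scores: dict[frozenset, float] = field(default_factory=dict)

    def set_score(self, g1: str, g2: str, score: float) -> None:
        score = float(score)
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for pair ({g1}, {g2})")
        self._scores[frozenset((g1, g2))] = score

    def score(self, g1: str, g2: str, default: float | None = None) -> float:
        """Symmetric score lookup; ``default`` returned when the pair is absent."""
        key = frozenset((g1, g2))
        if key in self._scores:
            return self._scores[key]
        if default is None:
            raise KeyError(f"no edge between {g1!r} and {g2!r}")
        return default

    def has_edge(self, g1: str, g2: str) -> bool:
        return frozenset((g1, g2)) in self._scores

    @property
    def n_edges(self) -> int:
        return len(self._scores)

    @property
    def gene_ids(self) -> set:
        ids: set = set()
        for key in self._scores:
            ids.update(key)
        return ids

    def score_range(self) -> tuple[float, float]:
        if not self._scores:
            raise ValueError("empty gene network has no score range")
        vals = list(self._scores.values())
        return min(vals), max(vals)

    def items(self):
        for key, score in self._scores.items():
            pair = tuple(sorted(key))
            # frozenset({g}) arises from a self-edge line; keep it symmetric
            g1, g2 = (pair[0], pair[0]) if len(pair) == 1 else pair
            yield g1, g2, score

    def map_scores(self, fn) -> "GeneNetwork":
        out = GeneNetwork()
        out._scores = {k: float(fn(v)) for k, v in self._scores.items()}
        return out


def load_association_edges(path) -> AssociationMatrix:
    """Load an MDA edge list (``disease_id<TAB>microbe_id``) into a matrix.

    Duplicate (disease, microbe) rows collapse to a single association.  A
    header line is detected by the literal string ``disease`` in the first
    field.  Extra columns are ignored.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and "disease" in fields[0].lower():
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"fields (disease_id, microbe_id), got {line!r}"
                )
            pairs.add((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValueError(f"{path}: no associations")
    disease_ids = tuple(sorted({d for d, _ in pairs}))
    microbe_ids = tuple(sorted({m for _, m in pairs}))
    d_index = {d: i for i, d in enumerate(disease_ids)}
    m_index = {m: j for j, m in enumerate(microbe_ids)}
    values = np.zeros((len(disease_ids), len(microbe_ids)), dtype=np.int8)
    for d, m in pairs:
        values[d_index[d], m_index[m]] = 1
    X = AssociationMatrix(values, disease_ids, microbe_ids)
    logger.info(
        "loaded %d unique associations between %d diseases and %d microbes",
        X.n_associations, X.n_diseases, X.n_microbes,
    )
    return X


def load_gene_network(path) -> GeneNetwork:
    """Load a gene network TSV (``gene1<TAB>gene2<TAB>lls_score``).

    On duplicate pairs (in either orientation) the last occurrence wins and a
    warning is emitted.
    """
    net = GeneNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower().startswith("gene"):
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 fields "
                    f"(gene1, gene2, score), got {line!r}"
                )
            g1, g2 = fields[0].strip(), fields[1].strip()
            try:
                score = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {fields[2]!r}"
                ) from None
            if net.has_edge(g1, g2):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate edge ({g1}, {g2}); "
                    "last occurrence wins",
                    stacklevel=2,
                )
            net.set_score(g1, g2, score)
    return net


def load_disease_gene_map(path) -> dict[str, set]:
    """Load a disease-to-gene TSV (``disease_id<TAB>gene_id``) into a mapping.

    Diseases absent from the file simply have no entry; callers treat a
    missing disease as an empty gene set.
    """
    mapping: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and "disease" in fields[0].lower():
                continue
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields "
                    f"(disease_id, gene_id), got {line!r}"
                )
            mapping.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return mapping


def write_similarity_matrix(values: np.ndarray, ids, path) -> None:
    """Write a square similarity matrix as TSV with identifier headers."""
    values = np.asarray(values, dtype=float)
    ids = list(ids)
    if values.shape != (len(ids), len(ids)):
        raise ValueError("matrix shape does not match identifier list")
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_similarity_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Load a similarity matrix TSV; validates squareness and symmetry.

    Returns ``(values, ids)``.  Asymmetry beyond 1e-9 is an error naming the
    worst entry.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    row_ids = tuple(str(r) for r in df.index)
    if df.shape[0] != df.shape[1] or ids != row_ids:
        raise ValueError(
            f"{path}: not a square matrix with matching row/column identifiers"
        )
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > 1e-9:
        i, j = worst
        raise ValueError(
            f"{path}: asymmetric beyond 1e-9: S[{ids[i]!r},{ids[j]!r}]="
            f"{values[i, j]!r} vs S[{ids[j]!r},{ids[i]!r}]={values[j, i]!r}"
        )
    return values, ids
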