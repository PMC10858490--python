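"""Pairwise phenotype similarity: Lin, restricted hierarchical Lin, cosine.

Lin similarity normalises the information content of the most informative
common ancestor by the ICs of the two terms:

    sim_lin(p1, p2) = 2 * IC(MICA) / (IC(p1) + IC(p2))

The restricted hierarchical variant sets the similarity to zero unless one
term subsumes the other (they lie on the same branch of the hierarchy):
ontological siblings such as chronic kidney disease and acute kidney injury
share an informative parent yet have distinct etiologies, and the
restriction prevents them from being treated as similar.  The embedding
method scores terms by the cosine of precomputed term vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ontology import OntologyGraph, TermStats

METHODS = ("binary", "lin", "restricted_lin", "embedding_cosine")


class CoverageError(KeyError):
    """A term required by the similarity model has no data."""


@dataclass(frozen=True)
class EmbeddingTable:
    """Term -> vector mapping, all vectors of one dimension ``dim``."""

    vectors: Mapping[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for term, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"embedding for {term!r} has shape {vec.shape}, expected ({self.dim},)"
                )
            if not np.any(vec):
                raise ValueError(f"zero vector for term {term!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __getitem__(self, term: str) -> np.ndarray:
        try:
            return self.vectors[term]
        except KeyError:
            raise CoverageError(f"no embedding for term {term!r}") from None


@dataclass(frozen=True)
class SimilarityModel:
    """A symmetric term-pair similarity bound to its supporting data.

    ``method`` selects the formula; ontology methods need ``graph`` and
    ``stats``, the cosine method needs ``embeddings``.  For every method
    ``sim(p, p) = 1`` on covered terms and ``sim`` is symmetric.
    """

    method: str
    graph: OntologyGraph | None = None
    stats: TermStats | None = None
    embeddings: EmbeddingTable | None = None
    _anc_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method in ("lin", "restricted_lin") and (
            self.graph is None or self.stats is None
        ):
            raise ValueError(f"method {self.method!r} requires graph and stats")
        if self.method == "embedding_cosine" and self.embeddings is None:
            raise ValueError("method 'embedding_cosine' requires embeddings")

    def _ancestors(self, term: str) -> set[str]:
        anc = self._anc_cache.get(term)
        if anc is None:
            anc = self.graph.ancestors(term, reflexive=True)
            self._anc_cache[term] = anc
        return anc

    def sim(self, p1: str, p2: str) -> float:
        """Similarity in [0, 1] (cosine negatives clipped to 0)."""
        if self.method == "binary":
            return 1.0 if p1 == p2 else 0.0
        if self.method == "lin":
            return lin_similarity(self, p1, p2)
        if self.method == "restricted_lin":
            return restricted_lin_similarity(self, p1, p2)
        return max(0.0, cosine_similarity(self, p1, p2))


def lin_similarity(model: SimilarityModel, p1: str, p2: str) -> float:
    """Lin similarity; 1 for identical terms (even at the IC-0 root)."""
    if p1 == p2:
        model._ancestors(p1)  # raises on unknown term
        return 1.0
    ic = model.stats.ic
    common = model._ancestors(p1) & model._ancestors(p2)
    mica_ic = max(ic[t] for t in common)
    denom = ic[p1] + ic[p2]
    if denom == 0.0:
        return 0.0
    return 2.0 * mica_ic / denom


def restricted_lin_similarity(model: SimilarityModel, p1: str, p2: str) -> float:
    """Lin similarity if one term reflexively subsumes the other, else 0."""
    if p1 == p2:
        model._ancestors(p1)
        return 1.0
    if p2 in model._ancestors(p1) or p1 in model._ancestors(p2):
        return lin_similarity(model, p1, p2)
    return 0.0


def cosine_similarity(model: SimilarityModel, p1: str, p2: str) -> float:
    """Raw cosine in [-1, 1] between the two term embeddings."""
    v1 = model.embeddings[p1]
    v2 = model.embeddings[p2]
    return float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))


def similarity_matrix(model: SimilarityModel, feature_terms: Sequence[str]) -> np.ndarray:
    """Symmetric matrix ``M[i, j] = sim(p_i, p_j)`` over an ordered term list.

    Raises :class:`CoverageError` listing every feature term the model does
    not cover.
    """
    n = len(feature_terms)
    if model.method == "binary":
        return np.eye(n)
    if model.method == "embedding_cosine":
        missing = [t for t in feature_terms if t not in model.embeddings]
        if missing:
            raise CoverageError(f"terms without embeddings: {missing}")
        vecs = np.stack([model.embeddings[t] for t in feature_terms])
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        m = (vecs / norms) @ (vecs / norms).T
        return np.clip(m, 0.0, 1.0)
    missing = [t for t in feature_terms if t not in model.graph]
    if missing:
        raise CoverageError(f"terms not in ontology: {missing}")
    m = np.empty((n, n))
    for i, p1 in enumerate(feature_terms):
        m[i, i] = 1.0
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = model.sim(p1, feature_terms[j])
    return m
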