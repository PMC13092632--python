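"""Text embedding providers and exact nearest-description retrieval.

Every downstream stage (abbreviation disambiguation, candidate
identification, context filtering, nesting minimization) consumes a single
semantic-similarity contract: map text to a unit vector and compare by
cosine.  Two provider families satisfy it:

* :class:`HashingEmbeddingProvider` — a deterministic, seedless character
  3-gram feature-hashing embedder.  It needs no model weights, is stable
  across processes and platforms, and is the default provider for offline
  runs and the whole test suite.
* :class:`NeuralEmbeddingProvider` — a thin adapter over a
  ``sentence-transformers`` model (e.g. a BioLORD-style biomedical
  similarity model for English, or a multilingual paraphrase model for
  German input).  Weights are never bundled; the adapter raises a clear
  error when the optional dependency is missing.

Retrieval is an exact dense cosine scan over the description matrix.  At the
corpus sizes this library indexes in tests and batch runs, a matrix product
is both exact and fast; approximate indexes would only trade exactness for
speed that is not needed here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "EmbeddingProvider",
    "HashingEmbeddingProvider",
    "NeuralEmbeddingProvider",
    "SimilarityHit",
    "DescriptionIndex",
    "EmbeddingCache",
    "cosine",
    "get_provider",
]

_NORM_TOL = 1e-6


class EmbeddingProvider(Protocol):
    """Contract for text→unit-vector providers.

    Implementations must be deterministic: embedding a fixed string yields
    an identical vector across calls and across processes for the same
    provider configuration, and every returned row has unit L2 norm.
    """

    name: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def _validate_texts(texts: Sequence[str]) -> None:
    if len(texts) == 0:
        raise ValueError("embed() requires at least one text")
    for i, t in enumerate(texts):
        if not isinstance(t, str) or not t.strip():
            raise ValueError(f"text at index {i} is empty after whitespace stripping")


@dataclass(frozen=True)
class HashingEmbeddingProvider:
    """Character 3-gram feature hashing into a fixed-dimension unit vector.

    Recipe (seedless, platform-stable):

    1. lowercase the text and collapse runs of whitespace to single spaces;
    2. pad with one leading and one trailing space so word boundaries
       contribute their own 3-grams;
    3. for each character 3-gram, hash it with BLAKE2b (8-byte digest);
       the bucket is ``digest mod dim`` and the sign is taken from the
       lowest bit of ``digest // dim``, i.e. signed feature hashing;
    4. L2-normalize the accumulated bucket counts.

    BLAKE2b is used instead of Python's builtin ``hash`` because the
    builtin is salted per process; the recipe must be reproducible across
    processes and machines.
    """

    dim: int = 256
    name: str = "hash-3gram"

    def _gram_index(self, gram: str) -> tuple[int, float]:
        digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest()
        value = int.from_bytes(digest, "big")
        sign = 1.0 if (value // self.dim) & 1 else -1.0
        return value % self.dim, sign

    def embed_one(self, text: str) -> np.ndarray:
        normalized = " ".join(text.lower().split())
        padded = f" {normalized} "
        vec = np.zeros(self.dim, dtype=np.float64)
        for i in range(len(padded) - 2):
            idx, sign = self._gram_index(padded[i : i + 3])
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # degenerate (e.g. 1-char text); fall back to a fixed axis
            vec[0] = 1.0
            return vec
        return vec / norm

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        _validate_texts(texts)
        return np.vstack([self.embed_one(t) for t in texts])


class NeuralEmbeddingProvider:
    """Adapter over a ``sentence-transformers`` model.

    The model name is any hub identifier (a biomedical similarity model for
    English, a multilingual paraphrase model for German).  Raw text is
    passed through untouched — the model's own tokenizer normalizes.
    """

    def __init__(self, model_name: str):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "Neural embedding providers require the optional "
                "'sentence-transformers' dependency (pip install notelink[neural])"
            ) from exc
        self._model = SentenceTransformer(model_name)  # pragma: no cover
        self.name = model_name  # pragma: no cover
        self.dim = int(self._model.get_sentence_embedding_dimension())  # pragma: no cover

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        _validate_texts(texts)
        vectors = np.asarray(self._model.encode(list(texts)), dtype=np.float64)
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        return vectors / np.clip(norms, 1e-12, None)


def get_provider(name: str = "hash-3gram", dim: int = 256) -> EmbeddingProvider:
    """Resolve a provider by config name.

    ``"hash-3gram"`` selects the deterministic fallback; any other name is
    treated as a sentence-transformers model identifier.
    """
    if name == "hash-3gram":
        return HashingEmbeddingProvider(dim=dim)
    return NeuralEmbeddingProvider(name)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors of equal dimension."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class SimilarityHit:
    """One retrieved description: identifier, its concepts, cosine score."""

    description_id: str
    concept_ids: tuple[str, ...]
    score: float


class DescriptionIndex:
    """Exact cosine index over embedded description texts.

    Rows are unit vectors, so cosine similarity is a plain dot product.
    Queries return hits sorted by non-increasing score; ties are broken by
    ascending description id so results are fully deterministic.
    """

    def __init__(
        self,
        description_ids: Sequence[str],
        concept_ids_per_description: Sequence[Sequence[str]],
        matrix: np.ndarray,
    ):
        if len(description_ids) != matrix.shape[0]:
            raise ValueError("row count must equal description count")
        if len(description_ids) == 0:
            raise RuntimeError("description index is empty")
        self.description_ids = list(description_ids)
        self.concept_ids = [tuple(c) for c in concept_ids_per_description]
        self.matrix = np.asarray(matrix, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.description_ids)

    def top_k(self, query: np.ndarray, k: int) -> list[SimilarityHit]:
        if k < 1:
            raise ValueError("k must be >= 1")
        scores = self.matrix @ np.asarray(query, dtype=np.float64)
        # sort by (-score, description_id); lexsort's last key is primary
        order = np.lexsort((np.array(self.description_ids), -scores))
        hits = []
        for idx in order[: min(k, len(self))]:
            hits.append(
                SimilarityHit(
                    description_id=self.description_ids[idx],
                    concept_ids=self.concept_ids[idx],
                    score=float(scores[idx]),
                )
            )
        return hits

    def batch_top_k(self, queries: np.ndarray, k: int) -> list[list[SimilarityHit]]:
        """Top-k for many queries in one matrix product."""
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        scores = queries @ self.matrix.T
        out = []
        desc_arr = np.array(self.description_ids)
        for row in scores:
            order = np.lexsort((desc_arr, -row))
            out.append(
                [
                    SimilarityHit(
                        description_id=self.description_ids[idx],
                        concept_ids=self.concept_ids[idx],
                        score=float(row[idx]),
                    )
                    for idx in order[: min(k, len(self))]
                ]
            )
        return out


@dataclass
class EmbeddingCache:
    """In-process embedding cache keyed by (provider name, text).

    Repeated indexing of the same description set hits the cache instead of
    re-hashing or re-encoding.  The cache is content-addressed, so it is
    safe to share across indexes built with the same provider.
    """

    provider: EmbeddingProvider
    _store: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        _validate_texts(texts)
        missing = [t for t in texts if (self.provider.name, t) not in self._store]
        if missing:
            fresh = self.provider.embed(missing)
            for t, v in zip(missing, fresh):
                self._store[(self.provider.name, t)] = v
            self.misses += len(missing)
        self.hits += len(texts) - len(missing)
        return np.vstack([self._store[(self.provider.name, t)] for t in texts])
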