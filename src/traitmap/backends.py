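"""Trait-similarity scoring backends.

A *backend* is a named, deterministic scorer of text pairs together
with an :class:`Orientation` saying whether larger scores mean closer
(similarity) or farther (distance).  Everything downstream — candidate
ranking, evaluation, pairwise matrices — consumes backends only through
this contract, so edit-distance ratios, embedding cosines and
model-inferred ontology distances are interchangeable.

All backends normalize their inputs (lower-case, collapsed whitespace)
before scoring.

The Levenshtein ratio here uses the python-Levenshtein ``ratio``
convention: insertions and deletions cost 1 but substitutions cost 2,
giving ``ratio = (|s| + |t| - D) / (|s| + |t|)``.  With substitution
cost 2 the weighted distance equals ``|s| + |t| - 2*LCS(s, t)``, so the
ratio reduces to ``2*LCS / (|s| + |t|)``; note this differs from the
plain unit-cost edit-distance ratio.
"""

from __future__ import annotations

import enum
import hashlib
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .ontology import normalize_text

logger = logging.getLogger(__name__)


class Orientation(enum.Enum):
    """Whether a backend's scores are similarities or distances."""

    SIMILARITY = "similarity_higher_is_closer"
    DISTANCE = "distance_lower_is_closer"

    @property
    def higher_is_closer(self) -> bool:
        return self is Orientation.SIMILARITY


class BackendError(ValueError):
    """Configuration or format problem in a backend definition."""


class MissingVectorError(KeyError):
    """A text has no stored vector / pair score in a table-based backend."""


@dataclass(frozen=True)
class Backend:
    """A named trait-similarity scorer with a declared orientation.

    ``scorer`` receives *normalized* texts.  ``embed``, when present,
    maps a normalized text to a vector; consumers may use it to
    precompute label vectors once (ranking indexes do).
    """

    name: str
    orientation: Orientation
    scorer: Callable[[str, str], float]
    embed: Callable[[str], np.ndarray] | None = field(default=None)

    def score(self, query: str, target: str) -> float:
        return float(self.scorer(normalize_text(query), normalize_text(target)))


# -- Levenshtein ratio -----------------------------------------------------

def _lcs_length(s: str, t: str) -> int:
    """Length of the longest common subsequence (bit-parallel, O(nm/64))."""
    if not s or not t:
        return 0
    m = len(s)
    mask = (1 << m) - 1
    position: dict[str, int] = {}
    for i, c in enumerate(s):
        position[c] = position.get(c, 0) | (1 << i)
    row = mask
    for c in t:
        hits = row & position.get(c, 0)
        row = ((row + hits) | (row - hits)) & mask
    return m - bin(row).count("1")


def levenshtein_ratio(s: str, t: str) -> float:
    """Indel-weighted Levenshtein similarity in [0, 1].

    ``(|s| + |t| - D) / (|s| + |t|)`` with insertion/deletion cost 1 and
    substitution cost 2; equivalently ``2*LCS(s, t) / (|s| + |t|)``.
    Two empty strings are defined as identical (ratio 1.0).
    """
    total = len(s) + len(t)
    if total == 0:
        return 1.0
    return 2.0 * _lcs_length(s, t) / total


def levenshtein_backend() -> Backend:
    """The edit-distance-ratio backend (similarity orientation)."""
    return Backend(
        name="levenshtein",
        orientation=Orientation.SIMILARITY,
        scorer=levenshtein_ratio,
    )


# -- cosine ----------------------------------------------------------------

def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine of the angle between two equal-length vectors.

    A zero vector has no direction; such pairs score 0 (with a logged
    warning) so that pipelines stay total on degenerate inputs.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise BackendError(f"vector dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        logger.warning("cosine of a zero vector defined as 0")
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# -- hashed character-n-gram embedder -------------------------------------

def _char_ngrams(text: str, n_low: int, n_high: int) -> list[str]:
    grams = []
    for n in range(n_low, n_high + 1):
        grams.extend(text[i : i + n] for i in range(len(text) - n + 1))
    return grams


def _hash_bucket(gram: str, dim: int, seed: int) -> tuple[int, float]:
    """Stable (bucket, sign) for an n-gram under a seeded blake2 hash."""
    h = hashlib.blake2b(
        gram.encode("utf-8"), digest_size=8, key=str(seed).encode()
    ).digest()
    value = int.from_bytes(h, "big")
    return value % dim, 1.0 if (value >> 63) & 1 else -1.0


def build_ngram_embedder(
    corpus: Sequence[str],
    n_range: tuple[int, int] = (3, 4),
    dim: int = 256,
    seed: int = 0,
) -> Backend:
    """Fit a hashed character-n-gram TF-IDF embedder on a corpus.

    Character n-grams (lengths ``n_range[0]..n_range[1]``) of each
    normalized text are hashed into ``dim`` signed buckets; bucket
    weights are term frequency times a smoothed inverse document
    frequency fitted on the corpus.  The returned backend scores cosine
    similarity of these vectors and exposes ``embed`` for vector
    precomputation.  Identical corpus + configuration + seed give
    bit-identical scores.

    This is a self-contained, download-free embedding; pretrained
    sentence-embedding models enter the pipeline through
    :func:`load_vector_backend` instead.
    """
    if len(corpus) == 0:
        raise BackendError("n-gram embedder needs a non-empty corpus")
    n_low, n_high = n_range
    if not (1 <= n_low <= n_high):
        raise BackendError(f"invalid n-gram range {n_range}")
    if dim < 1:
        raise BackendError("embedding dimension must be positive")

    doc_freq: Counter[str] = Counter()
    for text in corpus:
        doc_freq.update(set(_char_ngrams(normalize_text(text), n_low, n_high)))
    n_docs = len(corpus)
    # sklearn-style smoothed idf: log((1 + N) / (1 + df)) + 1
    idf = {
        g: math.log((1 + n_docs) / (1 + df)) + 1.0 for g, df in doc_freq.items()
    }
    default_idf = math.log(1 + n_docs) + 1.0  # unseen n-grams

    bucket_cache: dict[str, tuple[int, float]] = {}

    def embed(text: str) -> np.ndarray:
        vec = np.zeros(dim, dtype=float)
        counts = Counter(_char_ngrams(normalize_text(text), n_low, n_high))
        for gram, tf in counts.items():
            cached = bucket_cache.get(gram)
            if cached is None:
                cached = _hash_bucket(gram, dim, seed)
                bucket_cache[gram] = cached
            bucket, sign = cached
            vec[bucket] += sign * tf * idf.get(gram, default_idf)
        return vec

    def scorer(a: str, b: str) -> float:
        return cosine_similarity(embed(a), embed(b))

    return Backend(
        name=f"ngram[{n_low}-{n_high},dim={dim},seed={seed}]",
        orientation=Orientation.SIMILARITY,
        scorer=scorer,
        embed=embed,
    )


# -- precomputed vector tables --------------------------------------------

VectorTable = Union[str, Path, pd.DataFrame, Mapping[str, Sequence[float]]]


def _vectors_from_table(table: VectorTable) -> dict[str, np.ndarray]:
    if isinstance(table, Mapping):
        items = [(str(k), np.asarray(v, dtype=float)) for k, v in table.items()]
    else:
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", header=None, dtype=str)
        items = []
        for row in table.itertuples(index=False):
            key = str(row[0])
            try:
                vec = np.asarray([float(x) for x in row[1:]], dtype=float)
            except (TypeError, ValueError) as exc:
                raise BackendError(f"non-numeric vector entry for key {key!r}") from exc
            items.append((key, vec))
    if not items:
        raise BackendError("empty vector table")
    vectors: dict[str, np.ndarray] = {}
    dim = items[0][1].shape
    for key, vec in items:
        key = normalize_text(key)
        if key in vectors:
            raise BackendError(f"duplicate vector key {key!r}")
        if vec.shape != dim or np.isnan(vec).any():
            raise BackendError(
                f"ragged or invalid vector row for key {key!r}: "
                f"expected dimension {dim[0]}"
            )
        vectors[key] = vec
    return vectors


def load_vector_backend(
    table: VectorTable,
    orientation: Orientation = Orientation.SIMILARITY,
    name: str = "vectors",
) -> Backend:
    """Backend over precomputed text -> vector rows (TSV path, DataFrame
    or mapping; first column key, remaining columns floats).

    Similarity-oriented tables score cosine similarity between stored
    vectors; a distance orientation scores euclidean distance.  Keys are
    normalized like every other backend input; texts absent from the
    table raise :class:`MissingVectorError` at query time.
    """
    vectors = _vectors_from_table(table)

    def lookup(text: str) -> np.ndarray:
        try:
            return vectors[text]
        except KeyError:
            raise MissingVectorError(
                f"no stored vector for text {text!r} in backend {name!r}"
            ) from None

    if orientation is Orientation.SIMILARITY:
        def scorer(a: str, b: str) -> float:
            return cosine_similarity(lookup(a), lookup(b))
    else:
        def scorer(a: str, b: str) -> float:
            return float(np.linalg.norm(lookup(a) - lookup(b)))

    return Backend(name=name, orientation=orientation, scorer=scorer, embed=lookup)
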