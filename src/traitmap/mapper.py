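"""Rank ontology terms (or peer traits) for a free-text query.

Ranking is exhaustive: every term label is scored against the query by
the backend and candidates are ordered best-first under the backend's
orientation.  Ties are broken by term identifier so that rankings — and
therefore exact-match counts — are fully deterministic.

The two-stage hybrid ranker mirrors a common retrieval pattern: a cheap
first-stage backend shortlists the top ``x`` candidates, and a costlier
second-stage backend rescores just that shortlist to produce the final
top ``n``.  With ``x`` equal to the index size the hybrid collapses to
pure second-stage ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import Backend, Orientation, cosine_similarity
from .ontology import OntologyGraph, normalize_text


@dataclass(frozen=True)
class ScoredCandidate:
    """One ranked term prediction for a query."""

    term: str
    label: str
    score: float
    rank: int  # 1-based


@dataclass(frozen=True)
class RankedCandidates:
    """Best-first ordered predictions for one query."""

    query: str
    backend_name: str
    candidates: tuple[ScoredCandidate, ...]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]

    @property
    def terms(self) -> list[str]:
        return [c.term for c in self.candidates]

    @property
    def top(self) -> ScoredCandidate:
        if not self.candidates:
            raise ValueError(f"no candidates for query {self.query!r}")
        return self.candidates[0]


class CandidateIndex:
    """Scoring index over the labels of an ontology's terms.

    For backends exposing ``embed`` (vector backends), label vectors are
    precomputed once at build time and queries are scored by cosine
    against the cached matrix; other backends are scored pairwise.
    """

    def __init__(self, backend: Backend, graph: OntologyGraph):
        self.backend = backend
        # fixed, sorted order makes rebuilds and tie-breaking reproducible
        self._terms = graph.terms
        self._labels = [graph.label(t) for t in self._terms]
        self._label_vectors: np.ndarray | None = None
        if backend.embed is not None:
            self._label_vectors = np.vstack(
                [backend.embed(lbl) for lbl in self._labels]
            )

    def __len__(self) -> int:
        return len(self._terms)

    @property
    def terms(self) -> list[str]:
        return list(self._terms)

    def _scores(self, query: str) -> np.ndarray:
        query = normalize_text(query)
        if self._label_vectors is not None and self.backend.embed is not None:
            qv = self.backend.embed(query)
            if self.backend.orientation is Orientation.SIMILARITY:
                return np.array(
                    [cosine_similarity(qv, lv) for lv in self._label_vectors]
                )
            return np.linalg.norm(self._label_vectors - qv[None, :], axis=1)
        return np.array(
            [self.backend.scorer(query, lbl) for lbl in self._labels]
        )

    def rank(self, query: str, n: int) -> RankedCandidates:
        if not normalize_text(query):
            raise ValueError("empty query")
        if n < 1:
            raise ValueError("n must be >= 1")
        scores = self._scores(query)
        order = _best_first_order(scores, self._terms, self.backend.orientation)
        top = order[: min(n, len(order))]
        candidates = tuple(
            ScoredCandidate(
                term=self._terms[i],
                label=self._labels[i],
                score=float(scores[i]),
                rank=rank,
            )
            for rank, i in enumerate(top, start=1)
        )
        return RankedCandidates(
            query=query, backend_name=self.backend.name, candidates=candidates
        )


def _best_first_order(
    scores: np.ndarray, terms: list[str], orientation: Orientation
) -> list[int]:
    """Indices sorted best-first by score, ties broken by term id."""
    sign = -1.0 if orientation.higher_is_closer else 1.0
    return sorted(range(len(terms)), key=lambda i: (sign * scores[i], terms[i]))


def build_index(backend: Backend, graph: OntologyGraph) -> CandidateIndex:
    """Precompute a ranking index over all term labels of ``graph``."""
    return CandidateIndex(backend, graph)


def rank_candidates(index: CandidateIndex, query: str, n: int) -> RankedCandidates:
    """Top-``n`` terms for ``query``, best-first under the backend's
    orientation; ``n`` beyond the index size returns all terms."""
    return index.rank(query, n)


def hybrid_rank(
    index_stage1: CandidateIndex,
    scorer_stage2: Backend,
    query: str,
    x: int,
    n: int,
) -> RankedCandidates:
    """Two-stage retrieval: stage-1 shortlist of ``x`` candidates,
    rescored and re-ranked by the stage-2 backend, truncated to ``n``.

    Returned scores and ranks reflect stage 2 only.
    """
    if n < 1 or x < n:
        raise ValueError(f"need 1 <= n <= x, got n={n}, x={x}")
    shortlist = index_stage1.rank(query, x)
    nquery = normalize_text(query)
    scores = np.array(
        [scorer_stage2.scorer(nquery, c.label) for c in shortlist]
    )
    terms = [c.term for c in shortlist]
    order = _best_first_order(scores, terms, scorer_stage2.orientation)
    candidates = tuple(
        ScoredCandidate(
            term=terms[i],
            label=shortlist[i].label,
            score=float(scores[i]),
            rank=rank,
        )
        for rank, i in enumerate(order[: min(n, len(order))], start=1)
    )
    return RankedCandidates(
        query=nquery,
        backend_name=f"{index_stage1.backend.name}-x-{scorer_stage2.name}",
        candidates=candidates,
    )
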