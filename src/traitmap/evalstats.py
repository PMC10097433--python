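"""Score ranked predictions against gold mappings with ontology topology.

For each gold query the ranked predictions of a backend are annotated
with the Batet similarity between each predicted term and the manually
assigned term.  From these annotated queries the module derives the
benchmark statistics:

* exact-match counts (rank-1 prediction identical to the manual term),
  broken down by mapping type;
* counts of rank-1 predictions at or above a Batet threshold — at
  threshold 1.0 this coincides with the exact-match total whenever
  labels are unique per term;
* rank-weighted average Batet scores of the top ``N`` predictions
  (weights ``N, N-1, ..., 1``, normalized by their sum) and the per-N
  curve of their means across queries;
* a pooled two-proportion z-test and a two-sample Kolmogorov–Smirnov
  test for comparing methods.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .golddata import MAPPING_TYPES, GoldMapping
from .mapper import RankedCandidates
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluatedQuery:
    """Ranked predictions for one gold query, annotated with the Batet
    similarity of each predicted term to the manual term
    (``batet_per_rank[i]`` belongs to rank ``i + 1``)."""

    gold: GoldMapping
    predictions: RankedCandidates
    batet_per_rank: tuple[float, ...]

    @property
    def top_is_exact(self) -> bool:
        return (
            len(self.predictions) > 0
            and self.predictions[0].term == self.gold.term
        )


@dataclass(frozen=True)
class MatchSummary:
    """Exact-match totals, partitioned by mapping type."""

    total_matched: int
    by_mapping_type: dict[str, int]
    n_queries: int

    @property
    def proportion(self) -> float:
        if self.n_queries == 0:
            raise ValueError("no queries evaluated")
        return self.total_matched / self.n_queries


def attach_batet(
    gold: GoldMapping,
    predictions: RankedCandidates,
    graph: OntologyGraph,
) -> EvaluatedQuery:
    """Annotate each predicted term with its Batet similarity to the
    gold term (raises a lookup error naming any term absent from the
    ontology)."""
    scores = tuple(
        graph.batet_similarity(gold.term, cand.term) for cand in predictions
    )
    return EvaluatedQuery(gold=gold, predictions=predictions, batet_per_rank=scores)


def exact_match_summary(evaluated: Sequence[EvaluatedQuery]) -> MatchSummary:
    """Count queries whose rank-1 predicted term equals the gold term
    (identifier equality), by mapping type."""
    by_type: Counter[str] = Counter()
    for ev in evaluated:
        if ev.top_is_exact:
            by_type[ev.gold.mapping_type] += 1
    by_mapping_type = {t: by_type.get(t, 0) for t in MAPPING_TYPES}
    return MatchSummary(
        total_matched=sum(by_mapping_type.values()),
        by_mapping_type=by_mapping_type,
        n_queries=len(evaluated),
    )


def thresholded_match_count(
    evaluated: Sequence[EvaluatedQuery], threshold: float
) -> int:
    """Number of queries whose rank-1 Batet score is >= ``threshold``
    (exact floating comparison; queries without predictions never
    count)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return sum(
        1
        for ev in evaluated
        if ev.batet_per_rank and ev.batet_per_rank[0] >= threshold
    )


def weighted_average_score(scores: Sequence[float], n: int) -> float:
    """Rank-weighted mean of the first ``n`` scores: weights
    ``n, n-1, ..., 1`` normalized by their sum (``n(n+1)/2``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(scores) < n:
        raise ValueError(f"need at least {n} scores, got {len(scores)}")
    weights = np.arange(n, 0, -1, dtype=float)
    return float(np.dot(weights, np.asarray(scores[:n], dtype=float)) / weights.sum())


def topn_curve(
    evaluated: Sequence[EvaluatedQuery],
    max_n: int,
    on_short: str = "drop",
) -> np.ndarray:
    """Mean over queries of the rank-weighted average Batet score, for
    each top-``N`` level ``N = 1..max_n``.

    The ``N = 1`` point is simply the mean rank-1 Batet score.  Queries
    with fewer than ``N`` predictions are excluded from the ``N``-th
    point with a logged count (``on_short="drop"``, the default) or
    raise an error naming the first offender (``on_short="raise"``).
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if on_short not in ("drop", "raise"):
        raise ValueError("on_short must be 'drop' or 'raise'")
    curve = np.empty(max_n, dtype=float)
    for n in range(1, max_n + 1):
        values = []
        n_short = 0
        for ev in evaluated:
            if len(ev.batet_per_rank) < n:
                if on_short == "raise":
                    raise ValueError(
                        f"query {ev.gold.query!r} has only "
                        f"{len(ev.batet_per_rank)} predictions, need {n}"
                    )
                n_short += 1
                continue
            values.append(weighted_average_score(ev.batet_per_rank, n))
        if n_short:
            logger.info("top-%d curve point: %d short quer(ies) dropped", n, n_short)
        if not values:
            raise ValueError(f"no query has {n} predictions")
        curve[n - 1] = float(np.mean(values))
    return curve


def proportions_ztest(k1: int, k2: int, n: int) -> tuple[float, float]:
    """Pooled two-proportion z-test for counts ``k1`` and ``k2`` out of
    ``n`` trials each; returns ``(z, two-sided p)`` from the standard
    normal.  Antisymmetric in the counts: swapping them flips the sign
    of z and leaves p unchanged."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k1 <= n and 0 <= k2 <= n):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = k1 / n, k2 / n
    pooled = (k1 + k2) / (2 * n)
    se = np.sqrt(pooled * (1 - pooled) * (2 / n))
    if se == 0.0:  # both proportions 0 or both 1 -> identical
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test with the asymptotic
    p-value; returns ``(D, p)``."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(np.asarray(x, float), np.asarray(y, float), method="asymp")
    return float(res.statistic), float(res.pvalue)
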