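"""Ontology entity-alignment training pairs and inferred-distance backends.

A pair-scoring model can be taught ontology structure by training it to
predict, from two term labels alone, how many graph hops separate the
terms.  This module builds that training data — label pairs stratified
by exact undirected hop distance, balanced per stratum so short
distances are not swamped by the combinatorially dominant long ones —
and provides the consumer contract: any table of model-inferred pair
distances becomes a distance-oriented :class:`~traitmap.backends.Backend`
that plugs into ranking, evaluation and matrix comparison unchanged.

Model training itself (architecture, loss, epochs) is out of scope;
only the dataset and the scorer contract live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import networkx as nx
import numpy as np
import pandas as pd

from .backends import Backend, MissingVectorError, Orientation
from .ontology import OntologyGraph, normalize_text

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentPair:
    """Two term labels with the exact hop distance of their terms."""

    text_a: str
    text_b: str
    steps: int

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be non-negative")


def generate_alignment_pairs(
    graph: OntologyGraph,
    max_steps: int,
    pairs_per_distance: int,
    seed: int = 0,
) -> list[AlignmentPair]:
    """Sample labelled term-label pairs stratified by hop distance.

    For every distance ``d`` in ``0..max_steps`` up to
    ``pairs_per_distance`` unordered term pairs at exactly distance
    ``d`` are drawn uniformly (``d = 0`` pairs are self-pairs) and
    emitted as their labels.  Sampling is seeded and reproducible;
    strata with fewer available pairs than requested are emitted in
    full with a logged shortfall.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if pairs_per_distance < 1:
        raise ValueError("pairs_per_distance must be >= 1")
    terms = graph.terms
    if len(terms) < 2:
        raise ValueError("need at least two terms")

    undirected = nx.Graph()
    undirected.add_nodes_from(terms)
    undirected.add_edges_from(graph.edges())
    strata: dict[int, list[tuple[str, str]]] = {
        d: [] for d in range(max_steps + 1)
    }
    strata[0] = [(t, t) for t in terms]
    for source in terms:
        lengths = nx.single_source_shortest_path_length(
            undirected, source, cutoff=max_steps
        )
        for target, d in lengths.items():
            if d >= 1 and source < target:  # one direction per unordered pair
                strata[d].append((source, target))

    rng = np.random.default_rng(seed)
    pairs: list[AlignmentPair] = []
    for d in range(max_steps + 1):
        available = sorted(strata[d])
        if len(available) > pairs_per_distance:
            idx = rng.choice(len(available), size=pairs_per_distance, replace=False)
            chosen = [available[i] for i in sorted(idx)]
        else:
            chosen = available
            if len(available) < pairs_per_distance:
                logger.warning(
                    "distance %d: only %d pair(s) available (%d requested)",
                    d, len(available), pairs_per_distance,
                )
        pairs.extend(
            AlignmentPair(
                text_a=graph.label(a), text_b=graph.label(b), steps=d
            )
            for a, b in chosen
        )
    return pairs


def pairs_to_frame(pairs: list[AlignmentPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.text_a, p.text_b, p.steps) for p in pairs],
        columns=["text_a", "text_b", "steps"],
    )


PairTable = Union[str, Path, pd.DataFrame, Mapping[tuple[str, str], float]]


def inferred_distance_backend(
    pair_score_table: PairTable, name: str = "inferred-distance"
) -> Backend:
    """Distance-oriented backend over a stored (text_a, text_b) -> score
    table of model-inferred ontology distances.

    The table is queried symmetrically: if both orders of a pair are
    stored the smaller score wins.  Texts are normalized like every
    other backend input; unseen pairs raise a missing-score error.
    """
    if isinstance(pair_score_table, Mapping):
        rows = [(a, b, s) for (a, b), s in pair_score_table.items()]
    else:
        if not isinstance(pair_score_table, pd.DataFrame):
            pair_score_table = pd.read_csv(
                pair_score_table, sep="\t", header=None,
                names=["text_a", "text_b", "score"], dtype={0: str, 1: str},
            )
        rows = [
            (r[0], r[1], float(r[2]))
            for r in pair_score_table.itertuples(index=False)
        ]
    scores: dict[tuple[str, str], float] = {}
    for a, b, s in rows:
        key = (normalize_text(a), normalize_text(b))
        s = float(s)
        scores[key] = min(s, scores[key]) if key in scores else s

    def scorer(a: str, b: str) -> float:
        forward = scores.get((a, b))
        backward = scores.get((b, a))
        if forward is None and backward is None:
            raise MissingVectorError(
                f"no inferred distance stored for pair ({a!r}, {b!r})"
            )
        candidates = [s for s in (forward, backward) if s is not None]
        return min(candidates)

    return Backend(name=name, orientation=Orientation.DISTANCE, scorer=scorer)


def step_distance_backend(graph: OntologyGraph) -> Backend:
    """An oracle inferred-distance backend that scores two *labels* by
    the true hop distance of their terms — useful for self-consistency
    checks of the orientation contract (labels must be unique)."""
    by_label: dict[str, str] = {}
    for term in graph.terms:
        label = graph.label(term)
        if label in by_label:
            raise ValueError(f"label {label!r} is not unique")
        by_label[label] = term

    def scorer(a: str, b: str) -> float:
        try:
            ta, tb = by_label[a], by_label[b]
        except KeyError as exc:
            raise MissingVectorError(f"unknown label {exc.args[0]!r}") from None
        return graph.step_distance(ta, tb)

    return Backend(
        name="step-distance", orientation=Orientation.DISTANCE, scorer=scorer
    )
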