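"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
Batet oracle materializes full transitive closures by naive parent
chasing, the hop-distance oracle is a plain breadth-first search, and
the edit-ratio oracle is the quadratic weighted-Levenshtein dynamic
program.  Property tests compare the implementation against these.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from traitmap import OntologyGraph


# -- toy graphs used throughout the contract examples ---------------------

@pytest.fixture
def toy_graph() -> OntologyGraph:
    """root -> {A, B}, A -> C; four labelled terms."""
    return OntologyGraph(
        edges=[("root", "A"), ("root", "B"), ("A", "C")],
        labels={"root": "Root", "A": "alpha", "B": "beta", "C": "gamma"},
    )


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """root -> {A, B}, both A and B -> D (a diamond)."""
    return OntologyGraph(
        edges=[("root", "A"), ("root", "B"), ("A", "D"), ("B", "D")],
        labels={"root": "root", "A": "a", "B": "b", "D": "d"},
    )


@pytest.fixture
def two_roots_graph() -> OntologyGraph:
    return OntologyGraph(
        edges=[("r1", "x"), ("r2", "y")],
        labels={"r1": "first root", "r2": "second root", "x": "x", "y": "y"},
    )


# -- random DAGs -----------------------------------------------------------

def random_dag_edges(
    n_terms: int, rng: np.random.Generator
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """A random rooted DAG: term i attaches to 1–2 earlier terms."""
    names = [f"t{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 2 if (i >= 2 and rng.random() < 0.3) else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        edges.extend((names[int(p)], names[i]) for p in parents)
    labels = {name: f"label {name}" for name in names}
    return edges, labels


@pytest.fixture
def random_dag_factory():
    def make(n_terms: int, seed: int) -> OntologyGraph:
        edges, labels = random_dag_edges(n_terms, np.random.default_rng(seed))
        return OntologyGraph(edges, labels)

    return make


# -- independent oracles ---------------------------------------------------

def oracle_ancestors(edges: list[tuple[str, str]], term: str) -> frozenset[str]:
    """Inclusive ancestor set by naive repeated parent-chasing."""
    parents: dict[str, set[str]] = {}
    for p, c in edges:
        parents.setdefault(c, set()).add(p)
    closed = {term}
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            nxt |= parents.get(t, set())
        frontier = nxt - closed
        closed |= nxt
    return frozenset(closed)


def oracle_batet(edges: list[tuple[str, str]], a: str, b: str) -> float:
    anc_a = oracle_ancestors(edges, a)
    anc_b = oracle_ancestors(edges, b)
    union = len(anc_a | anc_b)
    inter = len(anc_a & anc_b)
    return 1.0 - math.log2(1.0 + (union - inter) / union)


def oracle_step_distance(
    edges: list[tuple[str, str]], nodes: list[str], a: str, b: str
) -> float:
    """Breadth-first search over the undirected edge set."""
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for p, c in edges:
        adjacency[p].add(c)
        adjacency[c].add(p)
    queue = deque([(a, 0)])
    seen = {a}
    while queue:
        node, d = queue.popleft()
        if node == b:
            return float(d)
        for nb in adjacency[node]:
            if nb not in seen:
                seen.add(nb)
                queue.append((nb, d + 1))
    return math.inf


def oracle_levenshtein_ratio(s: str, t: str) -> float:
    """Quadratic DP with insertion/deletion cost 1, substitution cost 2."""
    n, m = len(s), len(t)
    if n + m == 0:
        return 1.0
    dist = np.zeros((n + 1, m + 1))
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 0 if s[i - 1] == t[j - 1] else 2
            dist[i, j] = min(
                dist[i - 1, j] + 1,
                dist[i, j - 1] + 1,
                dist[i - 1, j - 1] + sub,
            )
    return (n + m - dist[n, m]) / (n + m)
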