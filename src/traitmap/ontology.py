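"""Ontology graphs and topology-based term similarity.

An ontology is modelled as a rooted directed acyclic graph of terms
(edges point parent -> child) with one human-readable label per term.
The central quantity is the Batet ancestor-set similarity

    sim(a, b) = 1 - log2(1 + (|U| - |I|) / |U|)

where ``U`` and ``I`` are the union and intersection of the *inclusive*
ancestor sets of ``a`` and ``b`` (each term counts among its own
ancestors, so ``sim(a, a) = 1``).  The score lives in ``[0, 1]``; terms
with disjoint ancestries (e.g. under different roots) score 0.

Hop distance between terms is the shortest-path length over the
parent/child edges treated as undirected; disconnected pairs are
reported with the :data:`NO_PATH` sentinel rather than an exception.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`step_distance` for disconnected term pairs.
NO_PATH = math.inf

TableLike = Union[str, Path, pd.DataFrame]

_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lower-case and collapse internal whitespace; strip the ends."""
    return _WS.sub(" ", str(text)).strip().lower()


class OntologyError(ValueError):
    """Structural problem in the ontology input (cycle, missing label...)."""


class UnknownTermError(KeyError):
    """A term identifier was not found in the ontology."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unknown ontology term: {self.term!r}"


class OntologyGraph:
    """Rooted DAG of terms with labels.

    Parameters
    ----------
    edges:
        Iterable of ``(parent, child)`` term-identifier pairs.
    labels:
        Mapping from term identifier to label text.  Labels are
        normalized (lower-cased, whitespace-collapsed) at construction.
        Terms may appear in ``labels`` without edges (isolated terms),
        but every term used in an edge must carry a label.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        labels: Mapping[str, str],
    ):
        graph = nx.DiGraph()
        n_dupes = 0
        for parent, child in edges:
            parent, child = str(parent), str(child)
            if graph.has_edge(parent, child):
                n_dupes += 1
                continue
            graph.add_edge(parent, child)
        if n_dupes:
            logger.warning("dropped %d duplicate ontology edge(s)", n_dupes)

        self._labels = {str(t): normalize_text(lbl) for t, lbl in labels.items()}
        for term in self._labels:
            graph.add_node(term)

        missing = sorted(t for t in graph.nodes if t not in self._labels)
        if missing:
            raise OntologyError(
                f"{len(missing)} term(s) in edges lack labels: {missing[:10]}"
            )
        for term, label in self._labels.items():
            if not term:
                raise OntologyError("empty term identifier")
            if not label:
                raise OntologyError(f"term {term!r} has an empty label")

        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        roots = [t for t in graph.nodes if graph.in_degree(t) == 0]
        if not roots:
            raise OntologyError("ontology has no root term")

        self._graph = graph
        self._undirected = graph.to_undirected(as_view=True)
        self._roots = sorted(roots)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------

    @property
    def terms(self) -> list[str]:
        """All term identifiers, sorted."""
        return sorted(self._graph.nodes)

    @property
    def roots(self) -> list[str]:
        """Terms with no parent, sorted."""
        return list(self._roots)

    @property
    def n_terms(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self.n_terms

    def label(self, term: str) -> str:
        self._require(term)
        return self._labels[term]

    @property
    def labels(self) -> dict[str, str]:
        """Term -> normalized label mapping (copy)."""
        return dict(self._labels)

    def parents(self, term: str) -> list[str]:
        self._require(term)
        return sorted(self._graph.predecessors(term))

    def children(self, term: str) -> list[str]:
        self._require(term)
        return sorted(self._graph.successors(term))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._graph.edges)

    def _require(self, term: str) -> None:
        if term not in self._graph:
            raise UnknownTermError(term)

    # -- topology metrics ------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Inclusive ancestor set: the term plus everything reachable
        by following child -> parent edges.  Memoized per term."""
        self._require(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def batet_similarity(self, a: str, b: str) -> float:
        """Batet ancestor-set similarity in [0, 1]; 1 iff the inclusive
        ancestor sets coincide, 0 for disjoint ancestries."""
        anc_a, anc_b = self.ancestors(a), self.ancestors(b)
        union = len(anc_a | anc_b)
        inter = len(anc_a & anc_b)
        return batet_from_counts(union, inter)

    def step_distance(self, a: str, b: str) -> float:
        """Undirected shortest-path hop count; :data:`NO_PATH` if the
        terms are in different connected components."""
        self._require(a)
        self._require(b)
        try:
            return float(nx.shortest_path_length(self._undirected, a, b))
        except nx.NetworkXNoPath:
            return NO_PATH


def batet_from_counts(union_size: int, intersection_size: int) -> float:
    """Batet similarity from ancestor-set cardinalities:
    ``1 - log2(1 + (|U| - |I|) / |U|)``."""
    if union_size <= 0:
        raise ValueError("ancestor-set union cannot be empty")
    if not 0 <= intersection_size <= union_size:
        raise ValueError("need 0 <= |I| <= |U|")
    return 1.0 - math.log2(1.0 + (union_size - intersection_size) / union_size)


# -- loading ---------------------------------------------------------------

_EDGE_HEADERS = {"parent", "parent_id", "child", "child_id", "subject", "object"}
_LABEL_HEADERS = {"term", "term_id", "id", "label", "name"}


def _read_two_column_tsv(table: TableLike, known_headers: set[str]) -> pd.DataFrame:
    """Read a 2+-column TSV; the header row is optional and detected by
    name.  Only the first two columns are used (first = parent/term,
    second = child/label)."""
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise OntologyError("table needs at least two columns")
        return table.iloc[:, :2]
    df = pd.read_csv(
        table, sep="\t", header=None, dtype=str, keep_default_na=False,
        comment="#",
    )
    if df.shape[1] < 2:
        raise OntologyError(f"{table}: expected at least two TSV columns")
    first_row = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if any(v in known_headers for v in first_row):
        df = df.iloc[1:].reset_index(drop=True)
    return df.iloc[:, :2]


def load_ontology(edge_table: TableLike, label_table: TableLike) -> OntologyGraph:
    """Build a validated :class:`OntologyGraph` from a parent/child edge
    table and a term/label table (TSV paths or DataFrames; headers
    optional, columns positional: parent first, child second).

    Duplicate edges are dropped with a warning; cycles and edge terms
    without labels raise :class:`OntologyError`.
    """
    edges_df = _read_two_column_tsv(edge_table, _EDGE_HEADERS)
    labels_df = _read_two_column_tsv(label_table, _LABEL_HEADERS)
    edges = [(str(p), str(c)) for p, c in edges_df.itertuples(index=False)]
    labels: dict[str, str] = {}
    for term, label in labels_df.itertuples(index=False):
        term = str(term)
        if term in labels and labels[term] != normalize_text(label):
            raise OntologyError(f"conflicting labels for term {term!r}")
        labels[term] = str(label)
    return OntologyGraph(edges, labels)


def load_obo(path: str | Path) -> OntologyGraph:
    """Load an OBO file (``is_a`` edges only) through the same contract
    as :func:`load_ontology`.  Requires the optional ``obonet`` package.
    """
    import obonet  # optional dependency

    g = obonet.read_obo(path)
    edges = []
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":  # obonet edges point child -> parent
            edges.append((parent, child))
    labels = {t: d.get("name", "") for t, d in g.nodes(data=True)}
    return OntologyGraph(edges, labels)


# Thin functional facade mirroring the graph methods.

def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    return graph.ancestors(term)


def batet_similarity(graph: OntologyGraph, a: str, b: str) -> float:
    return graph.batet_similarity(a, b)


def step_distance(graph: OntologyGraph, a: str, b: str) -> float:
    return graph.step_distance(a, b)
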