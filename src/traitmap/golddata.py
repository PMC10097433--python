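"""Gold-standard trait -> ontology-term mapping tables.

Curated mapping datasets in the EBI UK Biobank -> EFO style associate a
free-text query (a study variable name) with a manually assigned
ontology term plus a *mapping type*: Exact (same concept), Broad
(mapped to a parent concept), Narrow (child concept) or Other.

Two curation protocols are provided:

``filter_ontology_eval``
    prepares the mapping-to-ontology benchmark — drops ambiguous
    (multi-term) queries, lower-cases, removes queries identical to
    their term's label (uninformative for ranking), keeps only terms
    present in the loaded ontology, and deduplicates;

``filter_exact_unique``
    prepares the direct trait-to-trait benchmark — Exact mappings only,
    the same hygiene rules, then one query per distinct term (and one
    term per query), first occurrence winning.

Both filters log how many records each rule removed so the surviving
counts can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .ontology import OntologyGraph, normalize_text

logger = logging.getLogger(__name__)

MAPPING_TYPES = ("Exact", "Broad", "Narrow", "Other")
_CANONICAL_TYPE = {t.lower(): t for t in MAPPING_TYPES}


class GoldTableError(ValueError):
    """Format problem in a gold mapping table."""


@dataclass(frozen=True)
class GoldMapping:
    """One manually curated query -> term mapping."""

    query: str
    term: str
    mapping_type: str  # one of MAPPING_TYPES

    def __post_init__(self):
        if not self.query:
            raise GoldTableError("empty query in gold mapping")
        if self.mapping_type not in MAPPING_TYPES:
            raise GoldTableError(
                f"unknown mapping type {self.mapping_type!r} "
                f"(expected one of {MAPPING_TYPES})"
            )


def _find_column(columns: Sequence[str], tokens: tuple[str, ...], what: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for token in tokens:
        if token in lowered:
            return lowered[token]
    for c in columns:  # substring fallback for EBI-style headers
        if any(token in c.lower() for token in tokens):
            return c
    raise GoldTableError(
        f"cannot locate the {what} column among {list(columns)}"
    )


def parse_gold_table(
    table: Union[str, Path, pd.DataFrame],
    query_col: str | None = None,
    term_col: str | None = None,
    type_col: str | None = None,
) -> list[GoldMapping]:
    """Parse a headered TSV (or DataFrame) of gold mappings.

    Columns are located by name (case-insensitively; EBI-style headers
    such as ``ZOOMA QUERY`` / ``MAPPED_TERM_URI`` / ``MAPPING_TYPE``
    match by substring) or given explicitly.  Row order is preserved
    and no filtering is applied; mapping types are normalized
    case-insensitively, and rows with unrecognized types raise an error
    listing the offenders.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(
            table, sep="\t", dtype=str, keep_default_na=False, comment="#"
        )
    cols = list(table.columns.astype(str))
    query_col = query_col or _find_column(cols, ("query", "trait", "variable"), "query")
    term_col = term_col or _find_column(cols, ("term", "uri", "efo"), "term")
    type_col = type_col or _find_column(cols, ("mapping_type", "type"), "mapping type")

    records: list[GoldMapping] = []
    bad_types: list[tuple[int, str]] = []
    for i, row in enumerate(table.itertuples(index=False)):
        row = dict(zip(cols, row))
        raw_type = str(row[type_col]).strip()
        canonical = _CANONICAL_TYPE.get(raw_type.lower())
        if canonical is None:
            bad_types.append((i, raw_type))
            continue
        records.append(
            GoldMapping(
                query=str(row[query_col]).strip(),
                term=str(row[term_col]).strip(),
                mapping_type=canonical,
            )
        )
    if bad_types:
        raise GoldTableError(
            f"{len(bad_types)} row(s) with unknown mapping type: {bad_types[:10]}"
        )
    return records


def _hygiene(
    gold: Iterable[GoldMapping],
    graph: OntologyGraph,
    drop_label_identical: bool,
    audit: dict[str, int],
) -> list[GoldMapping]:
    """Shared rules: lower-case queries, optionally drop query==label
    records, drop terms missing from the graph, deduplicate."""
    out: list[GoldMapping] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in gold:
        rec = replace(rec, query=normalize_text(rec.query))
        if rec.term not in graph:
            audit["term_not_in_ontology"] += 1
            continue
        if drop_label_identical and rec.query == graph.label(rec.term):
            audit["query_identical_to_label"] += 1
            continue
        key = (rec.query, rec.term, rec.mapping_type)
        if key in seen:
            audit["duplicate_row"] += 1
            continue
        seen.add(key)
        out.append(rec)
    return out


def filter_ontology_eval(
    gold: Sequence[GoldMapping], graph: OntologyGraph
) -> list[GoldMapping]:
    """Curate gold mappings for the mapping-to-ontology benchmark.

    In order: (1) drop every record of any query assigned more than one
    distinct term; (2) lower-case queries; (3) drop records whose query
    equals the mapped term's label; (4) drop records whose term is not
    in ``graph``; (5) deduplicate identical rows.  Surviving row order
    is preserved; per-rule removal counts are logged.
    """
    audit = {
        "multi_term_query": 0,
        "query_identical_to_label": 0,
        "term_not_in_ontology": 0,
        "duplicate_row": 0,
    }
    terms_per_query: dict[str, set[str]] = {}
    for rec in gold:
        terms_per_query.setdefault(normalize_text(rec.query), set()).add(rec.term)
    unambiguous = []
    for rec in gold:
        if len(terms_per_query[normalize_text(rec.query)]) > 1:
            audit["multi_term_query"] += 1
        else:
            unambiguous.append(rec)
    out = _hygiene(unambiguous, graph, drop_label_identical=True, audit=audit)
    logger.info(
        "ontology-eval filter: %d -> %d records (removed %s)",
        len(gold), len(out), audit,
    )
    return out


def filter_exact_unique(
    gold: Sequence[GoldMapping], graph: OntologyGraph
) -> list[GoldMapping]:
    """Curate gold mappings for the direct trait-to-trait benchmark.

    Keeps Exact mappings only, applies the hygiene rules (lower-case,
    in-ontology, dedupe — label-identical queries are *kept* here, the
    benchmark compares traits to each other, not to labels), then
    retains one query per distinct term — first occurrence wins — so
    the result has pairwise-distinct terms and pairwise-distinct
    queries.
    """
    audit = {
        "not_exact": 0,
        "query_identical_to_label": 0,
        "term_not_in_ontology": 0,
        "duplicate_row": 0,
        "repeated_term_or_query": 0,
    }
    exact = []
    for rec in gold:
        if rec.mapping_type == "Exact":
            exact.append(rec)
        else:
            audit["not_exact"] += 1
    cleaned = _hygiene(exact, graph, drop_label_identical=False, audit=audit)
    out: list[GoldMapping] = []
    seen_terms: set[str] = set()
    seen_queries: set[str] = set()
    for rec in cleaned:
        if rec.term in seen_terms or rec.query in seen_queries:
            audit["repeated_term_or_query"] += 1
            continue
        seen_terms.add(rec.term)
        seen_queries.add(rec.query)
        out.append(rec)
    logger.info(
        "exact-unique filter: %d -> %d records (removed %s)",
        len(gold), len(out), audit,
    )
    return out


def gold_to_frame(gold: Sequence[GoldMapping]) -> pd.DataFrame:
    """Gold records as a DataFrame with columns query/term/mapping_type."""
    return pd.DataFrame(
        [(g.query, g.term, g.mapping_type) for g in gold],
        columns=["query", "term", "mapping_type"],
    )
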