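"""Synthetic ontologies and gold-mapping tables with planted truth.

Real evaluations of trait mapping need an ontology and a manually
curated query -> term table; this module fabricates both so that every
pipeline stage is testable end to end without downloads.  The generator
emulates the features that matter to the method:

* a rooted DAG with occasional two-parent terms (diamond motifs, so
  ancestor-set logic is exercised beyond trees);
* one lexical family per root — labels under different roots are built
  from disjoint vocabularies, planting the "two top-level branches"
  structure that ontology-based clustering should recover;
* gold queries that are *perturbed copies* of term labels (synonym
  swaps from a bundled mini-thesaurus, word drops, character edits), so
  the correct answer to every query is known by construction;
* Broad mappings made by genuinely re-assigning a query to a parent of
  its source term.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, normalize_text

#: Probability that a non-root term receives a second parent (diamonds).
TWO_PARENT_PROB = 0.1

#: Default per-root label vocabularies: a disease-like and a
#: measurement-like lexical family, mirroring the disease / quantitative
#: split seen at the top of real trait ontologies.  The first word of a
#: branch vocabulary is its family head noun and is appended to every
#: label of that branch ("... disease" / "... measurement"), the naming
#: convention real trait ontologies follow.
DISEASE_VOCAB = (
    "disease cancer asthma diabetes cardiac renal hepatic chronic acute "
    "syndrome infection carcinoma fibrosis anemia arthritis "
    "sclerosis neoplasm ulcer dementia stroke"
).split()
MEASUREMENT_VOCAB = (
    "measurement systolic pressure count ratio mass height glucose "
    "cholesterol volume rate index density concentration level score "
    "intake duration frequency impedance"
).split()
DEFAULT_VOCABS = (DISEASE_VOCAB, MEASUREMENT_VOCAB)

#: Bundled mini-thesaurus for synonym-swap noise (both directions).
_SYNONYM_PAIRS = [
    ("cancer", "carcinoma"), ("heart", "cardiac"), ("kidney", "renal"),
    ("liver", "hepatic"), ("lung", "pulmonary"), ("brain", "cerebral"),
    ("blood", "serum"), ("high", "elevated"), ("low", "reduced"),
    ("disease", "disorder"), ("chronic", "longstanding"), ("acute", "sudden"),
    ("pressure", "tension"), ("mass", "weight"), ("rate", "frequency"),
    ("level", "concentration"), ("count", "number"), ("score", "index"),
    ("stomach", "gastric"), ("bone", "skeletal"), ("skin", "cutaneous"),
    ("eye", "ocular"), ("ear", "auditory"), ("nerve", "neural"),
    ("muscle", "muscular"), ("vessel", "vascular"), ("gut", "intestinal"),
    ("sugar", "glucose"), ("fat", "lipid"), ("salt", "sodium"),
    ("anemia", "anaemia"), ("tumor", "tumour"), ("swelling", "oedema"),
    ("infection", "sepsis"), ("fever", "pyrexia"), ("pain", "ache"),
    ("breathing", "respiration"), ("heartbeat", "pulse"),
    ("dementia", "alzheimer"), ("stroke", "infarction"),
    ("ulcer", "lesion"), ("asthma", "wheeze"), ("diabetes", "hyperglycemia"),
    ("arthritis", "joint inflammation"), ("fibrosis", "scarring"),
    ("sclerosis", "hardening"), ("syndrome", "condition"),
    ("intake", "consumption"), ("duration", "length"), ("volume", "capacity"),
]
THESAURUS: dict[str, str] = {}
for _a, _b in _SYNONYM_PAIRS:
    THESAURUS[_a] = _b
    THESAURUS[_b] = _a


class GenerationError(RuntimeError):
    """The requested synthetic dataset cannot be generated."""


@dataclass(frozen=True)
class NoiseConfig:
    """Lexical-perturbation rates for gold-query generation.

    ``char_edit_rate`` is the per-character probability of an edit
    (substitution, insertion or deletion), ``word_drop_rate`` the
    per-word drop probability, ``synonym_swap_rate`` the per-word
    probability of replacement by its thesaurus partner.  A zero-rate
    configuration is the identity.  Outcomes are fully determined by
    ``seed`` (and the label being perturbed).
    """

    char_edit_rate: float = 0.0
    word_drop_rate: float = 0.0
    synonym_swap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("char_edit_rate", "word_drop_rate", "synonym_swap_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


#: Ready-made noise levels used throughout the synthetic benchmarks.
MILD_NOISE = NoiseConfig(char_edit_rate=0.02, word_drop_rate=0.0,
                         synonym_swap_rate=0.0, seed=0)
HEAVY_NOISE = NoiseConfig(char_edit_rate=0.3, word_drop_rate=0.1,
                          synonym_swap_rate=0.3, seed=0)


def _label_rng(noise_seed: int, label: str) -> np.random.Generator:
    # per-label stream: perturbation of a label is independent of the
    # order in which labels are perturbed
    return np.random.default_rng(
        [noise_seed & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]
    )


def perturb_label(label: str, noise: NoiseConfig) -> str:
    """Apply synonym swaps, then word drops, then character edits to a
    label, each by seeded draws; zero rates return the input unchanged.
    The result is never empty."""
    if not label:
        raise ValueError("cannot perturb an empty label")
    label = normalize_text(label)
    if (noise.synonym_swap_rate == noise.word_drop_rate
            == noise.char_edit_rate == 0.0):
        return label
    rng = _label_rng(noise.seed, label)

    words = label.split()
    words = [
        THESAURUS[w]
        if w in THESAURUS and rng.random() < noise.synonym_swap_rate
        else w
        for w in words
    ]
    kept = [w for w in words if rng.random() >= noise.word_drop_rate]
    if not kept:  # never drop the whole label
        kept = [words[int(rng.integers(len(words)))]]

    text = list(" ".join(kept))
    alphabet = string.ascii_lowercase
    out: list[str] = []
    for ch in text:
        if rng.random() < noise.char_edit_rate:
            op = rng.integers(3)
            if op == 0:  # substitute
                out.append(alphabet[int(rng.integers(26))])
            elif op == 1:  # insert before
                out.append(alphabet[int(rng.integers(26))])
                out.append(ch)
            # op == 2: delete
        else:
            out.append(ch)
    perturbed = normalize_text("".join(out))
    return perturbed if perturbed else label


def simulate_ontology(
    n_terms: int,
    max_children: int = 4,
    n_roots: int = 2,
    vocab: tuple[list[str], ...] | None = None,
    seed: int = 0,
) -> OntologyGraph:
    """Generate a rooted DAG ontology with labelled terms.

    Terms are added one at a time, each attached to one uniformly drawn
    parent (among same-branch terms with spare child capacity) and,
    with probability :data:`TWO_PARENT_PROB`, a second same-branch
    parent — producing diamond motifs.  Labels are 2–3 distinct words
    from the vocabulary of the term's root branch, so the top-level
    branches form disjoint lexical families; all labels are unique (a
    vocabulary too small to keep them unique raises
    :class:`GenerationError`).
    """
    if n_roots < 1 or n_terms < n_roots:
        raise ValueError("need n_terms >= n_roots >= 1")
    if max_children < 1:
        raise ValueError("max_children must be >= 1")
    vocabs = tuple(vocab) if vocab is not None else DEFAULT_VOCABS
    rng = np.random.default_rng(seed)

    terms: list[str] = []
    branch_of: dict[str, int] = {}
    labels: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    n_children: dict[str, int] = {}
    used_labels: set[str] = set()
    by_branch: dict[int, list[str]] = {}

    def make_label(branch: int) -> str:
        words = vocabs[branch % len(vocabs)]
        if len(words) < 4:
            raise GenerationError("branch vocabulary needs >= 4 words")
        head, modifiers = words[0], words[1:]
        for _ in range(200):
            k = int(rng.integers(2, 4))
            idx = rng.choice(len(modifiers), size=k, replace=False)
            label = " ".join([modifiers[i] for i in idx] + [head])
            if label not in used_labels:
                used_labels.add(label)
                return label
        raise GenerationError(
            f"vocabulary of branch {branch} too small for unique labels"
        )

    for i in range(n_terms):
        term = f"SYN:{i:04d}"
        if i < n_roots:
            branch = i
        else:
            branch = int(rng.integers(n_roots))
            candidates = [
                t for t in by_branch[branch]
                if n_children.get(t, 0) < max_children
            ]
            if not candidates:  # every same-branch term is saturated
                candidates = by_branch[branch]
            parent = candidates[int(rng.integers(len(candidates)))]
            edges.append((parent, term))
            n_children[parent] = n_children.get(parent, 0) + 1
            others = [t for t in by_branch[branch] if t != parent]
            if others and rng.random() < TWO_PARENT_PROB:
                second = others[int(rng.integers(len(others)))]
                edges.append((second, term))
                n_children[second] = n_children.get(second, 0) + 1
        terms.append(term)
        branch_of[term] = branch
        by_branch.setdefault(branch, []).append(term)
        labels[term] = make_label(branch)

    return OntologyGraph(edges, labels)


def simulate_gold(
    graph: OntologyGraph,
    n_queries: int,
    noise: NoiseConfig,
    broad_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a gold-mapping table of perturbed term labels.

    ``n_queries`` distinct terms are drawn; each query is a perturbed
    copy of its term's label.  With probability ``broad_fraction`` a
    record is promoted to a Broad mapping by re-assigning its mapped
    term to a uniformly drawn parent of the source term (terms without
    parents stay Exact).  Returns the gold table (columns ``query``,
    ``term``, ``mapping_type``) and a truth table additionally carrying
    the originating ``source_term`` of every query.
    """
    if not 0.0 <= broad_fraction <= 1.0:
        raise ValueError("broad_fraction must be in [0, 1]")
    terms = graph.terms
    if n_queries > len(terms):
        raise ValueError("n_queries exceeds the number of terms")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    chosen_idx = rng.choice(len(terms), size=n_queries, replace=False)
    chosen = [terms[i] for i in sorted(chosen_idx)]

    gold_rows = []
    truth_rows = []
    for term in chosen:
        query = perturb_label(graph.label(term), noise)
        mapped, mtype = term, "Exact"
        if rng.random() < broad_fraction:
            parents = graph.parents(term)
            if parents:
                mapped = parents[int(rng.integers(len(parents)))]
                mtype = "Broad"
        gold_rows.append((query, mapped, mtype))
        truth_rows.append((query, term, mapped, mtype))
    gold = pd.DataFrame(gold_rows, columns=["query", "term", "mapping_type"])
    truth = pd.DataFrame(
        truth_rows, columns=["query", "source_term", "term", "mapping_type"]
    )
    return gold, truth
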