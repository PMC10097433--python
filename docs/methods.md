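# Methods

## Problem and model

`traitmap` addresses two linked tasks. First, *trait-to-ontology
mapping*: given a free-text variable name from a population study and
an ontology of traits, rank the ontology's term labels by a
string-similarity backend and judge the ranked predictions not only by
exact identifier agreement with a manual gold mapping but by how close
each prediction sits to the gold term in the ontology graph. Second,
*direct trait-to-trait mapping*: compare methods through the full
pairwise score matrices they induce over a set of traits, without going
through an ontology at all.

The ontology is a rooted directed acyclic graph (edges parent → child)
with one normalized (lower-cased, whitespace-collapsed) label per term.
Multiple roots are permitted — real trait ontologies have several
top-level branches — and terms whose ancestries are disjoint are
maximally dissimilar.

### Batet similarity

With inclusive ancestor sets $A(\cdot)$ (a term is its own ancestor),
$U = A(a) \cup A(b)$ and $I = A(a) \cap A(b)$:

$\mathrm{sim}(a,b) = 1 - \log_2(1 + (|U|-|I|)/|U|)$.

The inclusive convention is required for $\mathrm{sim}(a,a) = 1$; the
log base is 2, matching the measure's published form. Disjoint
ancestries give $1 - \log_2 2 = 0$. The formula is exposed directly
(`batet_from_counts`) so that alternative implementations can be
cross-checked against it; the test suite verifies it against a
brute-force transitive-closure oracle on random DAGs. Ancestor sets are
memoized per term; the contract is repeatable results, not a
particular traversal order.

### Backends and orientation

Every scorer is wrapped as a `Backend` with a declared *orientation*:
similarity (higher = closer) or distance (lower = closer). All
consumers — ranking, evaluation, matrices — are orientation-aware, so
edit ratios, embedding cosines and model-inferred ontology distances
are interchangeable. All backends normalize their inputs the same way
labels are normalized; the choice to lower-case uniformly (rather than
only during gold-table curation) is recorded here so results can be
re-run both ways by swapping the normalizer.

* **Levenshtein ratio** uses insertion/deletion cost 1, substitution
  cost 2 — the python-Levenshtein `ratio` convention, computed as
  $2\,\mathrm{LCS}/(|s|+|t|)$ with a bit-parallel LCS. The both-empty
  case is defined as 1.0; one empty string gives 0 by the formula.
  Plain unit-cost ratios give different numbers; this is deliberate and
  tested against a quadratic dynamic-programming oracle.
* **Hashed character-n-gram embedder**: character n-grams (default
  lengths 3–4) hashed into 256 signed buckets (seeded, stable blake2
  hashing), weighted by term frequency × smoothed IDF fitted on a
  corpus (typically the ontology's labels), scored by cosine. It is a
  self-contained, deterministic embedding with fixed memory; externally
  trained sentence embedders enter the pipeline as exported vector
  tables instead (`load_vector_backend`). Identical corpus, config and
  seed give bit-identical scores.
* **Cosine of a zero vector** is defined as 0 with a warning rather
  than an error, keeping pipelines total on degenerate inputs.
* **Inferred-distance backends** wrap a stored (text, text) → score
  table, queried symmetrically (minimum over both orders). Model
  training itself is out of scope; the package produces the training
  data (below) and consumes any resulting pair-scorer.

### Ranking

Ranking is exhaustive over all term labels — correctness first; no
pruning or approximate nearest-neighbour stage. Ties are broken by term
identifier after the score, making rankings (and therefore exact-match
counts on tied labels) deterministic. "Top match" means the rank-1
candidate after tie-breaking. The two-stage hybrid re-scores the
stage-1 top-*x* shortlist with the stage-2 backend and reports stage-2
ordering only; with *x* equal to the index size it equals pure stage-2
ranking (a tested identity).

### Gold-table curation

Two protocols over EBI-style (query, term, mapping-type) tables, with
mapping types Exact / Broad / Narrow / Other normalized
case-insensitively:

1. *Ontology-eval*: drop all records of any query assigned more than
   one distinct term; lower-case; drop records whose query equals the
   mapped term's label (string identity after normalization — the
   identity notion is a design choice recorded here); drop terms absent
   from the loaded ontology; deduplicate. Order preserved.
2. *Exact-unique*: Exact records only, the same hygiene rules (without
   the label-identity drop — identity queries are informative when
   traits are compared to each other), then one query per distinct term
   and one term per query, first occurrence winning. The
   first-occurrence rule is a choice the source protocol leaves open;
   each filter logs per-rule removal counts so surviving totals can be
   audited against published dataset sizes.

Both filters are idempotent and always return a subset of the
lower-cased input (property-tested).

### Evaluation statistics

A query counts as exactly matched iff its rank-1 predicted term equals
the gold term by identifier. Thresholded counts use ≥ with exact
floating comparison. The top-N weighted average uses untruncated linear
weights $N, N-1, \dots, 1$ normalized by their sum; the per-N curve is
the mean over queries of per-query weighted averages (the only reading
that keeps curves comparable across methods with equal query counts),
and its N=1 point is definitionally the mean rank-1 Batet score.
Queries with fewer than N predictions are dropped from the N-th curve
point with a logged count by default (`on_short="raise"` restores the
strict contract). The two-proportion z-test is the pooled closed form
with normal tails; the KS test is two-sided with asymptotic p. Both are
two-sided and reported raw — no multiple-testing correction, matching
how such pairwise method comparisons are conventionally reported.

### Trait-to-trait matrices

Score matrices are symmetric by construction (each unordered pair
scored once); the diagonal is structurally excluded from every
statistic ("excluding self") — upper-triangle extraction is the only
path into downstream code. Distances are normalized to similarities by
negation, which preserves ranks without assuming a bounded transform;
normalization is idempotent. Cross-method comparison uses Spearman on
upper triangles and a Mantel permutation test: Pearson on upper
triangles, simultaneous row/column permutations of one matrix,
two-sided counting of $|r_{perm}| \ge |r_{obs}|$ with the observed
arrangement included in the null set (so $p \ge 1/(\text{perms}+1)$;
999 permutations by default, seeded). An exact mode enumerates all
$n!$ permutations for small matrices and is used to validate the
sampler. Clustering is average linkage on $\max(\text{sim}) -
\text{sim}$ dissimilarities (linkage exposed as a knob; the choice of
average linkage is a default, not a claim about the reference
analyses, which do not name theirs).

### Alignment training data

Entity-alignment pairs are (label, label, hop-distance) triples, with
hop distance the shortest path over the parent/child graph treated as
undirected, capped at `max_steps`. Sampling is balanced per distance
stratum (uniform within a stratum, seeded) to counter the natural
dominance of large distances; distance-0 pairs are self-pairs.
Shortfalls in thin strata are logged, not fatal. Every emitted
distance is re-verified against a breadth-first-search oracle in tests.

## Synthetic benchmark: what it emulates and what it does not

`simulate_ontology` grows a DAG by attaching each new term to one
uniformly chosen same-branch parent (capacity-capped at 4 children),
with probability 0.1 of a second same-branch parent — enough diamond
motifs to exercise ancestor-set logic beyond trees. Each root defines a
lexical family: labels are 2–3 modifier words from the branch
vocabulary plus the branch's head noun ("… disease" / "… measurement"),
mirroring the naming convention of real trait ontologies and planting
the disease-vs-measurement split that ontology-based clustering should
recover. Labels are unique by rejection sampling (failure raises rather
than silently colliding).

`simulate_gold` samples terms and perturbs their labels into queries:
synonym swaps from a bundled ~50-pair mini-thesaurus, then word drops,
then character edits, each by seeded draws; per-label random streams
make perturbation independent of call order. *Mild* noise is a 2%
per-character edit rate and nothing else — a typo-level gap under which
an edit-distance mapper should succeed almost always; *heavy* noise
(30% character edits, 10% word drops, 30% synonym swaps) approximates
genuinely re-worded variable names. Broad mappings are planted by
re-assigning a query's mapped term to a true parent of its source term.

What passing the synthetic benchmark does **not** show: real gold
tables contain multi-entity and negated queries, ICD-coded variables,
and curation errors, none of which the generator produces; real
ontology labels are not drawn from disjoint vocabularies, so real
cross-family lexical similarity is far higher than the planted
near-zero; and pretrained sentence embedders have failure modes (e.g.
generic-word dominance) the hashed n-gram stand-in does not share.
Synthetic results validate the machinery and its contracts, not
real-data accuracy levels.

## Problem sizes and numerical choices

The bundled benchmarks use a 200-term / 2-root ontology with 100 gold
queries (mapping benchmarks) and a 40-term instance (matrix and
clustering benchmarks); property suites use random DAGs of ≤ 50 terms
and 1 000-pair oracle comparisons — sizes at which exhaustive scoring
and permutation tests complete in seconds while still exercising every
code path. Scores are compared exactly where determinism is promised
(embedder rebuilds, CLI reruns) and to 1e-12 against oracles otherwise.
Matrix symmetry is enforced within 1e-9. Floats in CLI output are
printed with 12 significant digits so byte-level determinism is
auditable. Degenerate inputs are made total where a pipeline should
survive them (zero-vector cosine, no-path sentinel for disconnected
terms, empty-string ratio) and fatal where they signal corrupt input
(cycles, unlabelled edge terms, ragged vector tables, duplicate matrix
labels).

## Known limitations

* Matching is against primary labels only, not ontology synonyms;
  exact-match percentages on real data may differ from analyses that
  match synonyms too.
* Exhaustive ranking is O(queries × terms); fine for tens of thousands
  of labels, not engineered for millions.
* The Mantel variant (Pearson, 999 simultaneous permutations) and the
  clustering linkage are stated defaults; analyses that used other
  variants are comparable qualitatively, not numerically.
* The mini-thesaurus is small and English-only; synonym noise is a
  caricature of real lexical variation.
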