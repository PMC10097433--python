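"""Direct trait-to-trait comparison via pairwise score matrices.

Each backend yields a symmetric trait x trait matrix of its scores; an
ontology yields the analogous Batet matrix over the traits' manually
mapped terms.  Matrices are compared across methods with Spearman rank
correlation of their (orientation-normalized) upper triangles and with
the Mantel permutation test, and summarized by average-linkage
hierarchical clustering of ``1 - similarity`` dissimilarities.

The diagonal is structurally excluded from every statistic ("excluding
self"): upper-triangle extraction is the only path into correlation or
clustering code.  Distance-oriented matrices are converted to
similarity by negation, which preserves ranks without assuming a
bounded transform; normalization is idempotent.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .backends import Backend, Orientation
from .ontology import OntologyGraph, normalize_text

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric pairwise score matrix over a fixed item order.

    The diagonal is set to the orientation's best value (1 for
    similarity, 0 for distance) but carries no information: all
    statistics read only the strict upper triangle.
    """

    items: tuple[str, ...]
    values: np.ndarray
    orientation: Orientation
    method_name: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} items"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("matrix is not symmetric")
        if len(set(self.items)) != n:
            raise ValueError("duplicate item identifiers")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n(self) -> int:
        return len(self.items)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def as_similarity(self) -> "ScoreMatrix":
        """Orientation-normalized copy: distances are negated into
        similarities; similarity matrices pass through unchanged (so
        normalizing twice equals normalizing once)."""
        if self.orientation is Orientation.SIMILARITY:
            return self
        values = -self.values.copy()
        if self.n > 1:  # diagonal carries no information; keep it best-valued
            np.fill_diagonal(values, -np.inf)
            np.fill_diagonal(values, values.max())
        return replace(
            self, values=values, orientation=Orientation.SIMILARITY
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.items, columns=self.items)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        orientation: Orientation = Orientation.SIMILARITY,
        method_name: str = "",
    ) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(
            items=tuple(str(i) for i in df.index),
            values=df.to_numpy(dtype=float),
            orientation=orientation,
            method_name=method_name or str(path),
        )


def pairwise_score_matrix(backend: Backend, traits: Sequence[str]) -> ScoreMatrix:
    """Backend scores for every unordered pair of traits (computed once
    per pair, so the matrix is symmetric by construction).

    Traits are normalized first; duplicates after normalization are
    rejected because they would make matrix labels ambiguous.
    """
    norm = [normalize_text(t) for t in traits]
    if len(norm) < 2:
        raise ValueError("need at least two traits")
    dupes = {t for t in norm if norm.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate traits after normalization: {sorted(dupes)}")
    n = len(norm)
    best = 1.0 if backend.orientation.higher_is_closer else 0.0
    values = np.full((n, n), best, dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        s = backend.scorer(norm[i], norm[j])
        values[i, j] = values[j, i] = s
    return ScoreMatrix(
        items=tuple(norm),
        values=values,
        orientation=backend.orientation,
        method_name=backend.name,
    )


def batet_matrix(graph: OntologyGraph, terms: Sequence[str]) -> ScoreMatrix:
    """Batet similarity for every pair of ontology terms (similarity
    orientation, diagonal 1)."""
    terms = list(terms)
    n = len(terms)
    values = np.eye(n, dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        s = graph.batet_similarity(terms[i], terms[j])
        values[i, j] = values[j, i] = s
    return ScoreMatrix(
        items=tuple(terms),
        values=values,
        orientation=Orientation.SIMILARITY,
        method_name="batet",
    )


def _aligned_triangles(a: ScoreMatrix, b: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    if a.items != b.items:
        raise ValueError(
            f"item lists differ between {a.method_name!r} and {b.method_name!r}"
        )
    return a.as_similarity().upper_triangle(), b.as_similarity().upper_triangle()


def method_spearman(a: ScoreMatrix, b: ScoreMatrix) -> float:
    """Spearman rank correlation between the orientation-normalized
    strict upper triangles of two matrices over the same items."""
    x, y = _aligned_triangles(a, b)
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant upper triangle: correlation undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel(
    a: ScoreMatrix,
    b: ScoreMatrix,
    permutations: int | None = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two matrices over the same items.

    The statistic is the Pearson correlation of the strict upper
    triangles (after orientation normalization).  The two-sided p-value
    permutes the rows and columns of ``b`` simultaneously and counts
    permutations with ``|r| >= |r_observed|``; the observed arrangement
    is included in the null set, so p is never below
    ``1 / (permutations + 1)``.  ``permutations=None`` enumerates all
    ``n!`` permutations exactly (items count must stay small).
    """
    x, _ = _aligned_triangles(a, b)
    b_sim = b.as_similarity().values
    n = a.n
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(x, b_sim[iu])

    if permutations is None:
        if math.factorial(n) > 50_000:
            raise ValueError("exhaustive Mantel limited to small matrices")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        r_null = np.array([_pearson(x, b_sim[np.ix_(p, p)][iu]) for p in perms])
        p_value = float(np.mean(np.abs(r_null) >= abs(r_obs) - 1e-12))
        return r_obs, p_value

    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    hits = 1  # the observed arrangement counts against itself
    for _ in range(permutations):
        p = rng.permutation(n)
        r_perm = _pearson(x, b_sim[np.ix_(p, p)][iu])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, hits / (permutations + 1)


def cluster_order(
    m: ScoreMatrix, linkage_method: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of a score matrix.

    The matrix is orientation-normalized and turned into the
    dissimilarity ``max(sim) - sim`` (zero diagonal); linkage is
    ``average`` by default.  Returns the deterministic dendrogram leaf
    order (as item names) and the scipy linkage matrix.
    """
    sim = m.as_similarity()
    if sim.n == 1:
        return [sim.items[0]], np.empty((0, 4))
    values = sim.values.copy()
    tri = sim.upper_triangle()
    dis = float(tri.max()) - values
    np.fill_diagonal(dis, 0.0)
    dis = np.maximum(dis, 0.0)
    condensed = squareform(dis, checks=False)
    linkage = hierarchy.linkage(condensed, method=linkage_method)
    leaves = hierarchy.leaves_list(linkage)
    return [sim.items[i] for i in leaves], linkage


def top_split(m: ScoreMatrix, linkage_method: str = "average") -> tuple[set[str], set[str]]:
    """The two-cluster partition at the dendrogram's top split."""
    _, linkage = cluster_order(m, linkage_method)
    if linkage.shape[0] == 0:
        raise ValueError("need at least two items for a split")
    assignment = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    left = {item for item, c in zip(m.items, assignment) if c == 1}
    right = {item for item, c in zip(m.items, assignment) if c == 2}
    return left, right
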