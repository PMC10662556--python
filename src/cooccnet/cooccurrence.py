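"""The co-occurrence probability distance between genes.

For each gene the table induces, per categorical attribute, an empirical
conditional distribution P(value | gene). The distance between two genes
on one attribute is the subset-maximization statistic

    delta(x, y) = max_w [ P_x(w) + P_y(~w) ] - 1

where w ranges over all subsets of the attribute's categories and ~w is
the complement. The maximum is attained by the set of categories where
P_x(v) >= P_y(v), which gives the closed form

    delta(x, y) = sum_v max(P_x(v), P_y(v)) - 1 = 1/2 * sum_v |P_x(v) - P_y(v)|,

i.e. the total-variation distance between the two conditional profiles.
The overall gene distance is the mean over the configured attributes. It
lies in [0, 1], is symmetric, vanishes exactly when all per-attribute
profiles coincide, and (being an average of total-variation distances)
satisfies the triangle inequality.

Two implementations coexist deliberately:

* ``attribute_distance`` — the closed-form fast path, exact rational
  arithmetic on :class:`~fractions.Fraction` profiles;
* ``attribute_distance_bruteforce`` — literal enumeration of all 2^K
  subsets, kept as an independent oracle for testing (guarded against
  large vocabularies).

``pairwise_distance_matrix`` is a vectorized float64 path for all-pairs
computation at scale; it is cross-checked against the exact pairwise
path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    CooccnetError,
    UnknownAttributeError,
    UnknownGeneError,
    VocabularyTooLargeError,
)
from .mutation_data import MutationTable

#: Hard cap for brute-force subset enumeration (2^20 subsets).
BRUTEFORCE_MAX_CATEGORIES = 20


@dataclass(frozen=True)
class ConditionalProfile:
    """Empirical distribution P(value | gene) for one gene and attribute.

    Probabilities are exact rationals (count / support); categories the
    gene never shows are simply absent and read as probability zero —
    no smoothing or pseudocounts are applied.
    """

    gene: str
    attribute: str
    probs: Mapping[str, Fraction]
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise CooccnetError("profile support must be >= 1")
        total = sum(self.probs.values())
        if abs(total - 1) > 1e-12 or any(p < 0 for p in self.probs.values()):
            raise CooccnetError(f"profile probabilities sum to {total}, not 1")

    def prob(self, category: str) -> Fraction:
        return self.probs.get(category, Fraction(0))

    def mass(self, subset: frozenset[str]) -> Fraction:
        """P(w): total probability of a category subset."""
        return sum((self.probs.get(v, Fraction(0)) for v in subset), Fraction(0))


@dataclass(frozen=True)
class AttributeDistanceResult:
    """Distance on one attribute; ``argmax_subset`` only on the brute-force path."""

    value: Fraction | float
    argmax_subset: frozenset[str] | None = None


def conditional_profile(
    table: MutationTable, gene: str, attribute: str
) -> ConditionalProfile:
    """Compute P(value | gene) for one attribute from per-row frequencies."""
    if attribute not in table.attribute_names:
        raise UnknownAttributeError(attribute)
    if gene not in table.gene_index:
        raise UnknownGeneError(gene)
    counts: dict[str, int] = {}
    support = 0
    for rec in table.records:
        if rec.gene == gene:
            support += 1
            v = rec.attributes[attribute]
            counts[v] = counts.get(v, 0) + 1
    probs = {v: Fraction(c, support) for v, c in sorted(counts.items())}
    return ConditionalProfile(gene=gene, attribute=attribute, probs=probs, support=support)


def _check_match(p: ConditionalProfile, q: ConditionalProfile) -> None:
    if p.attribute != q.attribute:
        raise CooccnetError(
            f"attribute mismatch: {p.attribute!r} vs {q.attribute!r}"
        )


def attribute_distance(
    p: ConditionalProfile, q: ConditionalProfile
) -> AttributeDistanceResult:
    """Closed-form co-occurrence distance: sum_v max(p[v], q[v]) - 1.

    Exact when the profiles carry :class:`~fractions.Fraction` values.
    """
    _check_match(p, q)
    union = set(p.probs) | set(q.probs)
    value = sum((max(p.prob(v), q.prob(v)) for v in union), Fraction(0)) - 1
    return AttributeDistanceResult(value=value)


def attribute_distance_bruteforce(
    p: ConditionalProfile, q: ConditionalProfile
) -> AttributeDistanceResult:
    """Literal subset enumeration of max_w [P_x(w) + P_y(~w)] - 1.

    Enumerates all 2^K subsets of the union vocabulary; exponential, so
    refused beyond ``BRUTEFORCE_MAX_CATEGORIES`` categories. Ties between
    maximizing subsets are broken by smallest cardinality, then by
    lexicographic category order, so the reported argmax ω is
    deterministic. Retained as the independent oracle for the fast path.
    """
    _check_match(p, q)
    union = sorted(set(p.probs) | set(q.probs))
    if len(union) > BRUTEFORCE_MAX_CATEGORIES:
        raise VocabularyTooLargeError(
            f"{len(union)} categories would need 2^{len(union)} subsets; "
            "use attribute_distance instead"
        )
    full = frozenset(union)
    best_value: Fraction | None = None
    best_subset: tuple[str, ...] | None = None
    for k in range(len(union) + 1):
        for combo in combinations(union, k):
            w = frozenset(combo)
            value = p.mass(w) + q.mass(full - w) - 1
            if best_value is None or value > best_value:
                best_value, best_subset = value, combo
            # combinations() yields size-then-lex order, so the first
            # maximizer seen is already the canonical tie-break winner.
    assert best_value is not None and best_subset is not None
    return AttributeDistanceResult(value=best_value, argmax_subset=frozenset(best_subset))


def gene_distance(table: MutationTable, x: str, y: str) -> Fraction:
    """Mean co-occurrence distance over all configured attributes.

    The divisor is the number of categorical attributes (the gene column
    itself is not an attribute of the comparison).
    """
    for g in (x, y):
        if g not in table.gene_index:
            raise UnknownGeneError(g)
    total = Fraction(0)
    for attr in table.attribute_names:
        px = conditional_profile(table, x, attr)
        py = conditional_profile(table, y, attr)
        total += attribute_distance(px, py).value
    return total / len(table.attribute_names)


@dataclass
class DistanceMatrix:
    """Symmetric gene-by-gene distance matrix with a deterministic index."""

    genes: list[str]
    values: np.ndarray
    attributes_used: list[str]
    divisor_m_minus_1: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise CooccnetError("matrix shape does not match gene list")

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise UnknownGeneError(gene) from None

    def distance(self, x: str, y: str) -> float:
        return float(self.values[self.index_of(x), self.index_of(y)])

    def to_tsv(self, path: str | Path) -> None:
        """Full symmetric matrix, gene names as header row and column."""
        df = pd.DataFrame(self.values, index=self.genes, columns=self.genes)
        df.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        if genes != [str(c) for c in df.columns]:
            raise CooccnetError("matrix row and column gene names differ")
        return cls(
            genes=genes,
            values=df.to_numpy(dtype=float),
            attributes_used=[],
            divisor_m_minus_1=0,
        )

    def edge_list(self, threshold: float = 1.0) -> pd.DataFrame:
        """Long format: one row per unordered pair with distance <= threshold."""
        rows = []
        for i, j in combinations(range(len(self.genes)), 2):
            d = float(self.values[i, j])
            if d <= threshold + 1e-9:
                rows.append((self.genes[i], self.genes[j], d, 1.0 - d))
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "distance", "similarity"]
        )


def _profile_matrix(
    frame: pd.DataFrame, genes: Sequence[str], attribute: str
) -> np.ndarray:
    """Row-normalized gene x category count matrix for one attribute."""
    counts = pd.crosstab(frame["gene"], frame[attribute])
    counts = counts.reindex(index=genes, fill_value=0)
    probs = counts.to_numpy(dtype=float)
    return probs / probs.sum(axis=1, keepdims=True)


def pairwise_distance_matrix(table: MutationTable) -> DistanceMatrix:
    """All-pairs gene distance matrix (vectorized float path).

    Genes are sorted lexicographically; per attribute the conditional
    profiles are assembled once into a gene x category matrix and all
    pairs evaluated as half the L1 distance between rows. The result is
    symmetric with an exactly-zero diagonal and is independent of record
    order.
    """
    if len(table.gene_index) < 2:
        raise CooccnetError("need at least 2 genes for a distance matrix")
    genes = list(table.gene_index)  # already sorted
    frame = pd.DataFrame(
        {
            "gene": [r.gene for r in table.records],
            **{
                a: [r.attributes[a] for r in table.records]
                for a in table.attribute_names
            },
        }
    )
    acc = np.zeros(len(genes) * (len(genes) - 1) // 2)
    for attr in table.attribute_names:
        probs = _profile_matrix(frame, genes, attr)
        acc += 0.5 * pdist(probs, metric="cityblock")
    acc /= len(table.attribute_names)
    values = squareform(np.clip(acc, 0.0, 1.0))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        genes=genes,
        values=values,
        attributes_used=list(table.attribute_names),
        divisor_m_minus_1=len(table.attribute_names),
    )
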