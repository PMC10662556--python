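"""Shared fixtures: the 4-row worked-example table and random-table builders."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from cooccnet import MutationRecord, MutationTable

#: The worked example: four point mutations over two genes.
WORKED_ROWS = [
    ("FAM171B", "Missense", "AA→AC"),
    ("FAM171B", "Nonsense", "GG→GT"),
    ("FAM171B", "Missense", "GG→GA"),
    ("ABCA6", "Missense", "GG→GT"),
]

ATTRS = ["mutation_type", "nucleotide_change"]

MUTATION_TYPES = ["Missense", "Nonsense", "RNA", "Silent", "Splice_Site", "Nonstop"]
NUCLEOTIDE_CHANGES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]  # the 12 single-base substitutions


def make_table(rows: list[tuple[str, str, str]]) -> MutationTable:
    return MutationTable(
        records=[
            MutationRecord(gene=g, attributes={"mutation_type": m, "nucleotide_change": n})
            for g, m, n in rows
        ],
        attribute_names=list(ATTRS),
    )


@pytest.fixture
def worked_example_table() -> MutationTable:
    rows = [(g, m, n.replace("→", ">")) for g, m, n in WORKED_ROWS]
    return make_table(rows)


@pytest.fixture
def worked_example_tsv(tmp_path):
    """The worked example written as a TSV file, with unicode arrows."""
    path = tmp_path / "worked.tsv"
    lines = ["gene\tmutation_type\tnucleotide_change"]
    lines += [f"{g}\t{m}\t{n}" for g, m, n in WORKED_ROWS]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def random_table(
    rng: np.random.Generator, n_genes: int = 8, n_records: int = 25
) -> MutationTable:
    """A random mutation table over the standard vocabularies."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    rows = []
    # ensure every gene appears at least once
    for k in range(n_records):
        g = genes[k] if k < n_genes else genes[rng.integers(n_genes)]
        rows.append(
            (
                g,
                MUTATION_TYPES[rng.integers(len(MUTATION_TYPES))],
                NUCLEOTIDE_CHANGES[rng.integers(len(NUCLEOTIDE_CHANGES))],
            )
        )
    return make_table(rows)


def random_profile_pair(rng: np.random.Generator, max_categories: int = 12):
    """Two random rational profiles on a shared attribute, overlapping supports."""
    from cooccnet import ConditionalProfile

    k = int(rng.integers(1, max_categories + 1))
    cats = [f"c{i}" for i in range(k)]

    def draw() -> ConditionalProfile:
        support = int(rng.integers(1, 30))
        counts = rng.multinomial(support, np.ones(k) / k)
        probs = {
            c: Fraction(int(n), support) for c, n in zip(cats, counts) if n > 0
        }
        return ConditionalProfile(
            gene="g", attribute="a", probs=probs, support=support
        )

    return draw(), draw()
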