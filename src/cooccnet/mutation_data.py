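"""Reading, validating and normalizing somatic mutation tables.

The co-occurrence distance consumes a flat table with one row per observed
point mutation: a gene identifier plus one categorical value per configured
attribute (by default *mutation type* and *nucleotide change*). Two input
dialects are supported:

* a minimal tab-separated table with a header row (``read_tsv``), and
* MAF (Mutation Annotation Format, as distributed by TCGA), restricted to
  single-nucleotide substitutions (``read_maf``).

Duplicate rows are deliberately preserved: the conditional probabilities
downstream are per-row frequencies, so every recurrence of the same
mutation counts. Sample identity is ignored — mutations are pooled per
gene across samples.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigurationError,
    DataRowError,
    EmptyInputError,
)

logger = logging.getLogger(__name__)

#: Default role → column-name mapping for the minimal TSV dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "gene": "gene",
    "mutation_type": "mutation_type",
    "nucleotide_change": "nucleotide_change",
}

#: The four DNA bases; point mutations are substitutions within this set.
BASES = frozenset("ACGT")

#: Default Variant_Classification → mutation-type vocabulary (six classes).
#: Keys are matched case-insensitively; unmapped classes are dropped with a
#: logged count.
DEFAULT_CLASSIFICATION_MAP: dict[str, str] = {
    "missense_mutation": "Missense",
    "nonsense_mutation": "Nonsense",
    "rna": "RNA",
    "silent": "Silent",
    "splice_site": "Splice_Site",
    "nonstop_mutation": "Nonstop",
}

# Arrow variants seen in the wild ("→", "->", ">") are canonicalized to ">"
# with surrounding whitespace removed, so "GG → GT" and "GG>GT" are one
# category.
_ARROW_RE = re.compile(r"\s*(?:→|->|>)\s*")


def canonicalize_change(value: str) -> str:
    """Normalize arrow notation inside a nucleotide-change string."""
    return _ARROW_RE.sub(">", value.strip())


def derive_nucleotide_change(ref: str, alt: str) -> str:
    """Return the ``"REF>ALT"`` category for a single-base substitution.

    There are exactly 12 possible outputs (ordered pairs of distinct bases
    over {A, C, G, T}).

    Raises
    ------
    DataRowError
        If either allele is not a single base in {A, C, G, T}, or the
        alleles are equal (no change is not a mutation).
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise DataRowError(
            f"not a single-nucleotide substitution: {ref!r} -> {alt!r}"
        )
    if ref == alt:
        raise DataRowError(f"reference and alternate allele are equal: {ref!r}")
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class MutationRecord:
    """One observed point mutation: a gene plus categorical attribute values."""

    gene: str
    attributes: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.gene.strip():
            raise DataRowError("blank gene identifier")
        for name, value in self.attributes.items():
            if not str(value).strip():
                raise DataRowError(f"blank value for attribute {name!r}")


@dataclass
class MutationTable:
    """Ordered collection of mutation records plus derived bookkeeping.

    ``vocabulary`` maps each attribute to the sorted tuple of categories
    actually observed; ``gene_index`` is the sorted list of distinct genes.
    Both are recomputed from the records at construction time, so they can
    never drift out of sync.
    """

    records: list[MutationRecord]
    attribute_names: list[str]
    vocabulary: dict[str, tuple[str, ...]] = field(init=False)
    gene_index: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.attribute_names:
            raise ConfigurationError("at least one attribute is required")
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise ConfigurationError("duplicate attribute names")
        if not self.records:
            raise EmptyInputError("mutation table has no records")
        vocab: dict[str, set[str]] = {a: set() for a in self.attribute_names}
        genes: set[str] = set()
        for rec in self.records:
            genes.add(rec.gene)
            for a in self.attribute_names:
                try:
                    vocab[a].add(rec.attributes[a])
                except KeyError:
                    raise DataRowError(
                        f"record for {rec.gene!r} lacks attribute {a!r}"
                    ) from None
        self.vocabulary = {a: tuple(sorted(vocab[a])) for a in self.attribute_names}
        self.gene_index = sorted(genes)

    def __len__(self) -> int:
        return len(self.records)

    def records_for(self, gene: str) -> list[MutationRecord]:
        return [r for r in self.records if r.gene == gene]


def _clean_row(
    gene: str,
    values: Mapping[str, str],
    line: int,
    lenient: bool,
) -> MutationRecord | None:
    gene = gene.strip()
    cleaned = {}
    for name, v in values.items():
        v = v.strip()
        if name == "nucleotide_change":
            v = canonicalize_change(v)
        cleaned[name] = v
    try:
        return MutationRecord(gene=gene, attributes=cleaned)
    except DataRowError as exc:
        if lenient:
            logger.warning("skipping line %d: %s", line, exc)
            return None
        raise DataRowError(str(exc), line=line) from None


def read_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    lenient: bool = False,
) -> MutationTable:
    """Read a minimal mutation TSV into a :class:`MutationTable`.

    ``column_map`` maps roles to column names; the ``gene`` role is
    required and every other role becomes a categorical attribute (in
    mapping order). Duplicate rows are preserved. In strict mode (default)
    a blank gene or attribute aborts with the offending line number; with
    ``lenient=True`` such rows are skipped with a warning.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    if "gene" not in column_map:
        raise ConfigurationError("column_map must define the 'gene' role")
    attribute_roles = [r for r in column_map if r != "gene"]
    if not attribute_roles:
        raise ConfigurationError("column_map must define at least one attribute role")

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EmptyInputError(f"{path} is empty") from None
        header = [h.strip() for h in header]
        col_idx: dict[str, int] = {}
        for role, col in column_map.items():
            try:
                col_idx[role] = header.index(col)
            except ValueError:
                raise ConfigurationError(
                    f"column {col!r} (role {role!r}) not found in header of {path}"
                ) from None
        records: list[MutationRecord] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                gene = row[col_idx["gene"]]
                values = {role: row[col_idx[role]] for role in attribute_roles}
            except IndexError:
                if lenient:
                    logger.warning("skipping short line %d", line_no)
                    continue
                raise DataRowError("too few columns", line=line_no) from None
            rec = _clean_row(gene, values, line_no, lenient)
            if rec is not None:
                records.append(rec)
    if not records:
        raise EmptyInputError(f"{path} contains no data rows")
    return MutationTable(records=records, attribute_names=attribute_roles)


def write_tsv(
    table: MutationTable,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a table back to TSV; re-reading yields an identical table."""
    column_map = dict(column_map or {})
    cols = [column_map.get("gene", "gene")] + [
        column_map.get(a, a) for a in table.attribute_names
    ]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for rec in table.records:
            writer.writerow(
                [rec.gene] + [rec.attributes[a] for a in table.attribute_names]
            )


@dataclass
class MafFilterReport:
    """Accounting of MAF rows: kept + dropped categories = data rows in."""

    rows_in: int = 0
    records_out: int = 0
    dropped_non_snv: int = 0
    dropped_unmapped_class: int = 0

    def balanced(self) -> bool:
        return (
            self.records_out + self.dropped_non_snv + self.dropped_unmapped_class
            == self.rows_in
        )


@dataclass
class MafConfig:
    """Options for MAF ingestion.

    ``classification_map`` maps Variant_Classification values
    (case-insensitively) onto the mutation-type vocabulary; unmapped
    classes are dropped and counted.
    """

    classification_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASSIFICATION_MAP)
    )

    def normalized_map(self) -> dict[str, str]:
        return {k.lower(): v for k, v in self.classification_map.items()}


_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Reference_Allele", "Tumor_Seq_Allele2")


def read_maf(
    path: str | Path,
    config: MafConfig | None = None,
) -> tuple[MutationTable, MafFilterReport]:
    """Read a MAF file, keeping single-nucleotide substitutions only.

    A row is kept when both alleles are single distinct bases in
    {A, C, G, T}; when a ``Variant_Type`` column is present it must also
    read ``SNP``. The mutation type comes from ``Variant_Classification``
    through ``config.classification_map``; the nucleotide change is
    derived from the allele pair. Comment lines starting with ``#`` are
    skipped.

    Returns the table and a :class:`MafFilterReport` with drop counts.
    """
    config = config or MafConfig()
    class_map = config.normalized_map()
    path = Path(path)
    report = MafFilterReport()
    records: list[MutationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        reader = csv.reader(rows, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise EmptyInputError(f"{path} is empty") from None
        for col in _MAF_REQUIRED:
            if col not in header:
                raise ConfigurationError(f"MAF is missing required column {col!r}")
        idx = {c: header.index(c) for c in _MAF_REQUIRED}
        vt_idx = header.index("Variant_Type") if "Variant_Type" in header else None
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            report.rows_in += 1
            ref = row[idx["Reference_Allele"]].strip().upper()
            alt = row[idx["Tumor_Seq_Allele2"]].strip().upper()
            if vt_idx is not None and row[vt_idx].strip().upper() != "SNP":
                report.dropped_non_snv += 1
                continue
            try:
                change = derive_nucleotide_change(ref, alt)
            except DataRowError:
                report.dropped_non_snv += 1
                continue
            classification = row[idx["Variant_Classification"]].strip()
            mtype = class_map.get(classification.lower())
            if mtype is None:
                report.dropped_unmapped_class += 1
                continue
            records.append(
                MutationRecord(
                    gene=row[idx["Hugo_Symbol"]].strip(),
                    attributes={"mutation_type": mtype, "nucleotide_change": change},
                )
            )
            report.records_out += 1
    if report.dropped_unmapped_class:
        logger.info(
            "dropped %d rows with unmapped Variant_Classification",
            report.dropped_unmapped_class,
        )
    if not records:
        raise EmptyInputError(
            f"no records survived MAF filters: {report.rows_in} rows in, "
            f"{report.dropped_non_snv} non-SNV, "
            f"{report.dropped_unmapped_class} unmapped class"
        )
    table = MutationTable(
        records=records, attribute_names=["mutation_type", "nucleotide_change"]
    )
    return table, report
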