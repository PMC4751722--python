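"""Reading, writing and validation of microsatellite genotype tables.

Genotypes of polyploid individuals are observed as *allele phenotypes*: the
set of distinct fragment lengths amplified at a locus, with no copy-number
(dosage) information.  All containers here therefore store allele sets, never
multisets.  The canonical on-disk format is a long-format TSV with one allele
per row (columns ``sample``, ``role``, ``locus``, ``allele``); a wide format
with semicolon-separated alleles per locus column is accepted on read only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Role",
    "LocusGenotype",
    "IndividualRecord",
    "GenotypeTable",
    "ValidationReport",
    "GenotypeFormatError",
    "read_genotype_table",
    "write_genotype_table",
    "validate_cross_table",
    "read_measurement_table",
]

log = logging.getLogger(__name__)


class GenotypeFormatError(ValueError):
    """Raised when a genotype file or table violates the format contract."""


class Role(str, Enum):
    DAM = "DAM"
    SIRE = "SIRE"
    OFFSPRING = "OFFSPRING"


@dataclass(frozen=True)
class LocusGenotype:
    """Observed allele phenotype at one locus: distinct lengths in base pairs."""

    locus_id: str
    alleles: frozenset[int]

    def __post_init__(self) -> None:
        alleles = frozenset(int(a) for a in self.alleles)
        if not alleles:
            raise GenotypeFormatError(
                f"locus {self.locus_id!r}: a genotyped locus needs >=1 allele"
            )
        if any(a <= 0 for a in alleles):
            raise GenotypeFormatError(
                f"locus {self.locus_id!r}: allele lengths must be positive integers"
            )
        object.__setattr__(self, "alleles", alleles)

    def sorted_alleles(self) -> list[int]:
        return sorted(self.alleles)


@dataclass
class IndividualRecord:
    """One individual with its role in the cross and per-locus genotypes.

    A locus absent from ``genotypes`` is a missing genotype, not an error.
    ``ploidy_label`` is an optional functional-ploidy annotation (e.g. from
    flow cytometry); it is not serialised in the genotype TSV and is excluded
    from equality comparisons.
    """

    sample_id: str
    role: Role
    genotypes: dict[str, LocusGenotype]
    ploidy_label: int | None = field(default=None, compare=False)

    def alleles_at(self, locus: str) -> frozenset[int]:
        """Observed allele set at ``locus``; empty frozenset if missing."""
        g = self.genotypes.get(locus)
        return g.alleles if g is not None else frozenset()


@dataclass
class GenotypeTable:
    """A validated cross table: exactly one dam, one sire, any offspring.

    Individuals are canonically ordered (dam, sire, offspring by sample id)
    and ``loci`` is the sorted union of loci over all individuals, so that
    writing and re-reading a table is the identity.
    """

    individuals: list[IndividualRecord]
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ind.sample_id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            raise GenotypeFormatError("duplicate sample ids in table")
        dams = [i for i in self.individuals if i.role is Role.DAM]
        sires = [i for i in self.individuals if i.role is Role.SIRE]
        if len(dams) != 1 or len(sires) != 1:
            raise GenotypeFormatError(
                f"table must contain exactly one DAM and one SIRE "
                f"(found {len(dams)} DAM, {len(sires)} SIRE)"
            )
        offspring = sorted(
            (i for i in self.individuals if i.role is Role.OFFSPRING),
            key=lambda i: i.sample_id,
        )
        self.individuals = [dams[0], sires[0], *offspring]
        union: set[str] = set()
        for ind in self.individuals:
            union.update(ind.genotypes)
        self.loci = sorted(union)

    @property
    def dam(self) -> IndividualRecord:
        return self.individuals[0]

    @property
    def sire(self) -> IndividualRecord:
        return self.individuals[1]

    @property
    def offspring(self) -> list[IndividualRecord]:
        return self.individuals[2:]

    def individual(self, sample_id: str) -> IndividualRecord:
        for ind in self.individuals:
            if ind.sample_id == sample_id:
                return ind
        raise KeyError(sample_id)


@dataclass
class ValidationReport:
    """Report-only flags from :func:`validate_cross_table`.

    uninformative_loci
        loci where the parents share every allele, so no private allele can
        exist; these are excluded from the private-allele battery.
    non_parental
        (sample, locus, allele) triples where an offspring carries an allele
        absent from both parents (mutation or genotyping artefact).
    missing
        (sample, locus) pairs with no genotype.
    """

    uninformative_loci: list[str] = field(default_factory=list)
    non_parental: list[tuple[str, str, int]] = field(default_factory=list)
    missing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.uninformative_loci or self.non_parental or self.missing)


_LONG_COLUMNS = ["sample", "role", "locus", "allele"]


def _parse_role(raw: str, where: str) -> Role:
    try:
        return Role(str(raw).strip().upper())
    except ValueError:
        raise GenotypeFormatError(f"{where}: unknown role {raw!r}") from None


def _parse_allele(raw: object, where: str) -> int:
    s = str(raw).strip()
    try:
        v = int(float(s)) if float(s) == int(float(s)) else None
    except ValueError:
        v = None
    if v is None:
        raise GenotypeFormatError(f"{where}: non-numeric allele {raw!r}")
    return v


def _table_from_long(df: pd.DataFrame, source: str) -> GenotypeTable:
    seen: dict[str, tuple[Role, dict[str, set[int]]]] = {}
    order: list[str] = []
    dup = 0
    for i, row in enumerate(df.itertuples(index=False)):
        where = f"{source} row {i + 2}"  # 1-based + header
        sample = str(row.sample).strip()
        role = _parse_role(row.role, where)
        locus = str(row.locus).strip()
        allele = _parse_allele(row.allele, where)
        if sample not in seen:
            seen[sample] = (role, {})
            order.append(sample)
        elif seen[sample][0] is not role:
            raise GenotypeFormatError(f"{where}: conflicting roles for {sample!r}")
        alleles = seen[sample][1].setdefault(locus, set())
        if allele in alleles:
            dup += 1
        alleles.add(allele)
    if dup:
        log.warning("%s: merged %d duplicate (sample, locus, allele) rows", source, dup)
    individuals = [
        IndividualRecord(
            sample_id=s,
            role=seen[s][0],
            genotypes={
                loc: LocusGenotype(loc, frozenset(a)) for loc, a in seen[s][1].items()
            },
        )
        for s in order
    ]
    return GenotypeTable(individuals)


def _table_from_wide(df: pd.DataFrame, source: str) -> GenotypeTable:
    loci = [c for c in df.columns if c not in ("sample", "role")]
    rows = []
    for i, row in df.iterrows():
        for locus in loci:
            cell = row[locus]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            for raw in str(cell).split(";"):
                raw = raw.strip()
                if raw:
                    rows.append((row["sample"], row["role"], locus, raw))
    long_df = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    return _table_from_long(long_df, source)


def read_genotype_table(path: str | Path, dialect: str = "auto") -> GenotypeTable:
    """Read a genotype TSV (long or wide) into a validated :class:`GenotypeTable`.

    ``dialect`` is ``"long"``, ``"wide"`` or ``"auto"`` (sniff by columns:
    an ``allele`` column means long format).  Duplicate (sample, locus,
    allele) rows are merged with a logged warning; parsing is independent of
    row order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if dialect == "auto":
        dialect = "long" if "allele" in cols else "wide"
    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in cols]
        if missing:
            raise GenotypeFormatError(f"{path}: missing required columns {missing}")
        return _table_from_long(df[_LONG_COLUMNS], str(path))
    if dialect == "wide":
        if "sample" not in cols or "role" not in cols:
            raise GenotypeFormatError(f"{path}: wide format needs sample and role columns")
        return _table_from_wide(df, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write ``table`` as canonical long-format TSV.

    Row order is deterministic: dam, sire, offspring by sample id; within a
    sample, loci sorted, alleles ascending.  Two calls on the same table
    produce byte-identical files.
    """
    path = Path(path)
    lines = ["\t".join(_LONG_COLUMNS)]
    for ind in table.individuals:
        for locus in sorted(ind.genotypes):
            for allele in ind.genotypes[locus].sorted_alleles():
                lines.append(f"{ind.sample_id}\t{ind.role.value}\t{locus}\t{allele}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_cross_table(table: GenotypeTable) -> ValidationReport:
    """Flag uninformative loci, non-parental alleles and missing genotypes.

    Report-only: never mutates or rejects the table.  A locus is
    uninformative when the parental allele sets are identical — no private
    allele can exist there and it carries no signal for the parental-origin
    analysis.
    """
    report = ValidationReport()
    dam, sire = table.dam, table.sire
    for locus in table.loci:
        d, s = dam.alleles_at(locus), sire.alleles_at(locus)
        if d and s and d == s:
            report.uninformative_loci.append(locus)
        for ind in table.individuals:
            alleles = ind.alleles_at(locus)
            if not alleles:
                report.missing.append((ind.sample_id, locus))
            elif ind.role is Role.OFFSPRING:
                for a in sorted(alleles - d - s):
                    report.non_parental.append((ind.sample_id, locus, a))
    return report


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample DNA-content TSV.

    Requires a ``sample`` column and exactly one of ``dna_pg`` (absolute pg
    per nucleus) or ``ratio_to_standard`` (relative content).
    """
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise GenotypeFormatError(f"{path}: missing 'sample' column")
    value_cols = [c for c in ("dna_pg", "ratio_to_standard") if c in df.columns]
    if len(value_cols) != 1:
        raise GenotypeFormatError(
            f"{path}: need exactly one of 'dna_pg' or 'ratio_to_standard'"
        )
    df["sample"] = df["sample"].astype(str)
    return df[["sample", value_cols[0]]]
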