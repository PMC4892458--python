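"""Species-level trait data: records, datasets, and trait-table I/O.

Each species carries a demographic summary of its mature social groups —
the mean number of breeding females per group (B) and the mean total
number of females per group (N).  These are species averages, so both
fields are real-valued, not integers.  The social category (single
breeder vs. multiple breeders) is derived from B and stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .metrics import CLASSIFICATION_TOLERANCE, classify_social_structure

TAXON_GROUPS = ("wasp", "ant", "bird", "mammal", "other")

#: canonical column order of the trait table on disk
TABLE_COLUMNS = (
    "species_id",
    "taxon_group",
    "mean_breeding_females",
    "mean_total_females",
    "social_category",
)

_REQUIRED_COLUMNS = ("species_id", "taxon_group", "mean_breeding_females")


class SchemaError(ValueError):
    """A trait table is missing a required column."""


class ValidationError(ValueError):
    """One or more rows violate the dataset invariants.

    Attributes
    ----------
    problems : list of str
        One located diagnostic per offending row.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid trait data (%d problem%s):\n  %s"
            % (len(problems), "s" if len(problems) != 1 else "", "\n  ".join(problems))
        )


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' demographic summary.

    Invariants: ``mean_total_females >= mean_breeding_females > 0`` and
    ``mean_total_females >= 1``.
    """

    species_id: str
    taxon_group: str
    mean_breeding_females: float
    mean_total_females: float
    social_category: str | None = None

    @property
    def index_defined(self) -> bool:
        """Whether the monopolization index is defined (requires N > 1)."""
        return self.mean_total_females > 1.0

    def problems(self) -> list[str]:
        """Return invariant violations for this record (empty when valid)."""
        out = []
        b, n = self.mean_breeding_females, self.mean_total_females
        if not b > 0:
            out.append(f"{self.species_id}: mean_breeding_females must be > 0 (got {b})")
        if n < 1:
            out.append(f"{self.species_id}: mean_total_females must be >= 1 (got {n})")
        if b > n:
            out.append(
                f"{self.species_id}: breeding females ({b}) exceed total females ({n})"
            )
        if self.taxon_group not in TAXON_GROUPS:
            out.append(
                f"{self.species_id}: unknown taxon_group {self.taxon_group!r} "
                f"(expected one of {TAXON_GROUPS})"
            )
        return out

    def with_category(self, tolerance: float = CLASSIFICATION_TOLERANCE) -> "SpeciesRecord":
        """Return a copy with ``social_category`` derived from B.

        Left as ``None`` when B < 1 - tolerance (classification undefined;
        such records are legal but cannot be categorized).
        """
        if self.mean_breeding_females < 1.0 - tolerance:
            return self
        cat = classify_social_structure(self.mean_breeding_females, tolerance)
        return replace(self, social_category=cat)


@dataclass
class Dataset:
    """An ordered, validated collection of :class:`SpeciesRecord`."""

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        problems = []
        seen: set[str] = set()
        for rec in self.records:
            problems.extend(rec.problems())
            if rec.species_id in seen:
                problems.append(f"{rec.species_id}: duplicate species_id")
            seen.add(rec.species_id)
        if problems:
            raise ValidationError(problems)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    @property
    def flagged_undefined_index(self) -> list[str]:
        """Species whose monopolization index is undefined (N <= 1)."""
        return [r.species_id for r in self.records if not r.index_defined]

    def subset(self, species_ids: Iterable[str]) -> "Dataset":
        keep = set(species_ids)
        return Dataset(
            records=[r for r in self.records if r.species_id in keep],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [r.species_id for r in self.records],
                "taxon_group": [r.taxon_group for r in self.records],
                "mean_breeding_females": [r.mean_breeding_females for r in self.records],
                "mean_total_females": [r.mean_total_females for r in self.records],
                "social_category": [r.social_category for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Dataset":
        records = [
            SpeciesRecord(
                species_id=str(row.species_id),
                taxon_group=str(row.taxon_group),
                mean_breeding_females=float(row.mean_breeding_females),
                mean_total_females=float(row.mean_total_females),
                social_category=getattr(row, "social_category", None) or None,
            ).with_category()
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, provenance=provenance)


def read_species_table(
    path: str | Path,
    dialect: str | None = None,
) -> Dataset:
    """Read a species trait table (TSV by default, CSV by extension or dialect).

    The header must name ``species_id``, ``taxon_group``,
    ``mean_breeding_females`` and either ``mean_total_females`` or
    ``mean_nonbreeding_females`` (in which case N = B + non-breeding).

    Raises
    ------
    SchemaError
        When a required column is absent.
    ValidationError
        Listing every offending row (with its line number) when values
        fail to parse or violate the record invariants; no row is
        silently dropped.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trait table {path} is missing required column {col!r}")
    has_total = "mean_total_females" in df.columns
    has_nonbreeding = "mean_nonbreeding_females" in df.columns
    if not has_total and not has_nonbreeding:
        raise SchemaError(
            f"trait table {path} must name mean_total_females "
            "or mean_nonbreeding_females"
        )

    problems: list[str] = []
    records: list[SpeciesRecord] = []
    count_col = "mean_total_females" if has_total else "mean_nonbreeding_females"
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        sid = str(getattr(row, "species_id"))
        try:
            b = float(getattr(row, "mean_breeding_females"))
        except ValueError:
            problems.append(
                f"line {line} ({sid}): non-numeric mean_breeding_females "
                f"{getattr(row, 'mean_breeding_females')!r}"
            )
            continue
        try:
            other = float(getattr(row, count_col))
        except ValueError:
            problems.append(
                f"line {line} ({sid}): non-numeric {count_col} "
                f"{getattr(row, count_col)!r}"
            )
            continue
        n = other if has_total else b + other
        cat = getattr(row, "social_category", "") or None
        rec = SpeciesRecord(
            species_id=sid,
            taxon_group=str(getattr(row, "taxon_group")),
            mean_breeding_females=b,
            mean_total_females=n,
            social_category=cat,
        )
        rec_problems = rec.problems()
        if rec_problems:
            problems.extend(f"line {line}: {p}" for p in rec_problems)
        else:
            records.append(rec.with_category() if cat is None else rec)

    seen: set[str] = set()
    for rec in records:
        if rec.species_id in seen:
            problems.append(f"{rec.species_id}: duplicate species_id")
        seen.add(rec.species_id)

    if problems:
        raise ValidationError(problems)
    return Dataset(records=records, provenance=str(path))


def write_species_table(ds: Dataset, path: str | Path, dialect: str | None = None) -> None:
    """Write a dataset as a trait table; inverse of :func:`read_species_table`.

    Values are written with full repr precision, so a write/read round
    trip reproduces the dataset field-for-field.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if dialect == "csv" else "\t"
    df = ds.to_frame()
    df["social_category"] = df["social_category"].fillna("")
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
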