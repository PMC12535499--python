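"""Reading and writing LC-MS feature tables and HMDB taxonomy extracts.

The canonical on-disk dialect is delimited text with a header row, tab- or
comma-separated by file extension (``.tsv`` vs ``.csv``) — the two formats
feature-finding tools such as MZmine export.  Canonical feature-table
columns, in order::

    feature_id, mz, rt_min, polarity, annotation, hmdb_id, gradient_pct_a

Unknown extra columns (per-sample abundances and the like) are preserved on
read, carried through, and ignored by all computation: the framework's only
predictors are m/z and the gradient composition derived from RT.

Taxonomy extracts are two columns (``hmdb_id``, ``super_class``), as
pre-extracted from an HMDB release; XML parsing is out of scope here.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FeatureRecord",
    "FeatureTable",
    "TaxonomyMap",
    "RowError",
    "DialectError",
    "InputDataError",
    "read_feature_table",
    "read_taxonomy_table",
    "write_table",
    "write_taxonomy_table",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "feature_id",
    "mz",
    "rt_min",
    "polarity",
    "annotation",
    "hmdb_id",
    "gradient_pct_a",
)

_HMDB_PATTERN = re.compile(r"^HMDB\d+$")

_POLARITY_ALIASES = {
    "positive": "positive",
    "pos": "positive",
    "+": "positive",
    "p": "positive",
    "negative": "negative",
    "neg": "negative",
    "-": "negative",
    "n": "negative",
}


class DialectError(ValueError):
    """A required column is missing or the dialect mapping is unusable."""


class InputDataError(ValueError):
    """The file parsed but its content violates a table-level contract."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row: 0-based data-row index plus the reason."""

    row: int
    reason: str


@dataclass(frozen=True)
class FeatureRecord:
    """One LC-MS feature: an (m/z, RT) signal, identified or unknown."""

    feature_id: str
    mz: float
    rt_min: float
    polarity: str
    annotation: Optional[str] = None
    hmdb_id: Optional[str] = None
    gradient_pct_a: Optional[float] = None
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.mz > 0 and math.isfinite(self.mz)):
            raise ValueError(f"mz must be a positive finite number, got {self.mz!r}")
        if not (self.rt_min >= 0 and math.isfinite(self.rt_min)):
            raise ValueError(f"rt_min must be non-negative and finite, got {self.rt_min!r}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")
        if self.hmdb_id is not None and not _HMDB_PATTERN.match(self.hmdb_id):
            raise ValueError(f"hmdb_id does not match the HMDB accession pattern: {self.hmdb_id!r}")


@dataclass(frozen=True)
class FeatureTable:
    """An ordered collection of FeatureRecord with a provenance label."""

    records: tuple[FeatureRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[str, int] = {}
        dups = []
        for rec in self.records:
            seen[rec.feature_id] = seen.get(rec.feature_id, 0) + 1
        dups = sorted(fid for fid, n in seen.items() if n > 1)
        if dups:
            raise InputDataError(f"duplicate feature_id values: {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_records(self, records: Iterable[FeatureRecord]) -> "FeatureTable":
        return FeatureTable(tuple(records), provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Canonical columns first, then any extra columns seen on records."""
        extra_cols: list[str] = []
        for rec in self.records:
            for k in rec.extras:
                if k not in extra_cols:
                    extra_cols.append(k)
        rows = []
        for rec in self.records:
            row = {
                "feature_id": rec.feature_id,
                "mz": rec.mz,
                "rt_min": rec.rt_min,
                "polarity": rec.polarity,
                "annotation": rec.annotation,
                "hmdb_id": rec.hmdb_id,
                "gradient_pct_a": rec.gradient_pct_a,
            }
            for k in extra_cols:
                row[k] = rec.extras.get(k)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + extra_cols)


@dataclass(frozen=True)
class TaxonomyMap:
    """Mapping HMDB accession -> HMDB super-class string."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for acc, cls in self.entries.items():
            if not cls or not str(cls).strip():
                raise InputDataError(f"empty super class for accession {acc!r}")
        object.__setattr__(self, "entries", dict(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, accession: str) -> Optional[str]:
        return self.entries.get(accession)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _normalize_accession(raw: str) -> str:
    return raw.strip().upper()


_FLOAT_PATTERN = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_float(raw: str) -> float:
    """Locale-independent float parse: decimal point only, finite values only."""
    s = raw.strip()
    if not _FLOAT_PATTERN.match(s):
        raise ValueError(f"not a plain decimal number: {raw!r}")
    return float(s)


DEFAULT_DIALECT = {
    "id": "feature_id",
    "mz": "mz",
    "rt": "rt_min",
    "polarity": "polarity",
    "annotation": "annotation",
    "hmdb_id": "hmdb_id",
    "gradient_pct_a": "gradient_pct_a",
}

_REQUIRED_LOGICAL = ("id", "mz", "rt", "polarity")
_OPTIONAL_LOGICAL = ("annotation", "hmdb_id", "gradient_pct_a")


def read_feature_table(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    provenance: Optional[str] = None,
) -> tuple[FeatureTable, list[RowError]]:
    """Read a delimited feature table.

    ``dialect`` maps logical column names (id, mz, rt, polarity, and
    optionally annotation, hmdb_id, gradient_pct_a) to header names in the
    file; omitted logical names fall back to the canonical header names.
    Rows whose mz or rt do not parse (or violate record invariants) are
    rejected and reported with their 0-based data-row index; the remaining
    rows form the table.

    Returns (table, rejected_rows).
    """
    path = Path(path)
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for logical in _REQUIRED_LOGICAL:
        if mapping[logical] not in df.columns:
            raise DialectError(
                f"required column {mapping[logical]!r} (logical {logical!r}) "
                f"missing from {path.name}; header has {list(df.columns)}"
            )
    known_headers = {mapping[k] for k in mapping if mapping[k] in df.columns}
    extra_headers = [c for c in df.columns if c not in known_headers]

    records: list[FeatureRecord] = []
    rejected: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            mz = _parse_float(row_d[mapping["mz"]])
            rt = _parse_float(row_d[mapping["rt"]])
            pol_raw = row_d[mapping["polarity"]].strip().lower()
            if pol_raw not in _POLARITY_ALIASES:
                raise ValueError(f"unrecognized polarity {row_d[mapping['polarity']]!r}")
            annotation = None
            if mapping["annotation"] in row_d and row_d[mapping["annotation"]].strip():
                annotation = row_d[mapping["annotation"]].strip()
            hmdb_id = None
            if mapping["hmdb_id"] in row_d and row_d[mapping["hmdb_id"]].strip():
                hmdb_id = _normalize_accession(row_d[mapping["hmdb_id"]])
            pct_a = None
            if mapping["gradient_pct_a"] in row_d and row_d[mapping["gradient_pct_a"]].strip():
                pct_a = _parse_float(row_d[mapping["gradient_pct_a"]])
            rec = FeatureRecord(
                feature_id=row_d[mapping["id"]].strip(),
                mz=mz,
                rt_min=rt,
                polarity=_POLARITY_ALIASES[pol_raw],
                annotation=annotation,
                hmdb_id=hmdb_id,
                gradient_pct_a=pct_a,
                extras={k: row_d[k] for k in extra_headers},
            )
        except ValueError as exc:
            rejected.append(RowError(row=i, reason=str(exc)))
            continue
        records.append(rec)

    table = FeatureTable(tuple(records), provenance=provenance or str(path))
    return table, rejected


def read_taxonomy_table(path, header: str | bool = "auto") -> TaxonomyMap:
    """Read a two-column (accession, super class) taxonomy extract.

    ``header`` is True, False, or "auto" (first row treated as a header
    unless its first cell already looks like an HMDB accession).  Duplicate
    accessions with identical super classes collapse silently; conflicting
    duplicates raise :class:`InputDataError`.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r and any(c.strip() for c in r)]
    if not rows:
        return TaxonomyMap({})
    if header == "auto":
        has_header = not _HMDB_PATTERN.match(_normalize_accession(rows[0][0]))
    else:
        has_header = bool(header)
    data_rows = rows[1:] if has_header else rows

    entries: dict[str, str] = {}
    for r in data_rows:
        if len(r) < 2:
            raise InputDataError(f"taxonomy row has fewer than two columns: {r!r}")
        acc = _normalize_accession(r[0])
        cls = r[1].strip()
        if acc in entries and entries[acc].strip().lower() != cls.lower():
            raise InputDataError(
                f"conflicting super classes for accession {acc}: "
                f"{entries[acc]!r} vs {cls!r}"
            )
        entries.setdefault(acc, cls)
    return TaxonomyMap(entries)


def write_table(table, path) -> None:
    """Write a FeatureTable (or any DataFrame-like result) as delimited text.

    FeatureTable goes out in the canonical column order with empty cells for
    unset optional fields; reading it back with the canonical dialect
    reproduces the table field-for-field.
    """
    path = Path(path)
    if isinstance(table, FeatureTable):
        df = table.to_frame()
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(table)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def write_taxonomy_table(taxonomy: TaxonomyMap, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        sorted(taxonomy.entries.items()), columns=["hmdb_id", "super_class"]
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
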