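"""Row-oriented EMR corpus I/O.

The unit of analysis throughout the package is the *case*: one row of a
practice-management CSV export pairing an anonymous patient identifier with a
free-text clinical note.  Row numbers are 1-based positions in the source file
(or an explicit row-number column, when the export carries one) and are
preserved verbatim through every downstream artifact — keyword-in-context
sheets, result subsets, discrepancy reports — so that set algebra on rows and
human review always refer to the same records.

Files are plain CSV: UTF-8, comma-separated, RFC-4180 quoting, header row
required.  Quoted text may contain commas and embedded line breaks; the text
of a note round-trips byte-identically through write/read.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

from .errors import ConfigurationError, IntegrityError

if TYPE_CHECKING:  # pragma: no cover
    from .case_detection import CaseSet
    from .text_engine import KwicHit

__all__ = [
    "CsvDialect",
    "DEFAULT_DIALECT",
    "WRITTEN_DIALECT",
    "EmrRow",
    "Corpus",
    "GoldLabels",
    "read_corpus",
    "write_corpus",
    "write_kwic",
    "read_kwic",
    "write_results",
    "read_gold_labels",
    "write_gold_labels",
    "KWIC_COLUMNS",
]

#: Exact column order of the 5-column keyword-in-context review sheet.
KWIC_COLUMNS = ("row_number", "pre_context", "matched_term", "post_context", "patient_id")

_DATE_FORMATS = ("%Y-%m-%d", "%d/%m/%Y", "%d-%m-%Y", "%Y/%m/%d")


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for a corpus export.

    ``row_number_col`` is optional: when ``None`` rows are numbered 1-based in
    file order, otherwise row ids are read from that column.  ``date_col`` may
    be ``None`` for exports without a date column; dates are never used by
    classification.
    """

    patient_col: str = "patient_id"
    date_col: str | None = "date"
    text_col: str = "text"
    row_number_col: str | None = None
    encoding: str = "utf-8"


DEFAULT_DIALECT = CsvDialect()
#: Dialect matching the files this module itself writes (explicit row_number column).
WRITTEN_DIALECT = CsvDialect(row_number_col="row_number")


@dataclass(frozen=True)
class EmrRow:
    """One free-text clinical record row — the unit of classification."""

    row_id: int
    patient_id: str
    date: dt.date | None
    text: str


class Corpus:
    """An ordered collection of :class:`EmrRow` in original file order."""

    def __init__(self, rows: Iterable[EmrRow], provenance: str = "<memory>"):
        self.rows: tuple[EmrRow, ...] = tuple(rows)
        self.provenance = provenance
        seen: set[int] = set()
        for row in self.rows:
            if row.row_id in seen:
                raise IntegrityError(f"duplicate row_id {row.row_id} in corpus")
            seen.add(row.row_id)
        self._row_ids = frozenset(seen)
        self._by_id = {row.row_id: row for row in self.rows}
        # per-TokenizerConfig cache filled lazily by text_engine
        self._token_cache: dict = {}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def row_ids(self) -> frozenset[int]:
        return self._row_ids

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[EmrRow]:
        return iter(self.rows)

    def __getitem__(self, row_id: int) -> EmrRow:
        return self._by_id[row_id]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Corpus({self.n_rows} rows from {self.provenance!r})"


@dataclass(frozen=True)
class GoldLabels:
    """Manual gold-standard classification: row_id → set of positive categories.

    A row may carry multiple tags (one clinical note can mention, say, both a
    colic episode and an NSAID dispensed for it); untagged rows map to the
    empty set.
    """

    labels: Mapping[int, frozenset[str]]
    categories: tuple[str, ...]

    def positives(self, category: str) -> frozenset[int]:
        return frozenset(r for r, tags in self.labels.items() if category in tags)

    def __getitem__(self, row_id: int) -> frozenset[str]:
        return self.labels.get(row_id, frozenset())

    @property
    def row_ids(self) -> frozenset[int]:
        return frozenset(self.labels)


def _parse_date(raw: str, row_id: int) -> dt.date | None:
    raw = raw.strip()
    if not raw:
        return None
    for fmt in _DATE_FORMATS:
        try:
            return dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    warnings.warn(f"row {row_id}: unparseable date {raw!r}; date dropped")
    return None


def _check_columns(header: list[str] | None, needed: Iterable[str], path) -> None:
    header = header or []
    for col in needed:
        if col not in header:
            raise ConfigurationError(f"{path}: required column {col!r} not in header {header}")


def read_corpus(path, dialect: CsvDialect = DEFAULT_DIALECT) -> Corpus:
    """Read a corpus CSV.  Rows are numbered 1-based in file order unless the
    dialect names an explicit row-number column.  Empty notes are retained
    (they count toward true-negative denominators); they are never dropped."""
    path = Path(path)
    needed = [dialect.patient_col, dialect.text_col]
    if dialect.date_col:
        needed.append(dialect.date_col)
    if dialect.row_number_col:
        needed.append(dialect.row_number_col)
    rows: list[EmrRow] = []
    with open(path, newline="", encoding=dialect.encoding) as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, needed, path)
        for i, rec in enumerate(reader, start=1):
            if dialect.row_number_col:
                try:
                    row_id = int(rec[dialect.row_number_col])
                except ValueError as exc:
                    raise ConfigurationError(
                        f"{path}: non-integer row number {rec[dialect.row_number_col]!r}"
                    ) from exc
            else:
                row_id = i
            date = _parse_date(rec[dialect.date_col], row_id) if dialect.date_col else None
            rows.append(
                EmrRow(
                    row_id=row_id,
                    patient_id=rec[dialect.patient_col],
                    date=date,
                    text=rec[dialect.text_col] or "",
                )
            )
    return Corpus(rows, provenance=str(path))


def _write_rows(rows: Iterable[EmrRow], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "patient_id", "date", "text"])
        for row in rows:
            writer.writerow(
                [row.row_id, row.patient_id, row.date.isoformat() if row.date else "", row.text]
            )


def write_corpus(corpus: Corpus, path) -> None:
    """Write the full corpus with an explicit ``row_number`` column; readable
    back with :data:`WRITTEN_DIALECT`."""
    _write_rows(corpus.rows, path)


def write_results(case_set: "CaseSet", corpus: Corpus, path) -> None:
    """Write the subset of rows classified positive, original row numbers and
    original order preserved (the per-category "Results" dataset)."""
    unknown = set(case_set.row_ids) - set(corpus.row_ids)
    if unknown:
        raise IntegrityError(f"case set contains row ids absent from corpus: {sorted(unknown)[:5]}")
    _write_rows((row for row in corpus.rows if row.row_id in case_set.row_ids), path)


def write_kwic(hits: Iterable["KwicHit"], path) -> None:
    """Write the 5-column keyword-in-context review sheet.

    Columns, in this exact order: row_number, pre_context, matched_term,
    post_context, patient_id.  A row with k hits yields k lines.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(KWIC_COLUMNS)
        for hit in hits:
            writer.writerow(
                [hit.row_id, hit.pre_context, hit.matched_text, hit.post_context, hit.patient_id]
            )


def read_kwic(path) -> list[dict]:
    """Read a KWIC sheet back as a list of field dicts (for review tooling
    and round-trip checks)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, KWIC_COLUMNS, path)
        return list(reader)


def read_gold_labels(
    path, categories: Iterable[str], dialect: CsvDialect = DEFAULT_DIALECT
) -> GoldLabels:
    """Read a manual-classification file: the corpus columns plus one column
    per category.  Any non-empty cell is a positive tag; the literal tag text
    is not interpreted."""
    path = Path(path)
    categories = tuple(categories)
    labels: dict[int, frozenset[str]] = {}
    with open(path, newline="", encoding=dialect.encoding) as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, categories, path)
        for i, rec in enumerate(reader, start=1):
            if dialect.row_number_col and dialect.row_number_col in (reader.fieldnames or []):
                row_id = int(rec[dialect.row_number_col])
            elif "row_number" in (reader.fieldnames or []):
                row_id = int(rec["row_number"])
            else:
                row_id = i
            tags = frozenset(c for c in categories if (rec[c] or "").strip())
            labels[row_id] = tags
    return GoldLabels(labels=labels, categories=categories)


def write_gold_labels(gold: GoldLabels, corpus: Corpus, path, tag: str = "x") -> None:
    """Write gold labels in the manual-classification layout: corpus columns
    plus one column per category, ``tag`` marking positives."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "patient_id", "date", "text", *gold.categories])
        for row in corpus.rows:
            tags = gold[row.row_id]
            writer.writerow(
                [
                    row.row_id,
                    row.patient_id,
                    row.date.isoformat() if row.date else "",
                    row.text,
                    *(tag if c in tags else "" for c in gold.categories),
                ]
            )
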