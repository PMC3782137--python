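"""Data model and I/O for ethnomedicinal use-report surveys.

A survey is a flat table with one row per (disorder, species) pair,
carrying the number of informant mentions and usage metadata (organism
kind, used parts, preparations, administration route).  This module
defines the validated in-memory representation (:class:`UseRecord`,
:class:`SurveyTable`), CSV/TSV readers and writers with a lossless
round-trip guarantee, scientific-name normalization, and the packaged
survey of liver-disorder ethnomedicine recorded in local communities of
southern Korea, which is the worked dataset used throughout the package.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "KINDS",
    "APPLICATIONS",
    "CANONICAL_DISORDERS",
    "DEFAULT_ALIASES",
    "SurveyError",
    "SchemaError",
    "SurveyValidationError",
    "UseRecord",
    "SurveyTable",
    "normalize_name",
    "read_survey",
    "write_survey",
    "load_fixture",
]

#: Organism kingdoms a medicinal species may belong to.
KINDS = ("plant", "animal", "fungus")

#: Administration routes.
APPLICATIONS = ("oral", "topical")

#: Canonical spellings of the seven liver-disorder categories of the
#: packaged Korean survey.  Disorder labels in input files are matched
#: against these case-insensitively; labels outside the list are kept
#: verbatim, so arbitrary surveys remain loadable.
CANONICAL_DISORDERS = (
    "Fatigue recovery",
    "Hangover",
    "Hepatitis",
    "Jaundice",
    "Liver cancer",
    "Liver cirrhosis",
    "Liver-related ailments",
)

#: Orthographic variants observed in the source survey.  Keys are raw
#: (whitespace-normalized) name strings, values the canonical names.
#: Without these, distinct-species counts are inflated by spelling noise.
DEFAULT_ALIASES: dict[str, str] = {
    "Scolopendra subspinipes mutilan L. Koch": "Scolopendra subspinipes mutilans L. Koch",
    "Capsella bursapastoris (L.) L.W.Medicus": "Capsella bursapastoris (L.) L. W. Medicus",
    "Fomes fomentarius (L. : Fr.) Fr.": "Fomes fomentarius (L.: Fr.) Fr.",
}

REQUIRED_COLUMNS = (
    "disorder",
    "scientific_name",
    "mentions",
    "kind",
    "used_parts",
    "preparations",
    "application",
)

OPTIONAL_COLUMNS = ("local_name", "fl_printed")

#: Delimiter used to serialize set-valued fields inside one CSV cell.
SET_DELIMITER = ", "


class SurveyError(Exception):
    """Base class for survey I/O and validation failures."""


class SchemaError(SurveyError):
    """The input file lacks a required column."""


class SurveyValidationError(SurveyError):
    """A row violates the survey data model.

    Parameters
    ----------
    message:
        Human-readable description.
    row:
        Zero-based data-row index, when the failure is row-local.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


_WS = re.compile(r"\s+")


def normalize_name(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Return the canonical form of a scientific-name string.

    Collapses runs of whitespace to single spaces, trims the ends, and
    then applies the alias mapping (default: :data:`DEFAULT_ALIASES`).
    Alias values are themselves normalized, which makes the operation
    idempotent as long as no alias value is also an alias key.

    Raises
    ------
    SurveyValidationError
        If ``raw`` is empty or whitespace-only.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    name = _WS.sub(" ", raw).strip()
    if not name:
        raise SurveyValidationError("scientific name is empty")
    name = aliases.get(name, name)
    return _WS.sub(" ", name).strip()


def _canonical_disorder(label: str) -> str:
    label = _WS.sub(" ", label).strip()
    for canonical in CANONICAL_DISORDERS:
        if label.lower() == canonical.lower():
            return canonical
    return label


@dataclass(frozen=True)
class UseRecord:
    """One use report row: a disorder treated by a species.

    ``mentions`` counts the informants who cited this (disorder, species)
    pair; it is the atomic quantity all downstream indices consume.
    ``fl_printed`` optionally retains a fidelity-level percentage as
    printed in a source document; it is kept for auditing only and never
    enters any computation.
    """

    disorder: str
    scientific_name: str
    mentions: int
    kind: str
    used_parts: frozenset[str]
    preparations: frozenset[str]
    application: str = "oral"
    local_name: str | None = None
    fl_printed: float | None = None

    def __post_init__(self) -> None:
        if not self.disorder or not self.disorder.strip():
            raise SurveyValidationError("disorder label is empty")
        if not self.scientific_name or not self.scientific_name.strip():
            raise SurveyValidationError("scientific name is empty")
        if not isinstance(self.mentions, int) or isinstance(self.mentions, bool):
            raise SurveyValidationError(
                f"mentions must be an integer, got {self.mentions!r}"
            )
        if self.mentions < 1:
            raise SurveyValidationError(
                f"mentions must be >= 1, got {self.mentions}"
            )
        if self.kind not in KINDS:
            raise SurveyValidationError(
                f"kind must be one of {KINDS}, got {self.kind!r}"
            )
        if self.application not in APPLICATIONS:
            raise SurveyValidationError(
                f"application must be one of {APPLICATIONS}, got {self.application!r}"
            )
        for label, values in (("used_parts", self.used_parts),
                              ("preparations", self.preparations)):
            if not values:
                raise SurveyValidationError(f"{label} is empty")
            if any((not isinstance(v, str)) or not v.strip() for v in values):
                raise SurveyValidationError(f"{label} contains an empty label")


@dataclass
class SurveyTable:
    """A validated, ordered collection of :class:`UseRecord`.

    Invariants enforced at construction: (disorder, scientific name)
    pairs are unique, and every scientific name is canonical under the
    table's alias mapping.
    """

    records: list[UseRecord]
    name_aliases: dict[str, str] = field(default_factory=dict)
    #: Free-form notes collected while loading (applied aliases, etc.).
    validation_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for i, rec in enumerate(self.records):
            canonical = normalize_name(rec.scientific_name, self.name_aliases or None)
            if canonical != rec.scientific_name:
                raise SurveyValidationError(
                    f"scientific name {rec.scientific_name!r} is not canonical "
                    f"(expected {canonical!r})", row=i,
                )
            key = (rec.disorder, rec.scientific_name)
            if key in seen:
                raise SurveyValidationError(
                    f"duplicate (disorder, species) pair {key!r}", row=i
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_mentions(self) -> int:
        """Total number of use reports in the survey."""
        return sum(rec.mentions for rec in self.records)

    @property
    def disorders(self) -> list[str]:
        """Disorder labels in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.disorder not in out:
                out.append(rec.disorder)
        return out

    @property
    def species(self) -> list[str]:
        """Canonical species names in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.scientific_name not in out:
                out.append(rec.scientific_name)
        return out

    def species_kind(self) -> dict[str, str]:
        """Mapping canonical species name -> organism kind."""
        kinds: dict[str, str] = {}
        for rec in self.records:
            prev = kinds.setdefault(rec.scientific_name, rec.kind)
            if prev != rec.kind:
                raise SurveyValidationError(
                    f"species {rec.scientific_name!r} recorded with conflicting "
                    f"kinds {prev!r} and {rec.kind!r}"
                )
        return kinds

    def species_mentions(self) -> dict[str, int]:
        """Mapping canonical species name -> mentions summed over disorders."""
        totals: dict[str, int] = {}
        for rec in self.records:
            totals[rec.scientific_name] = totals.get(rec.scientific_name, 0) + rec.mentions
        return totals


def _split_set(cell: str) -> frozenset[str]:
    return frozenset(part.strip() for part in cell.split(",") if part.strip())


def _join_set(values: Iterable[str]) -> str:
    return SET_DELIMITER.join(sorted(values))


def _parse_row(
    raw: Mapping[str, str], row_index: int, aliases: Mapping[str, str]
) -> UseRecord:
    mentions_raw = (raw.get("mentions") or "").strip()
    try:
        mentions = int(mentions_raw)
    except ValueError:
        raise SurveyValidationError(
            f"mentions is not an integer: {mentions_raw!r}", row=row_index
        ) from None
    kind = (raw.get("kind") or "").strip().lower()
    if kind not in KINDS:
        raise SurveyValidationError(
            f"unknown kind {raw.get('kind')!r}", row=row_index
        )
    fl_raw = (raw.get("fl_printed") or "").strip()
    fl_printed = float(fl_raw) if fl_raw else None
    local = (raw.get("local_name") or "").strip() or None
    try:
        return UseRecord(
            disorder=_canonical_disorder(raw.get("disorder") or ""),
            scientific_name=normalize_name(raw.get("scientific_name") or "", aliases),
            mentions=mentions,
            kind=kind,
            used_parts=_split_set(raw.get("used_parts") or ""),
            preparations=_split_set(raw.get("preparations") or ""),
            application=(raw.get("application") or "").strip().lower(),
            local_name=local,
            fl_printed=fl_printed,
        )
    except SurveyValidationError as err:
        if err.row is None:
            raise SurveyValidationError(str(err), row=row_index) from None
        raise


def _infer_delimiter(path: Path, format: str | None) -> str:
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if format not in {"csv", "tsv"}:
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    return "\t" if format == "tsv" else ","


def read_survey(
    path: str | Path,
    format: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> SurveyTable:
    """Read a use-report table from a CSV/TSV file.

    Parameters
    ----------
    path:
        Input file.  The header must contain the columns
        ``disorder, scientific_name, mentions, kind, used_parts,
        preparations, application`` (``local_name`` and ``fl_printed``
        are optional).
    format:
        ``"csv"`` or ``"tsv"``; inferred from the file extension when
        omitted.
    aliases:
        Scientific-name alias mapping applied during normalization;
        defaults to :data:`DEFAULT_ALIASES`.

    Raises
    ------
    SchemaError
        If a required column is missing.
    SurveyValidationError
        For malformed rows (non-integer mentions, unknown kind, empty
        set-valued fields, duplicate (disorder, species) pairs), with
        the offending zero-based row index in the message.
    """
    path = Path(path)
    delimiter = _infer_delimiter(path, format)
    if aliases is None:
        aliases = DEFAULT_ALIASES
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_stream(fh, delimiter, dict(aliases))


def _read_stream(fh, delimiter: str, aliases: dict[str, str]) -> SurveyTable:
    reader = csv.DictReader(fh, delimiter=delimiter)
    header = reader.fieldnames or []
    for column in REQUIRED_COLUMNS:
        if column not in header:
            raise SchemaError(f"missing required column {column!r}")
    records: list[UseRecord] = []
    notes: list[str] = []
    for i, raw in enumerate(reader):
        rec = _parse_row(raw, i, aliases)
        raw_name = _WS.sub(" ", (raw.get("scientific_name") or "")).strip()
        if raw_name and raw_name != rec.scientific_name:
            notes.append(
                f"row {i}: normalized {raw_name!r} -> {rec.scientific_name!r}"
            )
        records.append(rec)
    return SurveyTable(records=records, name_aliases=aliases, validation_notes=notes)


def write_survey(
    table: SurveyTable, path: str | Path, format: str | None = None
) -> None:
    """Write a survey table to CSV/TSV.

    Set-valued fields are serialized comma-separated (sorted) inside a
    quoted cell, so ``read_survey(write_survey(t))`` reproduces ``t``
    record for record.
    """
    path = Path(path)
    delimiter = _infer_delimiter(path, format)
    columns = list(REQUIRED_COLUMNS[:2]) + ["local_name"] + list(REQUIRED_COLUMNS[2:]) + ["fl_printed"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter=delimiter)
        writer.writeheader()
        for rec in table.records:
            writer.writerow(
                {
                    "disorder": rec.disorder,
                    "scientific_name": rec.scientific_name,
                    "local_name": rec.local_name or "",
                    "mentions": rec.mentions,
                    "kind": rec.kind,
                    "used_parts": _join_set(rec.used_parts),
                    "preparations": _join_set(rec.preparations),
                    "application": rec.application,
                    "fl_printed": "" if rec.fl_printed is None else f"{rec.fl_printed:.1f}",
                }
            )


_FIXTURES = {"korean_liver_survey": "korean_liver_survey.csv"}


def load_fixture(name: str = "korean_liver_survey") -> SurveyTable:
    """Load a packaged survey by name.

    The default, ``"korean_liver_survey"``, is the complete use-report
    dataset of the liver-disorder ethnomedicine survey conducted in
    local communities of southern Korea (121 records, 1,514 use reports
    across seven disorder categories).  The file preserves the source's
    orthographic variants; normalization and the default alias table are
    applied on load, exactly as for any user-supplied file.
    """
    try:
        filename = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    data = resources.files("ethnoquant.data").joinpath(filename).read_text(encoding="utf-8")
    return _read_stream(io.StringIO(data), ",", dict(DEFAULT_ALIASES))
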