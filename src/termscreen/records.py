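"""Bibliographic record IO and hard-exclusion screening rules.

Records arrive from database exports as RIS or delimited text.  Each record
carries an identifier, optional DOI, title, optional abstract, an article-type
label and (for evaluation corpora) a gold eligibility label.  Records that can
never be screened on content — no DOI, no abstract, an ineligible article type,
or an abstract under a minimum character length — are flagged here so that
ranking can force them to the bottom of the screening order.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "ArticleRecord",
    "RecordSet",
    "ExclusionConfig",
    "RecordError",
    "read_records",
    "write_records",
    "flag_exclusions",
]


class RecordError(ValueError):
    """Raised for malformed inputs: unparsable files, duplicate ids, missing columns."""


@dataclass(frozen=True)
class ArticleRecord:
    """One bibliographic record.

    ``doi`` and ``abstract`` are ``None`` when genuinely absent; an
    all-whitespace abstract is normalised to absent at construction time so
    that "empty cell" and "missing field" are never distinguishable states.
    """

    record_id: str
    title: str
    doi: Optional[str] = None
    abstract: Optional[str] = None
    article_type: str = "article"
    gold_label: Optional[str] = None  # "eligible" | "ineligible" | None
    excluded: bool = False
    exclusion_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not str(self.record_id):
            raise RecordError("record_id must be a non-empty string")
        if self.gold_label not in (None, "eligible", "ineligible"):
            raise RecordError(
                f"gold_label must be 'eligible', 'ineligible' or absent, "
                f"got {self.gold_label!r} (record {self.record_id})"
            )
        # normalise blank-ish optional fields to absent
        for fld in ("doi", "abstract"):
            val = getattr(self, fld)
            if val is not None and not val.strip():
                object.__setattr__(self, fld, None)
        if self.abstract is not None:
            object.__setattr__(self, "abstract", self.abstract.strip())

    @property
    def is_eligible(self) -> Optional[bool]:
        if self.gold_label is None:
            return None
        return self.gold_label == "eligible"


@dataclass
class RecordSet:
    """An ordered collection of records with stable iteration order.

    Order equals input order unless the set was produced by an explicit
    re-ranking step.  ``provenance`` records where the data came from.
    """

    records: list[ArticleRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise RecordError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def by_id(self, record_id: str) -> ArticleRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)


@dataclass(frozen=True)
class ExclusionConfig:
    """Hard-exclusion rules applied before scoring.

    Defaults: a record is excluded if it has no DOI, no abstract, an abstract
    shorter than 200 characters, or an article type in the ineligible set.
    The ineligible-type list is a configurable convention (reviews, editorials,
    errata and letters are not primary empirical studies).
    """

    min_abstract_chars: int = 200
    ineligible_article_types: frozenset[str] = frozenset(
        {"review", "editorial", "erratum", "letter"}
    )
    require_doi: bool = True
    require_abstract: bool = True

    def __post_init__(self) -> None:
        if self.min_abstract_chars < 0:
            raise ValueError("min_abstract_chars must be >= 0")
        object.__setattr__(
            self,
            "ineligible_article_types",
            frozenset(t.strip().lower() for t in self.ineligible_article_types),
        )


# ---------------------------------------------------------------------------
# Reading

_DEFAULT_CSV_MAPPING = {
    "record_id": "record_id",
    "title": "title",
    "doi": "doi",
    "abstract": "abstract",
    "article_type": "article_type",
    "gold_label": "gold_label",
}

# RIS tag -> record field; TY doubles as the entry opener.
_DEFAULT_RIS_MAPPING = {"TI": "title", "T1": "title", "AB": "abstract",
                        "DO": "doi", "TY": "article_type", "ID": "record_id"}

_RIS_TYPE_LABELS = {
    "JOUR": "article", "REVW": "review", "EDIT": "editorial", "ERR": "erratum",
}


def read_records(
    path: str | Path,
    format: str = "csv",
    mapping: Optional[Mapping[str, str]] = None,
) -> RecordSet:
    """Read bibliographic records from ``path``.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``"ris"``, ``"csv"``, ``"tsv"``.
    mapping:
        For csv/tsv: record-field -> column-name overrides (``record_id`` and
        ``title`` must resolve).  For ris: RIS tag -> record-field overrides.

    Absent DOI / abstract cells become ``None``, never empty strings.
    """
    path = Path(path)
    if not path.exists():
        raise RecordError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "ris":
        records = _read_ris(path, dict(_DEFAULT_RIS_MAPPING, **(mapping or {})))
    elif fmt in ("csv", "tsv"):
        records = _read_delimited(
            path, "\t" if fmt == "tsv" else ",",
            dict(_DEFAULT_CSV_MAPPING, **(mapping or {})),
        )
    else:
        raise RecordError(f"unknown format {format!r}; expected ris, csv or tsv")
    provenance = [f"{path.name} read {_dt.datetime.now().isoformat(timespec='seconds')}"]
    return RecordSet(records=records, provenance=provenance)


def _read_delimited(path: Path, delim: str, mapping: Mapping[str, str]) -> list[ArticleRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise RecordError(f"{path}: empty file, header row required")
        for fld in ("record_id", "title"):
            if mapping[fld] not in reader.fieldnames:
                raise RecordError(
                    f"{path}: mandatory column {mapping[fld]!r} (for {fld}) missing "
                    f"from header {reader.fieldnames}"
                )
        records = []
        for lineno, row in enumerate(reader, start=2):
            def get(fld: str) -> Optional[str]:
                col = mapping.get(fld)
                val = row.get(col) if col else None
                return val if val not in (None, "") else None

            try:
                records.append(ArticleRecord(
                    record_id=get("record_id") or "",
                    title=get("title") or "",
                    doi=get("doi"),
                    abstract=get("abstract"),
                    article_type=get("article_type") or "article",
                    gold_label=get("gold_label"),
                ))
            except RecordError as exc:
                raise RecordError(f"{path} row {lineno}: {exc}") from exc
        _check_unique_ids(records, path)
        return records


def _read_ris(path: Path, mapping: Mapping[str, str]) -> list[ArticleRecord]:
    """Minimal RIS reader: ``XX  - value`` tag lines, entries closed by ``ER``.

    Untagged lines continue the previous tag's value (multi-line abstracts).
    """
    records: list[ArticleRecord] = []
    entry: dict[str, str] = {}
    last_tag: Optional[str] = None
    n_entries = 0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tag, sep, value = line[:2], line[2:6], line[6:]
            if len(line) >= 6 and tag.isalnum() and tag.isupper() and sep.strip() == "-":
                last_tag = tag
                if tag == "ER":
                    n_entries += 1
                    records.append(_ris_entry_to_record(entry, n_entries))
                    entry = {}
                else:
                    fld = mapping.get(tag)
                    if fld is not None:
                        entry[fld] = (entry[fld] + " " + value.strip()
                                      if fld in entry else value.strip())
            elif last_tag is not None and mapping.get(last_tag):
                fld = mapping[last_tag]
                entry[fld] = (entry.get(fld, "") + " " + line.strip()).strip()
    if entry:
        n_entries += 1
        records.append(_ris_entry_to_record(entry, n_entries))
    _check_unique_ids(records, path)
    return records


def _ris_entry_to_record(entry: dict[str, str], ordinal: int) -> ArticleRecord:
    atype = entry.get("article_type", "JOUR")
    return ArticleRecord(
        record_id=entry.get("record_id") or f"ris-{ordinal}",
        title=entry.get("title", ""),
        doi=entry.get("doi"),
        abstract=entry.get("abstract"),
        article_type=_RIS_TYPE_LABELS.get(atype, atype.lower()),
        gold_label=entry.get("gold_label"),
    )


def _check_unique_ids(records: Sequence[ArticleRecord], path: Path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise RecordError(f"{path}: duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)


# ---------------------------------------------------------------------------
# Writing

_OUT_COLUMNS = ["record_id", "doi", "title", "abstract", "article_type",
                "gold_label", "excluded", "exclusion_rules"]


def write_records(records: RecordSet | Iterable[ArticleRecord],
                  path: str | Path, format: str = "csv") -> None:
    """Write records as RFC-4180 CSV (or TSV), UTF-8, header row included.

    Round-trips through :func:`read_records`: absent optional fields are
    written as empty cells and re-read as absent.
    """
    fmt = format.lower()
    if fmt not in ("csv", "tsv"):
        raise RecordError(f"unsupported output format {format!r}")
    delim = "\t" if fmt == "tsv" else ","
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(_OUT_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.record_id,
                rec.doi or "",
                rec.title,
                rec.abstract or "",
                rec.article_type,
                rec.gold_label or "",
                "1" if rec.excluded else "",
                ";".join(rec.exclusion_rules),
            ])


# ---------------------------------------------------------------------------
# Exclusion rules


def exclusion_rules_for(rec: ArticleRecord, config: ExclusionConfig) -> tuple[str, ...]:
    """Names of the hard-exclusion rules that fire for one record."""
    fired: list[str] = []
    if config.require_doi and rec.doi is None:
        fired.append("no_doi")
    if rec.abstract is None:
        if config.require_abstract:
            fired.append("no_abstract")
    elif len(rec.abstract) < config.min_abstract_chars:
        fired.append("short_abstract")
    if rec.article_type.strip().lower() in config.ineligible_article_types:
        fired.append("ineligible_type")
    return tuple(fired)


def flag_exclusions(records: RecordSet,
                    config: Optional[ExclusionConfig] = None) -> RecordSet:
    """Return a new RecordSet with ``excluded`` and ``exclusion_rules`` set.

    Total and idempotent: every record is re-evaluated from scratch, so
    applying the same config twice is a no-op.  Abstract length is counted in
    characters of the whitespace-trimmed abstract.
    """
    config = config or ExclusionConfig()
    out = []
    for rec in records:
        fired = exclusion_rules_for(rec, config)
        out.append(replace(rec, excluded=bool(fired), exclusion_rules=fired))
    return RecordSet(records=out, provenance=list(records.provenance))
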