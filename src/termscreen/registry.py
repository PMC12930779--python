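"""Expert-weighted positive/negative keyword registry.

Screening keywords are short phrases curated and refined iteratively by a
domain expert.  Each phrase carries a polarity (positive = indicates
relevance, negative = indicates irrelevance) and an integer weight from 1 to
10; scoring uses weight/10 so weights translate to clean decimal multipliers.
The registry versions every committed change so the keyword list driving a
given screening pass can be audited and reused.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .tokenize import normalize_phrase

__all__ = [
    "Keyword",
    "KeywordRegistry",
    "RegistryError",
    "load_registry",
    "save_registry",
]

POSITIVE = "positive"
NEGATIVE = "negative"
MIN_WEIGHT, MAX_WEIGHT = 1, 10


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class Keyword:
    """A weighted screening phrase.

    ``phrase`` is stored fully normalized (lowercase NFKC, punctuation
    stripped, whitespace collapsed) so registry phrases match document tokens
    by construction.
    """

    phrase: str
    polarity: str
    weight: int

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise RegistryError(f"polarity must be positive/negative, got {self.polarity!r}")
        if not isinstance(self.weight, int) or isinstance(self.weight, bool):
            raise RegistryError(f"weight must be an integer, got {self.weight!r}")
        if not MIN_WEIGHT <= self.weight <= MAX_WEIGHT:
            raise RegistryError(
                f"weight must be between {MIN_WEIGHT} and {MAX_WEIGHT}, got {self.weight}"
            )
        norm = normalize_phrase(self.phrase)
        if not norm:
            raise RegistryError(f"phrase {self.phrase!r} is empty after normalization")
        object.__setattr__(self, "phrase", norm)

    @property
    def normalized_weight(self) -> float:
        """weight/10, the multiplier used in the term-score formula."""
        return self.weight / 10

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.phrase.split())

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass
class KeywordRegistry:
    """Versioned collection of screening keywords.

    Invariants: no phrase appears under both polarities, no duplicate
    (phrase, polarity) pairs, and ``version`` increments by one per committed
    mutation (so version == number of log entries).
    """

    keywords: list[Keyword] = field(default_factory=list)
    version: int = 0
    revision_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        phrases: dict[str, str] = {}
        for kw in self.keywords:
            if kw.phrase in phrases:
                if phrases[kw.phrase] != kw.polarity:
                    raise RegistryError(
                        f"phrase {kw.phrase!r} present with both polarities"
                    )
                raise RegistryError(f"duplicate keyword ({kw.phrase!r}, {kw.polarity})")
            phrases[kw.phrase] = kw.polarity

    def __len__(self) -> int:
        return len(self.keywords)

    def __iter__(self) -> Iterator[Keyword]:
        return iter(self.keywords)

    def get(self, phrase: str, polarity: Optional[str] = None) -> Optional[Keyword]:
        norm = normalize_phrase(phrase)
        for kw in self.keywords:
            if kw.phrase == norm and (polarity is None or kw.polarity == polarity):
                return kw
        return None

    def positive(self) -> list[Keyword]:
        return [k for k in self.keywords if k.polarity == POSITIVE]

    def negative(self) -> list[Keyword]:
        return [k for k in self.keywords if k.polarity == NEGATIVE]

    # -- mutations (return a new registry; the old version stays usable) ----

    def _commit(self, keywords: list[Keyword], message: str) -> "KeywordRegistry":
        log = list(self.revision_log)
        log.append({
            "version": self.version + 1,
            "change": message,
            "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        })
        return KeywordRegistry(keywords=keywords, version=self.version + 1,
                               revision_log=log)

    def add(self, phrase: str, polarity: str, weight: int) -> "KeywordRegistry":
        kw = Keyword(phrase, polarity, weight)
        existing = self.get(kw.phrase)
        if existing is not None:
            if existing.polarity != polarity:
                raise RegistryError(
                    f"phrase {kw.phrase!r} already registered with polarity "
                    f"{existing.polarity}; a phrase cannot carry both polarities"
                )
            raise RegistryError(f"keyword ({kw.phrase!r}, {polarity}) already present")
        return self._commit(self.keywords + [kw],
                            f"add {polarity} {kw.phrase!r} w={weight}")

    def revise_weight(self, phrase: str, polarity: str, new_weight: int) -> "KeywordRegistry":
        norm = normalize_phrase(phrase)
        existing = self.get(norm, polarity)
        if existing is None:
            raise RegistryError(f"keyword ({norm!r}, {polarity}) not in registry")
        new_kw = Keyword(norm, polarity, new_weight)
        keywords = [new_kw if k is existing else k for k in self.keywords]
        return self._commit(
            keywords,
            f"revise {polarity} {norm!r} w={existing.weight}->{new_weight}",
        )

    def remove(self, phrase: str, polarity: str) -> "KeywordRegistry":
        norm = normalize_phrase(phrase)
        existing = self.get(norm, polarity)
        if existing is None:
            raise RegistryError(f"keyword ({norm!r}, {polarity}) not in registry")
        keywords = [k for k in self.keywords if k is not existing]
        return self._commit(keywords, f"remove {polarity} {norm!r}")


# ---------------------------------------------------------------------------
# Persistence: keywords as a human-editable CSV, revision log in a sibling
# JSON file (<stem>.log.json).


def _log_path(path: Path) -> Path:
    return path.with_suffix(".log.json")


def save_registry(registry: KeywordRegistry, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phrase", "polarity", "weight"])
        for kw in registry.keywords:
            writer.writerow([kw.phrase, kw.polarity, kw.weight])
    with open(_log_path(path), "w", encoding="utf-8") as fh:
        json.dump({"version": registry.version, "revision_log": registry.revision_log},
                  fh, indent=2)
        fh.write("\n")


def load_registry(path: str | Path) -> KeywordRegistry:
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"no such registry file: {path}")
    keywords: list[Keyword] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"phrase", "polarity", "weight"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RegistryError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                weight = int(row["weight"])
            except (TypeError, ValueError):
                raise RegistryError(
                    f"{path} row {lineno}: weight {row.get('weight')!r} is not an integer"
                ) from None
            try:
                keywords.append(Keyword(row["phrase"], row["polarity"], weight))
            except RegistryError as exc:
                raise RegistryError(f"{path} row {lineno}: {exc}") from exc
    version, log = 0, []
    logp = _log_path(path)
    if logp.exists():
        with open(logp, encoding="utf-8") as fh:
            meta = json.load(fh)
        version, log = meta.get("version", 0), meta.get("revision_log", [])
    try:
        return KeywordRegistry(keywords=keywords, version=version, revision_log=log)
    except RegistryError as exc:
        raise RegistryError(f"{path}: {exc}") from exc


def registry_from_pairs(pairs) -> KeywordRegistry:
    """Build a registry from (phrase, polarity, weight) triples in one commit each."""
    reg = KeywordRegistry()
    for phrase, polarity, weight in pairs:
        reg = reg.add(phrase, polarity, weight)
    return reg
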