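"""Term scoring: weighted keyword matching over titles and abstracts.

The score for one record is

    TS = sum_p w_p * m_p  -  penalty * sum_n w_n * m_n

where the sums run over positive and negative keyword matches respectively,
w = expert weight / 10, and for each keyword

    m = (match count * keyword word count) / (word count of title + abstract).

The denominator normalises by document length, so duplicating a document's
text leaves TS unchanged, and the keyword-word-count factor lets multi-word
phrases count each constituent word.  The penalty on the negative sum
defaults to 1.2, biasing the score against records carrying irrelevance
markers.  Title-only screening (step 1 of the workflow) uses the same keyword
lists through :func:`title_screen`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .records import ArticleRecord
from .registry import Keyword, KeywordRegistry, NEGATIVE, POSITIVE
from .tokenize import tokenize_text

__all__ = [
    "TokenizedDoc",
    "MatchComponent",
    "TermScore",
    "ScoringConfig",
    "TitleRule",
    "ScoringError",
    "tokenize",
    "tokenize_record",
    "count_matches",
    "term_score",
    "title_screen",
    "score_records",
]

DEFAULT_PENALTY = 1.2


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class TokenizedDoc:
    """Ordered tokens of a record's title followed by its abstract."""

    tokens: tuple[str, ...]

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MatchComponent:
    """Per-keyword contribution to a term score.

    ``m`` is (match_count * keyword word count) / document word count;
    the weighted contribution is ``keyword.normalized_weight * m``.
    """

    keyword: Keyword
    match_count: int
    m: float

    @property
    def contribution(self) -> float:
        return self.keyword.normalized_weight * self.m


@dataclass(frozen=True)
class TermScore:
    """Decomposed term score: ts = pos_sum - penalty * neg_sum."""

    pos_sum: float
    neg_sum: float
    penalty: float
    ts: float
    components: tuple[MatchComponent, ...] = ()

    def rederive(self) -> float:
        """Recompute ts from the stored components (audit check)."""
        pos = sum(c.contribution for c in self.components
                  if c.keyword.polarity == POSITIVE)
        neg = sum(c.contribution for c in self.components
                  if c.keyword.polarity == NEGATIVE)
        return pos - self.penalty * neg


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring behaviour knobs.

    ``penalty`` multiplies the negative keyword sum (default 1.2).  Match
    counting is non-overlapping greedy left-to-right; the policy is named
    here so any future alternative is an explicit, recorded choice.
    """

    penalty: float = DEFAULT_PENALTY
    overlap_policy: Literal["non_overlapping"] = "non_overlapping"

    def __post_init__(self) -> None:
        if not self.penalty > 0:
            raise ScoringError(f"penalty must be > 0, got {self.penalty}")


@dataclass(frozen=True)
class TitleRule:
    """Title-elimination rule for step-1 screening.

    Default: eliminate a record iff its title matches at least one negative
    keyword and no positive keyword.  Decisions are meant for manual review,
    not silent deletion.
    """

    min_negative: int = 1
    max_positive: int = 0


def tokenize(title: Optional[str], abstract: Optional[str] = None) -> TokenizedDoc:
    """Tokenize title + abstract into one document (absent parts contribute nothing)."""
    return TokenizedDoc(tuple(tokenize_text(title) + tokenize_text(abstract)))


def tokenize_record(record: ArticleRecord, fields: str = "title+abstract") -> TokenizedDoc:
    if fields == "title":
        return tokenize(record.title)
    return tokenize(record.title, record.abstract)


def count_matches(doc: TokenizedDoc | Sequence[str], phrase: Sequence[str]) -> int:
    """Count non-overlapping, left-to-right occurrences of ``phrase`` in the doc.

    Greedy: each match consumes its tokens, so ``[a, a, a]`` contains the
    phrase ``[a, a]`` once, not twice.
    """
    tokens = doc.tokens if isinstance(doc, TokenizedDoc) else tuple(doc)
    phr = tuple(phrase)
    if not phr:
        raise ScoringError("phrase must be non-empty")
    n, k = len(tokens), len(phr)
    count = 0
    i = 0
    first = phr[0]
    while i <= n - k:
        if tokens[i] == first and tokens[i:i + k] == phr:
            count += 1
            i += k
        else:
            i += 1
    return count


def term_score(
    record: ArticleRecord | TokenizedDoc,
    registry: KeywordRegistry,
    config: Optional[ScoringConfig] = None,
) -> TermScore:
    """Compute the term score of one record over its title + abstract tokens.

    Raises :class:`ScoringError` on a tokenless document — such records carry
    no screenable text and should have been excluded upstream.
    """
    config = config or ScoringConfig()
    doc = record if isinstance(record, TokenizedDoc) else tokenize_record(record)
    if doc.word_count == 0:
        rid = getattr(record, "record_id", "<doc>")
        raise ScoringError(
            f"record {rid}: no tokens in title+abstract; term score undefined "
            "(record should have been excluded upstream)"
        )
    components: list[MatchComponent] = []
    pos_sum = neg_sum = 0.0
    for kw in registry:
        count = count_matches(doc, kw.tokens)
        if count == 0:
            continue
        m = count * kw.word_count / doc.word_count
        components.append(MatchComponent(keyword=kw, match_count=count, m=m))
        if kw.polarity == POSITIVE:
            pos_sum += kw.normalized_weight * m
        else:
            neg_sum += kw.normalized_weight * m
    ts = pos_sum - config.penalty * neg_sum
    return TermScore(pos_sum=pos_sum, neg_sum=neg_sum, penalty=config.penalty,
                     ts=ts, components=tuple(components))


def title_screen(
    record: ArticleRecord,
    registry: KeywordRegistry,
    rule: Optional[TitleRule] = None,
) -> str:
    """Step-1 decision for one record from its title alone.

    Returns ``"eliminate"`` or ``"retain"``.
    """
    rule = rule or TitleRule()
    doc = tokenize_record(record, fields="title")
    n_pos = sum(1 for kw in registry.positive() if count_matches(doc, kw.tokens) > 0)
    n_neg = sum(1 for kw in registry.negative() if count_matches(doc, kw.tokens) > 0)
    if n_neg >= rule.min_negative and n_pos <= rule.max_positive:
        return "eliminate"
    return "retain"


def score_records(records, registry: KeywordRegistry,
                  config: Optional[ScoringConfig] = None) -> dict[str, TermScore]:
    """Score every non-excluded record; returns record_id -> TermScore."""
    config = config or ScoringConfig()
    return {
        rec.record_id: term_score(rec, registry, config)
        for rec in records
        if not rec.excluded
    }
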