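"""Ranking of scored records and screening-evaluation statistics.

Rankings order records for manual screening: higher term score means a
smaller (better) rank number, and hard-excluded records always come last
regardless of score.  Evaluation against gold eligibility labels covers the
top-quartile eligible fraction, Spearman rank agreement between two
screening orders, recall-at-effort curves, reproducible seed/test splits,
export of labelled seed files for semi-automated screening tools, and a
simple workload estimator in reviewer-days.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .records import ArticleRecord, RecordSet
from .scoring import TermScore

__all__ = [
    "RankedRecord",
    "Ranking",
    "EvalReport",
    "RankingError",
    "rank_records",
    "validate_ranking",
    "quartile_eligible_fraction",
    "spearman_rho",
    "recall_curve",
    "recall_at_effort",
    "split_seed_test",
    "export_seed_file",
    "workload_days",
]


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class RankedRecord:
    record_id: str
    rank: int  # 1-based; smaller = screen earlier = more relevant
    ts: float
    excluded: bool


@dataclass
class Ranking:
    """Total order over records; excluded records are forced last."""

    entries: list[RankedRecord]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def rank_of(self, record_id: str) -> int:
        for e in self.entries:
            if e.record_id == record_id:
                return e.rank
        raise KeyError(record_id)

    def rank_map(self) -> dict[str, int]:
        return {e.record_id: e.rank for e in self.entries}

    def ordered_ids(self) -> list[str]:
        return [e.record_id for e in sorted(self.entries, key=lambda e: e.rank)]


@dataclass
class EvalReport:
    """Summary statistics for one ranking (or a comparison of two)."""

    n_total: int
    n_eligible: int
    quartile_eligible_fraction: Optional[float] = None
    spearman_rho: Optional[float] = None
    recall_curve: list[tuple[float, float]] = field(default_factory=list)
    rank_summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_eligible": self.n_eligible,
            "quartile_eligible_fraction": self.quartile_eligible_fraction,
            "spearman_rho": self.spearman_rho,
            "recall_curve": [list(p) for p in self.recall_curve],
            "rank_summaries": self.rank_summaries,
        }


def rank_records(
    scores: Mapping[str, TermScore | float],
    exclusions: Optional[Mapping[str, bool] | Iterable[str]] = None,
) -> Ranking:
    """Build a screening order from term scores and exclusion flags.

    Non-excluded records are sorted by score descending, ties broken by
    record_id (lexicographic) for reproducibility.  Excluded records follow
    in stable input order, whatever their scores.  Every record must carry a
    score or be excluded.
    """
    if exclusions is None:
        excluded_ids: set[str] = set()
        excluded_order: list[str] = []
    elif isinstance(exclusions, Mapping):
        excluded_order = [rid for rid, flag in exclusions.items() if flag]
        excluded_ids = set(excluded_order)
    else:
        excluded_order = list(exclusions)
        excluded_ids = set(excluded_order)

    missing = [rid for rid in excluded_ids if rid not in scores]
    scored_included = [(rid, _ts_value(s)) for rid, s in scores.items()
                       if rid not in excluded_ids]
    scored_included.sort(key=lambda kv: (-kv[1], kv[0]))

    entries: list[RankedRecord] = []
    rank = 0
    for rid, ts in scored_included:
        rank += 1
        entries.append(RankedRecord(rid, rank, ts, excluded=False))
    for rid in excluded_order:
        rank += 1
        ts = _ts_value(scores[rid]) if rid in scores else float("nan")
        entries.append(RankedRecord(rid, rank, ts, excluded=True))
    return Ranking(entries=entries)


def _ts_value(score: TermScore | float) -> float:
    return score.ts if isinstance(score, TermScore) else float(score)


def validate_ranking(ranking: Ranking) -> None:
    """Assert the ranking invariants; raises RankingError on violation.

    Checks: ranks are a permutation of 1..n; every excluded record ranks
    after every included one; scores are non-increasing over the included
    prefix.
    """
    n = len(ranking)
    ranks = sorted(e.rank for e in ranking)
    if ranks != list(range(1, n + 1)):
        raise RankingError("ranks are not a permutation of 1..n")
    by_rank = sorted(ranking.entries, key=lambda e: e.rank)
    max_included = max((e.rank for e in by_rank if not e.excluded), default=0)
    min_excluded = min((e.rank for e in by_rank if e.excluded), default=n + 1)
    if min_excluded <= max_included:
        raise RankingError("an excluded record ranks before an included one")
    included = [e for e in by_rank if not e.excluded]
    for prev, cur in zip(included, included[1:]):
        if cur.ts > prev.ts:
            raise RankingError("included scores are not non-increasing in rank")


# ---------------------------------------------------------------------------
# Evaluation statistics


def _eligible_ids(labels: Mapping[str, str] | RecordSet) -> set[str]:
    if isinstance(labels, RecordSet):
        return {r.record_id for r in labels if r.gold_label == "eligible"}
    return {rid for rid, lab in labels.items()
            if lab in ("eligible", 1, "1", True)}


def quartile_eligible_fraction(ranking: Ranking,
                               labels: Mapping[str, str] | RecordSet) -> float:
    """Fraction of eligible records ranked within the top quartile.

    Top quartile = ranks 1..ceil(n/4).  A well-performing screening order
    concentrates eligible records here; a random order yields ~0.25.
    """
    eligible = _eligible_ids(labels) & {e.record_id for e in ranking}
    if not eligible:
        raise RankingError("no eligible records; fraction undefined")
    cutoff = math.ceil(len(ranking) / 4)
    in_top = sum(1 for e in ranking if e.record_id in eligible and e.rank <= cutoff)
    return in_top / len(eligible)


def spearman_rho(ranks_a: Mapping[str, float] | Sequence[float],
                 ranks_b: Mapping[str, float] | Sequence[float]) -> float:
    """Spearman rank-order correlation with average ranks for ties.

    Accepts two aligned sequences, or two mappings over the same record set
    (aligned by key).  Undefined for n < 3 or constant input.
    """
    if isinstance(ranks_a, Mapping) or isinstance(ranks_b, Mapping):
        if not (isinstance(ranks_a, Mapping) and isinstance(ranks_b, Mapping)):
            raise RankingError("both arguments must be mappings, or both sequences")
        if set(ranks_a) != set(ranks_b):
            raise RankingError("mismatched record sets")
        keys = sorted(ranks_a)
        a = np.array([ranks_a[k] for k in keys], dtype=float)
        b = np.array([ranks_b[k] for k in keys], dtype=float)
    else:
        a = np.asarray(ranks_a, dtype=float)
        b = np.asarray(ranks_b, dtype=float)
        if a.shape != b.shape:
            raise RankingError("mismatched lengths")
    if a.size < 3:
        raise RankingError("need at least 3 paired observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise RankingError("constant input; Spearman rho undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def recall_curve(ranking: Ranking,
                 labels: Mapping[str, str] | RecordSet) -> list[tuple[float, float]]:
    """Recall-at-effort curve: for each prefix size k, (k/n, found(k)/n_eligible)."""
    eligible = _eligible_ids(labels) & {e.record_id for e in ranking}
    if not eligible:
        raise RankingError("no eligible records; recall undefined")
    n = len(ranking)
    ordered = ranking.ordered_ids()
    found = 0
    curve: list[tuple[float, float]] = []
    for k, rid in enumerate(ordered, start=1):
        if rid in eligible:
            found += 1
        curve.append((k / n, found / len(eligible)))
    return curve


def recall_at_effort(ranking: Ranking, labels, effort: float) -> float:
    """Recall after screening the top ``effort`` fraction of the ranking."""
    if not 0 < effort <= 1:
        raise RankingError("effort must be in (0, 1]")
    curve = recall_curve(ranking, labels)
    k = max(1, math.floor(effort * len(curve)))
    return curve[k - 1][1]


# ---------------------------------------------------------------------------
# Seed/test splitting and seed export


def split_seed_test(records: RecordSet, fraction: float,
                    rng_seed: int) -> tuple[RecordSet, RecordSet]:
    """Simple random split into a seed set and a test set.

    Seed size is round-half-up(fraction * n); the split is a partition and is
    reproducible under ``rng_seed``.
    """
    if not 0 < fraction < 1:
        raise RankingError(f"fraction must be in (0, 1), got {fraction}")
    n = len(records)
    n_seed = int(math.floor(fraction * n + 0.5))
    rng = np.random.default_rng(rng_seed)
    idx = rng.permutation(n)
    seed_idx = set(idx[:n_seed].tolist())
    seed = [records[i] for i in range(n) if i in seed_idx]
    test = [records[i] for i in range(n) if i not in seed_idx]
    prov = list(records.provenance)
    return (RecordSet(records=seed, provenance=prov + [f"seed split f={fraction} seed={rng_seed}"]),
            RecordSet(records=test, provenance=prov + [f"test split f={fraction} seed={rng_seed}"]))


def export_seed_file(records: RecordSet | Iterable[ArticleRecord],
                     path: str | Path,
                     decisions: Optional[Mapping[str, int]] = None) -> None:
    """Write a labelled seed CSV for a semi-automated screening tool.

    Columns: title, abstract, label (1 = relevant, 0 = irrelevant), matching
    the prior-knowledge import format common screening tools expect.
    ``decisions`` maps record_id -> 0/1; if omitted, gold labels are used.
    Every record must have a decision and an abstract (tools need text).
    """
    rows = []
    for rec in records:
        if decisions is not None:
            if rec.record_id not in decisions:
                raise RankingError(f"record {rec.record_id} lacks a screening decision")
            label = int(decisions[rec.record_id])
        else:
            if rec.gold_label is None:
                raise RankingError(f"record {rec.record_id} lacks a screening decision")
            label = 1 if rec.gold_label == "eligible" else 0
        if label not in (0, 1):
            raise RankingError(f"record {rec.record_id}: decision must be 0 or 1")
        if rec.abstract is None:
            raise RankingError(
                f"record {rec.record_id} has no abstract; seed export refused"
            )
        rows.append((rec.title, rec.abstract, label))
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["title", "abstract", "label"])
        writer.writerows(rows)


def workload_days(n_articles: int, daily_rate: int) -> int:
    """Whole reviewer-days to manually screen ``n_articles`` at ``daily_rate``/day.

    Uses the ceiling: 60,000 articles at 470/day is 128 days.
    """
    if daily_rate < 1:
        raise RankingError(f"daily_rate must be >= 1, got {daily_rate}")
    if n_articles < 0:
        raise RankingError(f"n_articles must be >= 0, got {n_articles}")
    return math.ceil(n_articles / daily_rate)
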