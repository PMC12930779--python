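"""Desk-scale simulation of semi-automated screening configurations.

The simulator emulates the two ways a screening tool is typically driven:

* **rank-once** — a stratified seed set of labelled relevant/irrelevant
  records trains a ranker once, which then orders all unscreened records;
* **active learning** — starting from a minimal seed, the top-ranked record
  is shown to a simulated reviewer (the gold label), the ranker refits, and
  the loop repeats until a screening budget or a stopping rule
  (k consecutive irrelevant decisions) is hit.

The external screening tool itself is out of scope; ranking is done by a
transparent, deterministic nearest-centroid bag-of-words ranker (cosine
similarity to the relevant centroid minus cosine similarity to the
irrelevant centroid).  It lives behind a small interface so an adapter to a
real tool could be slotted in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer

from .ranking import EvalReport, Ranking, rank_records, spearman_rho
from .records import RecordSet
from .tokenize import tokenize_text

__all__ = [
    "SimConfig",
    "ScreeningTrajectory",
    "ReferenceRanker",
    "SimulationError",
    "simulate_rank_once",
    "simulate_active",
    "compare_rankings",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """One screening-simulation configuration.

    ``n_seed_relevant``/``n_seed_irrelevant`` control the stratified seed
    sample; ``n_manual_screens`` is the reviewer's budget in active mode;
    ``stopping_k`` optionally ends active screening after k consecutive
    irrelevant decisions.
    """

    mode: str = "rank_once"  # "rank_once" | "active_learning"
    n_seed_relevant: int = 1
    n_seed_irrelevant: int = 1
    n_manual_screens: int = 20
    rng_seed: int = 0
    stopping_k: Optional[int] = None
    ranker: str = "nearest_centroid"

    def __post_init__(self) -> None:
        if self.mode not in ("rank_once", "active_learning"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.n_seed_relevant < 0 or self.n_seed_irrelevant < 0:
            raise SimulationError("seed counts must be >= 0")
        if self.mode == "rank_once" and (
            self.n_seed_relevant < 1 or self.n_seed_irrelevant < 1
        ):
            raise SimulationError(
                "rank_once mode requires at least 1 relevant and 1 irrelevant seed"
            )
        if self.stopping_k is not None and self.stopping_k < 1:
            raise SimulationError("stopping_k must be >= 1")


@dataclass
class ScreeningTrajectory:
    """Ordered log of simulated manual screening decisions.

    Each step records the id screened, its rank among unscreened records at
    screening time (always 1 under the greedy policy), and the gold label
    revealed.  ``stop_index`` is set when the stopping rule fired.
    ``final_ranking`` orders the records still unscreened when the
    simulation ended.
    """

    steps: list[tuple[int, str, int, str]] = field(default_factory=list)
    stop_index: Optional[int] = None
    seed_ids: list[str] = field(default_factory=list)
    final_ranking: Optional[Ranking] = None

    def __len__(self) -> int:
        return len(self.steps)

    def screened_ids(self) -> list[str]:
        return self.seed_ids + [rid for _, rid, _, _ in self.steps]

    def labels(self) -> list[str]:
        return [lab for _, _, _, lab in self.steps]


class ReferenceRanker:
    """Deterministic nearest-centroid bag-of-words relevance ranker.

    Documents (title + abstract) are vectorised once as term-count vectors
    over the corpus vocabulary; a candidate's score is its cosine similarity
    to the centroid of screened-relevant documents minus its cosine
    similarity to the centroid of screened-irrelevant documents.
    """

    def __init__(self, corpus: RecordSet):
        self._ids = corpus.ids()
        self._index = {rid: i for i, rid in enumerate(self._ids)}
        texts = [
            (rec.title or "") + " " + (rec.abstract or "") for rec in corpus
        ]
        vectorizer = CountVectorizer(analyzer=tokenize_text)
        X = vectorizer.fit_transform(texts).astype(np.float64)
        norms = np.asarray(sparse.linalg.norm(X, axis=1)).ravel()
        norms[norms == 0] = 1.0
        self._X = X
        self._X_unit = sparse.diags(1.0 / norms) @ X

    def score(
        self,
        relevant_ids: Sequence[str],
        irrelevant_ids: Sequence[str],
        candidate_ids: Sequence[str],
    ) -> dict[str, float]:
        """Score candidates given the screened sets; higher = more relevant."""
        if not relevant_ids or not irrelevant_ids:
            raise SimulationError(
                "ranker needs at least one screened record per class"
            )
        sims = []
        for ids in (relevant_ids, irrelevant_ids):
            rows = [self._index[r] for r in ids]
            centroid = np.asarray(self._X[rows].mean(axis=0)).ravel()
            norm = np.linalg.norm(centroid)
            if norm == 0:
                sims.append(np.zeros(len(candidate_ids)))
                continue
            cand_rows = [self._index[r] for r in candidate_ids]
            sims.append(self._X_unit[cand_rows] @ (centroid / norm))
        scores = sims[0] - sims[1]
        return {rid: float(s) for rid, s in zip(candidate_ids, scores)}


def _sample_seeds(corpus: RecordSet, config: SimConfig) -> tuple[list[str], list[str]]:
    relevant = sorted(r.record_id for r in corpus if r.gold_label == "eligible")
    irrelevant = sorted(r.record_id for r in corpus if r.gold_label == "ineligible")
    if len(relevant) < config.n_seed_relevant:
        raise SimulationError(
            f"corpus has {len(relevant)} relevant records, "
            f"{config.n_seed_relevant} seeds requested"
        )
    if len(irrelevant) < config.n_seed_irrelevant:
        raise SimulationError(
            f"corpus has {len(irrelevant)} irrelevant records, "
            f"{config.n_seed_irrelevant} seeds requested"
        )
    rng = np.random.default_rng(config.rng_seed)
    seed_rel = sorted(rng.choice(relevant, size=config.n_seed_relevant,
                                 replace=False).tolist())
    seed_irr = sorted(rng.choice(irrelevant, size=config.n_seed_irrelevant,
                                 replace=False).tolist())
    return seed_rel, seed_irr


def simulate_rank_once(
    corpus: RecordSet,
    config: SimConfig,
    seed_ids: Optional[tuple[Sequence[str], Sequence[str]]] = None,
    ranker: Optional[ReferenceRanker] = None,
) -> Ranking:
    """Rank-once simulation: fit on a seed set, rank the rest once.

    ``seed_ids`` may supply explicit (relevant, irrelevant) id lists — e.g.
    a pre-made 70% split — instead of sampling by ``rng_seed``.  Returns a
    ranking over the unscreened records (empty if seeds cover the corpus).
    """
    if seed_ids is None:
        seed_rel, seed_irr = _sample_seeds(corpus, config)
    else:
        seed_rel, seed_irr = list(seed_ids[0]), list(seed_ids[1])
        if not seed_rel or not seed_irr:
            raise SimulationError(
                "rank_once mode requires at least 1 relevant and 1 irrelevant seed"
            )
    screened = set(seed_rel) | set(seed_irr)
    candidates = [rid for rid in corpus.ids() if rid not in screened]
    if not candidates:
        return Ranking(entries=[])
    ranker = ranker or ReferenceRanker(corpus)
    scores = ranker.score(seed_rel, seed_irr, candidates)
    return rank_records(scores)


def simulate_active(
    corpus: RecordSet,
    config: SimConfig,
    ranker: Optional[ReferenceRanker] = None,
) -> ScreeningTrajectory:
    """Active-learning simulation with the gold label as simulated reviewer.

    Loop: rank unscreened records, screen the top-ranked one (reveal its
    gold label), refit, repeat for ``n_manual_screens`` steps or until
    ``stopping_k`` consecutive irrelevant decisions.
    """
    if config.n_seed_relevant < 1 or config.n_seed_irrelevant < 1:
        raise SimulationError(
            "active learning requires at least 1 relevant and 1 irrelevant seed"
        )
    seed_rel, seed_irr = _sample_seeds(corpus, config)
    ranker = ranker or ReferenceRanker(corpus)
    labels = {r.record_id: r.gold_label for r in corpus}

    relevant, irrelevant = list(seed_rel), list(seed_irr)
    screened = set(relevant) | set(irrelevant)
    unscreened = [rid for rid in corpus.ids() if rid not in screened]
    traj = ScreeningTrajectory(seed_ids=relevant + irrelevant)
    consecutive_irrelevant = 0
    for step in range(1, config.n_manual_screens + 1):
        if not unscreened:
            break
        scores = ranker.score(relevant, irrelevant, unscreened)
        top = max(unscreened, key=lambda rid: (scores[rid], rid))
        label = labels[top] or "ineligible"
        traj.steps.append((step, top, 1, label))
        unscreened.remove(top)
        if label == "eligible":
            relevant.append(top)
            consecutive_irrelevant = 0
        else:
            irrelevant.append(top)
            consecutive_irrelevant += 1
        if config.stopping_k is not None and consecutive_irrelevant >= config.stopping_k:
            traj.stop_index = step
            break
    if unscreened:
        scores = ranker.score(relevant, irrelevant, unscreened)
        traj.final_ranking = rank_records(scores)
    else:
        traj.final_ranking = Ranking(entries=[])
    return traj


def compare_rankings(
    ranking_a: Ranking,
    ranking_b: Ranking,
    labels: Mapping[str, str] | RecordSet,
) -> EvalReport:
    """Compare two screening orders over the same record set.

    Reports Spearman's rho between the two rank vectors and, per ranking,
    the median and quartiles of eligible vs ineligible record ranks.
    """
    ids_a = {e.record_id for e in ranking_a}
    ids_b = {e.record_id for e in ranking_b}
    if ids_a != ids_b:
        raise SimulationError("rankings cover different record sets")
    rho = spearman_rho(ranking_a.rank_map(), ranking_b.rank_map())
    if isinstance(labels, RecordSet):
        label_map = {r.record_id: r.gold_label for r in labels}
    else:
        label_map = dict(labels)
    eligible = {rid for rid in ids_a if label_map.get(rid) == "eligible"}

    summaries: dict[str, dict[str, float]] = {}
    for name, ranking in (("a", ranking_a), ("b", ranking_b)):
        for cls, members in (("eligible", eligible), ("ineligible", ids_a - eligible)):
            ranks = np.array([e.rank for e in ranking if e.record_id in members])
            if ranks.size:
                q1, med, q3 = np.percentile(ranks, [25, 50, 75])
                summaries[f"{name}_{cls}"] = {
                    "q1": float(q1), "median": float(med), "q3": float(q3),
                    "n": int(ranks.size),
                }
    return EvalReport(
        n_total=len(ids_a),
        n_eligible=len(eligible),
        spearman_rho=rho,
        rank_summaries=summaries,
    )
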