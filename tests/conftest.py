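import numpy as np
import pytest
from hypothesis import settings

from termscreen import (
    ArticleRecord,
    RecordSet,
    benchmark_corpus,
    benchmark_registry,
    flag_exclusions,
    registry_from_pairs,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_registry():
    return registry_from_pairs([
        ("sleep quality", "positive", 8),
        ("longitudinal", "positive", 10),
        ("rat", "negative", 5),
        ("in vitro", "negative", 9),
    ])


@pytest.fixture
def make_record():
    def _make(record_id="r1", title="a title", doi="10.1/x",
              abstract="word " * 50, **kw):
        return ArticleRecord(record_id=record_id, title=title, doi=doi,
                             abstract=abstract, **kw)
    return _make


@pytest.fixture
def sample_records(make_record):
    return RecordSet(records=[
        make_record("r1", title="Sleep quality in a longitudinal cohort",
                    gold_label="eligible"),
        make_record("r2", title="Protein folding in vitro", gold_label="ineligible"),
        make_record("r3", title="No abstract here", abstract=None,
                    gold_label="ineligible"),
        make_record("r4", title="Short abstract", abstract="x" * 199,
                    gold_label="eligible"),
        make_record("r5", title="A review of things", article_type="review",
                    gold_label="ineligible"),
    ])


@pytest.fixture(scope="session")
def benchmark():
    """The fixed strong-planting benchmark corpus, flagged, with its registry."""
    corpus = benchmark_corpus()
    flagged = flag_exclusions(corpus.records)
    labels = {r.record_id: r.gold_label for r in flagged}
    return flagged, benchmark_registry(), labels


def random_doc_and_registry(rng: np.random.Generator):
    """One fuzz case: a random token document and a compatible random registry.

    Documents mix background tokens with occurrences of the registry phrases
    so matches actually happen; phrases are 1-2 tokens from a small shared
    vocabulary, split between polarities.
    """
    vocab = [f"t{i}" for i in range(12)]
    n_kw = int(rng.integers(1, 7))
    phrases, seen = [], set()
    while len(phrases) < n_kw:
        k = int(rng.integers(1, 3))
        phrase = " ".join(rng.choice(vocab, size=k))
        if phrase not in seen:
            seen.add(phrase)
            phrases.append(phrase)
    polarities = ["positive" if rng.random() < 0.5 else "negative" for _ in phrases]
    weights = [int(rng.integers(1, 11)) for _ in phrases]
    registry = registry_from_pairs(list(zip(phrases, polarities, weights)))

    n_tokens = int(rng.integers(1, 60))
    tokens = list(rng.choice(vocab + ["zz1", "zz2", "zz3"], size=n_tokens))
    return tokens, registry


def naive_term_score(tokens, registry, penalty=1.2):
    """Independent quadratic-scan oracle for the term score.

    Finds all occurrence start positions of each phrase, then selects
    non-overlapping ones left-to-right — a different route from the
    production single-pass scan.
    """
    n = len(tokens)
    pos_sum = neg_sum = 0.0
    for kw in registry:
        ph = list(kw.tokens)
        k = len(ph)
        starts = [i for i in range(n - k + 1) if tokens[i:i + k] == ph]
        count, blocked_until = 0, 0
        for s in starts:
            if s >= blocked_until:
                count += 1
                blocked_until = s + k
        m = count * k / n
        if kw.polarity == "positive":
            pos_sum += (kw.weight / 10) * m
        else:
            neg_sum += (kw.weight / 10) * m
    return pos_sum - penalty * neg_sum
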