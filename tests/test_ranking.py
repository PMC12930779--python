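import itertools

import numpy as np
import pytest
from scipy import stats

from termscreen import (
    RankingError,
    RecordSet,
    export_seed_file,
    quartile_eligible_fraction,
    rank_records,
    read_records,
    recall_at_effort,
    recall_curve,
    spearman_rho,
    split_seed_test,
    validate_ranking,
    workload_days,
)
from termscreen.ranking import Ranking, RankedRecord


def ranking_from_order(ids, excluded=()):
    return Ranking(entries=[
        RankedRecord(rid, i + 1, float(len(ids) - i), rid in excluded)
        for i, rid in enumerate(ids)
    ])


class TestRankRecords:
    def test_sorted_by_score_descending(self):
        ranking = rank_records({"A": 0.5, "B": 0.9})
        assert ranking.ordered_ids() == ["B", "A"]
        validate_ranking(ranking)

    def test_excluded_record_ranks_last_regardless_of_score(self):
        ranking = rank_records({"C": 99.0, "D": 0.01}, exclusions=["C"])
        assert ranking.ordered_ids() == ["D", "C"]
        validate_ranking(ranking)

    def test_score_ties_break_by_record_id(self):
        ranking = rank_records({"F": 1.0, "E": 1.0})
        assert ranking.ordered_ids() == ["E", "F"]

    def test_multiple_excluded_keep_stable_input_order(self):
        ranking = rank_records({"a": 1.0, "b": 5.0, "c": 3.0},
                               exclusions=["b", "a"])
        assert ranking.ordered_ids() == ["c", "b", "a"]
        validate_ranking(ranking)

    def test_validator_rejects_broken_invariants(self):
        bad_perm = Ranking(entries=[RankedRecord("a", 1, 1.0, False),
                                    RankedRecord("b", 3, 0.5, False)])
        with pytest.raises(RankingError, match="permutation"):
            validate_ranking(bad_perm)
        excluded_first = Ranking(entries=[RankedRecord("a", 1, 1.0, True),
                                          RankedRecord("b", 2, 0.5, False)])
        with pytest.raises(RankingError, match="excluded"):
            validate_ranking(excluded_first)
        unsorted = Ranking(entries=[RankedRecord("a", 1, 0.1, False),
                                    RankedRecord("b", 2, 0.9, False)])
        with pytest.raises(RankingError, match="non-increasing"):
            validate_ranking(unsorted)


class TestQuartileEligibleFraction:
    def test_perfect_ranking_with_few_eligible_is_exactly_one(self):
        ids = [f"r{i:02d}" for i in range(12)]
        labels = {rid: "eligible" if i < 3 else "ineligible"
                  for i, rid in enumerate(ids)}
        assert quartile_eligible_fraction(ranking_from_order(ids), labels) == 1.0

    def test_worked_example_n8_two_of_three_in_top_quartile(self):
        ids = [f"r{i}" for i in range(8)]
        labels = {rid: "ineligible" for rid in ids}
        labels["r0"] = labels["r1"] = labels["r4"] = "eligible"  # ranks 1, 2, 5
        frac = quartile_eligible_fraction(ranking_from_order(ids), labels)
        assert frac == pytest.approx(2 / 3)

    def test_no_eligible_records_is_an_error(self):
        ids = ["a", "b", "c"]
        with pytest.raises(RankingError):
            quartile_eligible_fraction(ranking_from_order(ids),
                                       {rid: "ineligible" for rid in ids})

    def test_random_rankings_average_one_quarter(self):
        rng = np.random.default_rng(7)
        n, n_eligible = 200, 40
        ids = [f"r{i:03d}" for i in range(n)]
        labels = {rid: "eligible" if i < n_eligible else "ineligible"
                  for i, rid in enumerate(ids)}
        fracs = []
        for _ in range(500):
            order = [ids[j] for j in rng.permutation(n)]
            fracs.append(quartile_eligible_fraction(ranking_from_order(order), labels))
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.02)


def brute_force_spearman(a, b):
    """Average-rank Spearman via explicit rank assignment + Pearson."""
    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x), dtype=float)
        i = 0
        sx = np.asarray(x, dtype=float)[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    return stats.pearsonr(avg_ranks(a), avg_ranks(b)).statistic


class TestSpearman:
    def test_identity_reversal_and_worked_example(self):
        a = [1, 2, 3, 4]
        assert spearman_rho(a, a) == pytest.approx(1.0)
        assert spearman_rho(a, a[::-1]) == pytest.approx(-1.0)
        # classical no-ties formula: 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/60
        assert spearman_rho(a, [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_symmetry_and_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(30), rng.random(30)
        assert spearman_rho(a, b) == pytest.approx(spearman_rho(b, a))
        assert spearman_rho(np.exp(5 * a), b) == pytest.approx(spearman_rho(a, b))

    def test_tie_handling_matches_average_rank_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            a = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            b = rng.integers(0, 5, size=n).astype(float)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            assert spearman_rho(a, b) == pytest.approx(
                brute_force_spearman(a, b), abs=1e-12)

    def test_errors_on_mismatch_and_constants(self):
        with pytest.raises(RankingError, match="mismatch"):
            spearman_rho({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "d": 3})
        with pytest.raises(RankingError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(RankingError, match="at least 3"):
            spearman_rho([1, 2], [2, 1])


class TestRecallCurve:
    def _labels(self, ids, eligible):
        return {rid: "eligible" if rid in eligible else "ineligible" for rid in ids}

    def test_perfect_ranking_reaches_full_recall_at_prevalence_effort(self):
        ids = [f"r{i}" for i in range(10)]
        labels = self._labels(ids, set(ids[:3]))
        curve = recall_curve(ranking_from_order(ids), labels)
        assert curve[2] == (0.3, 1.0)
        assert curve[-1] == (1.0, 1.0)

    def test_worst_ranking_finds_nothing_before_the_tail(self):
        ids = [f"r{i}" for i in range(10)]
        labels = self._labels(ids, set(ids[-3:]))
        ranking = ranking_from_order(ids)
        assert recall_at_effort(ranking, labels, 0.7) == 0.0
        assert recall_at_effort(ranking, labels, 1.0) == 1.0

    def test_curve_is_nondecreasing_and_ends_at_one(self):
        rng = np.random.default_rng(5)
        ids = [f"r{i}" for i in range(50)]
        labels = self._labels(ids, set(rng.choice(ids, 10, replace=False)))
        order = [ids[j] for j in rng.permutation(50)]
        curve = recall_curve(ranking_from_order(order), labels)
        recalls = [r for _, r in curve]
        assert recalls == sorted(recalls)
        assert curve[-1] == (1.0, 1.0)

    def test_random_ranking_expected_recall_half_at_half_effort(self):
        rng = np.random.default_rng(17)
        ids = [f"r{i:03d}" for i in range(100)]
        labels = self._labels(ids, set(ids[:20]))
        vals = []
        for _ in range(500):
            order = [ids[j] for j in rng.permutation(100)]
            vals.append(recall_at_effort(ranking_from_order(order), labels, 0.5))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


class TestSplit:
    def test_ten_records_at_seventy_percent_split_seven_three(self, sample_records,
                                                              make_record):
        recs = RecordSet(records=[make_record(f"r{i}") for i in range(10)])
        seed, test = split_seed_test(recs, 0.7, rng_seed=1)
        assert (len(seed), len(test)) == (7, 3)

    def test_same_seed_gives_identical_split(self, make_record):
        recs = RecordSet(records=[make_record(f"r{i}") for i in range(30)])
        s1, t1 = split_seed_test(recs, 0.7, rng_seed=99)
        s2, t2 = split_seed_test(recs, 0.7, rng_seed=99)
        assert s1.ids() == s2.ids() and t1.ids() == t2.ids()

    def test_split_is_a_partition_over_fuzzed_inputs(self, make_record):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(2, 60))
            frac = float(rng.uniform(0.1, 0.9))
            recs = RecordSet(records=[make_record(f"r{i}") for i in range(n)])
            seed, test = split_seed_test(recs, frac, int(rng.integers(1 << 16)))
            assert set(seed.ids()) | set(test.ids()) == set(recs.ids())
            assert set(seed.ids()) & set(test.ids()) == set()

    def test_fraction_out_of_range_rejected(self, make_record):
        recs = RecordSet(records=[make_record("a"), make_record("b")])
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(RankingError):
                split_seed_test(recs, frac, 1)


class TestSeedExport:
    def test_export_writes_labelled_rows(self, make_record, tmp_path):
        recs = RecordSet(records=[
            make_record(f"r{i}", gold_label="eligible" if i < 2 else "ineligible")
            for i in range(5)])
        path = tmp_path / "seeds.csv"
        export_seed_file(recs, path)
        import csv
        rows = list(csv.DictReader(open(path)))
        assert len(rows) == 5
        assert sum(int(r["label"]) for r in rows) == 2
        assert set(rows[0]) == {"title", "abstract", "label"}

    def test_record_without_decision_is_refused(self, make_record, tmp_path):
        recs = RecordSet(records=[make_record("r1")])  # no gold label
        with pytest.raises(RankingError, match="decision"):
            export_seed_file(recs, tmp_path / "s.csv")

    def test_record_without_abstract_is_refused(self, make_record, tmp_path):
        recs = RecordSet(records=[make_record("r1", abstract=None,
                                              gold_label="eligible")])
        with pytest.raises(RankingError, match="abstract"):
            export_seed_file(recs, tmp_path / "s.csv")


class TestWorkload:
    @pytest.mark.parametrize("n,rate,expected", [
        (60000, 470, 128),   # 60,000/470 = 127.66 -> 128 whole days
        (470, 470, 1),
        (0, 470, 0),
        (471, 470, 2),
    ])
    def test_ceiling_days(self, n, rate, expected):
        assert workload_days(n, rate) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(RankingError):
            workload_days(100, 0)
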