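"""Group analysis: decoding accuracy, median split, tests, aggregation."""

import numpy as np
import pytest
from scipy import stats as sps

from storynf import (
    FeedbackEvent,
    SessionLog,
    UndefinedDecodingAccuracyError,
    aggregate,
    bonferroni,
    decoding_accuracy,
    group_ttest,
    median_split,
    pearson_r,
    summarize_participant,
)
from storynf.analysis import BEST, WORST, ParticipantSummary
from storynf.rngs import CHEATING, PARANOID


def _log(pid, group, pcs, choices, rewards=None, runs=None):
    rewards = rewards if rewards is not None else [0.0] * len(pcs)
    runs = runs if runs is not None else [1 + i // 7 for i in range(len(pcs))]
    log = SessionLog(participant_id=pid, assigned_group=group, seed=0)
    for i, (p, c, r, run) in enumerate(zip(pcs, choices, rewards, runs)):
        log.events.append(
            FeedbackEvent(
                run=run, station_index=i % 7, p_c=p, score_c=p, score_final=p,
                score_reward=r, payout=0.0, probe_choice=c, feedback_onset_tr=10 + i,
            )
        )
    return log


class TestDecodingAccuracy:
    def test_simple_difference(self):
        log = _log(
            "sub-01", CHEATING,
            [0.7, 0.7, 0.4, 0.4], [CHEATING, CHEATING, PARANOID, PARANOID],
        )
        assert decoding_accuracy(log) == pytest.approx(0.3)

    def test_identical_pc_gives_zero(self):
        log = _log("sub-01", CHEATING, [0.6] * 4, [CHEATING, PARANOID] * 2)
        assert decoding_accuracy(log) == 0.0

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(8)
        pcs = rng.uniform(0, 1, size=28).tolist()
        choices = rng.choice([CHEATING, PARANOID], size=28).tolist()
        log = _log("sub-01", PARANOID, pcs, choices)
        tot_c = n_c = tot_p = n_p = 0.0
        for p, c in zip(pcs, choices):
            if c == CHEATING:
                tot_c, n_c = tot_c + p, n_c + 1
            else:
                tot_p, n_p = tot_p + p, n_p + 1
        assert decoding_accuracy(log) == pytest.approx(tot_c / n_c - tot_p / n_p, abs=1e-12)

    def test_single_label_flagged_not_dropped(self):
        log = _log("sub-01", CHEATING, [0.5] * 4, [CHEATING] * 4)
        with pytest.raises(UndefinedDecodingAccuracyError):
            decoding_accuracy(log)
        summary = summarize_participant(log)
        assert not summary.accuracy_defined
        assert np.isnan(summary.decoding_accuracy)


def _summary(pid, group, acc):
    return ParticipantSummary(participant_id=pid, assigned_group=group, decoding_accuracy=acc)


class TestMedianSplit:
    def test_twenty_participants_five_best_per_group(self):
        rng = np.random.default_rng(0)
        summaries = [
            _summary(f"sub-{i:02d}", CHEATING if i < 10 else PARANOID, float(rng.normal()))
            for i in range(20)
        ]
        split = median_split(summaries)
        for group, lo, hi in ((CHEATING, 0, 10), (PARANOID, 10, 20)):
            best = [s for s in summaries[lo:hi] if split[s.participant_id] == BEST]
            assert len(best) == 5
        assert sum(v == BEST for v in split.values()) == 10

    def test_all_equal_accuracies_tiebreak_is_deterministic(self):
        summaries = [_summary(f"sub-{i:02d}", CHEATING, 0.1) for i in range(10)]
        split = median_split(summaries)
        assert sum(v == BEST for v in split.values()) == 5
        # lexicographically earliest ids win the tie for 'best'
        assert split["sub-00"] == BEST and split["sub-09"] == WORST
        assert split == median_split(summaries)

    def test_membership_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        accs = rng.uniform(-0.2, 0.4, size=10)
        summaries = [_summary(f"sub-{i:02d}", PARANOID, float(a)) for i, a in enumerate(accs)]
        split = median_split(summaries)
        order = sorted(range(10), key=lambda i: (-accs[i], f"sub-{i:02d}"))
        for rank, i in enumerate(order):
            assert split[f"sub-{i:02d}"] == (BEST if rank < 5 else WORST)

    def test_odd_group_requires_policy(self):
        summaries = [_summary(f"sub-{i}", CHEATING, float(i)) for i in range(5)]
        with pytest.raises(ValueError):
            median_split(summaries)
        split = median_split(summaries, odd_policy="extra_best")
        assert sum(v == BEST for v in split.values()) == 3

    def test_undefined_accuracy_rejected(self):
        summaries = [_summary("sub-00", CHEATING, np.nan), _summary("sub-01", CHEATING, 0.1)]
        summaries[0].accuracy_defined = False
        with pytest.raises(UndefinedDecodingAccuracyError):
            median_split(summaries)


class TestGroupTTest:
    def test_identical_means_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        t, df, p = group_ttest(vals, labels)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ten_vs_ten_has_df_18(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        labels = [CHEATING] * 10 + [PARANOID] * 10
        _, df, _ = group_ttest(vals, labels)
        assert df == 18

    def test_matches_closed_form_oracle(self):
        """Textbook pooled-variance computation to 1e-10."""
        a = np.array([2.1, 3.4, 1.9, 2.8, 3.0])
        b = np.array([1.2, 1.9, 2.2, 1.4])
        vals = np.concatenate([a, b])
        labels = ["a"] * 5 + ["b"] * 4
        t, df, p = group_ttest(vals, labels)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(a) + len(b) - 2)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == 7
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_one_tailed_direction(self):
        a = [3.0, 3.5, 4.0]
        b = [1.0, 1.5, 2.0]
        vals = a + b
        labels = ["a"] * 3 + ["b"] * 3
        t2, _, p2 = group_ttest(vals, labels)
        t1, _, p1 = group_ttest(vals, labels, tails="one", direction="greater")
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2 / 2)
        _, _, p_wrong = group_ttest(vals, labels, tails="one", direction="less")
        assert p_wrong == pytest.approx(1 - p2 / 2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0, 2.0], ["a", "a"])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_antilinear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_manual_formula(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = pearson_r(x, y)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t_hand = r_hand * np.sqrt(13 / (1 - r_hand**2))
        p_hand = 2 * sps.t.sf(abs(t_hand), 13)
        assert r == pytest.approx(r_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_p_matches_permutation_oracle(self):
        """The analytic p agrees with a label-permutation null within
        Monte-Carlo error."""
        rng = np.random.default_rng(21)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        r_obs, p_analytic = pearson_r(x, y)
        n_perm = 4000
        exceed = sum(
            abs(pearson_r(x, rng.permutation(y))[0]) >= abs(r_obs) for _ in range(n_perm)
        )
        p_perm = exceed / n_perm
        assert abs(p_perm - p_analytic) < 3 * np.sqrt(p_analytic * (1 - p_analytic) / n_perm) + 0.005

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    def test_station_family_survival(self):
        assert bonferroni([0.0016], 7)[0] == pytest.approx(0.0112)
        assert bonferroni([0.0016], 7)[0] < 0.05

    def test_run_family_nonsurvival(self):
        assert bonferroni([0.015], 4)[0] == pytest.approx(0.06)
        assert bonferroni([0.015], 4)[0] > 0.05

    def test_capped_at_one(self):
        assert bonferroni([1.0], 10)[0] == 1.0
        assert bonferroni([0.4, 0.9], 5).tolist() == [1.0, 1.0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)


class TestAggregate:
    def _random_logs(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        logs = []
        for i in range(n):
            group = CHEATING if i % 2 == 0 else PARANOID
            pcs = rng.uniform(0, 1, size=14).tolist()
            choices = rng.choice([CHEATING, PARANOID], size=14).tolist()
            rewards = rng.uniform(0, 1, size=14).tolist()
            logs.append(_log(f"sub-{i:02d}", group, pcs, choices, rewards))
        return logs

    def test_matches_nested_loop_oracle(self):
        logs = self._random_logs()
        table = aggregate(logs, by=["run", "group"])
        # brute force: participant means first, then across participants
        for run in (1, 2):
            for group in (CHEATING, PARANOID):
                per_part = []
                for log in logs:
                    if log.assigned_group != group:
                        continue
                    vals = [e.p_c for e in log.events if e.run == run]
                    if vals:
                        per_part.append(np.mean(vals))
                row = table[
                    (table["run"] == run) & (table["group"] == group) & (table["measure"] == "p_c")
                ].iloc[0]
                assert row["mean"] == pytest.approx(np.mean(per_part), abs=1e-10)
                assert row["sem"] == pytest.approx(sps.sem(per_part), abs=1e-10)
                assert row["n"] == len(per_part)

    def test_identical_participants_have_zero_sem(self):
        pcs = [0.6] * 14
        choices = [CHEATING] * 14
        logs = [
            _log("sub-00", CHEATING, pcs, choices),
            _log("sub-01", CHEATING, pcs, choices),
        ]
        table = aggregate(logs, by=["group"])
        assert (table["sem"] == 0).all()

    def test_single_participant_sem_flagged_nan(self):
        logs = self._random_logs(n=1)
        table = aggregate(logs, by=["group"])
        assert table["sem"].isna().all()
        assert (table["n"] == 1).all()

    def test_empty_and_bad_keys_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], by=["run"])
        with pytest.raises(ValueError):
            aggregate(self._random_logs(), by=["banana"])
        with pytest.raises(ValueError):
            aggregate(self._random_logs(), by=["split"])  # no split mapping
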