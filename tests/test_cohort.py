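"""Synthetic cohort generation: templates, patterns, cohorts, questionnaires."""

import numpy as np
import pytest

from storynf import (
    AgentState,
    CohortConfig,
    StationSpec,
    default_stations,
    generate_pilot_cohort,
    generate_questionnaire,
    generate_training_cohort,
    make_templates,
    sample_station_pattern,
    train_station_models,
)
from storynf.behavior import score_interpretation


class TestMakeTemplates:
    def test_zero_separation_gives_identical_templates(self):
        tp = make_templates(n_features=10, separation=0.0, seed=1)
        np.testing.assert_array_equal(tp.template_cheating, tp.template_paranoid)

    @pytest.mark.parametrize("separation", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("seed", [1, 2, 33])
    def test_template_distance_equals_separation(self, separation, seed):
        tp = make_templates(n_features=50, separation=separation, seed=seed)
        # independent norm route: explicit sum of squared differences
        d = np.sqrt(np.sum((tp.template_cheating - tp.template_paranoid) ** 2))
        assert d == pytest.approx(separation, abs=1e-12)

    def test_different_seeds_different_bases_same_distance(self):
        a = make_templates(50, 1.0, seed=1)
        b = make_templates(50, 1.0, seed=2)
        assert not np.allclose(a.midpoint, b.midpoint)
        da = np.linalg.norm(a.template_cheating - a.template_paranoid)
        db = np.linalg.norm(b.template_cheating - b.template_paranoid)
        assert da == pytest.approx(db, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = make_templates(30, 2.0, seed=5)
        b = make_templates(30, 2.0, seed=5)
        np.testing.assert_array_equal(a.template_cheating, b.template_cheating)

    @pytest.mark.parametrize("bad", [0, 1, -3])
    def test_invalid_n_features_rejected(self, bad):
        with pytest.raises(ValueError):
            make_templates(bad, 1.0, seed=0)


class TestSampleStationPattern:
    station = StationSpec(station_index=0, start_tr=40, n_trs=4, bias=0.0)

    def test_neutral_agent_noise_off_sits_at_midpoint(self, templates20):
        state = AgentState(theta=0.0)
        pat = sample_station_pattern(
            state, self.station, templates20, snr=1.0,
            rng=np.random.default_rng(0), noise_sd=0.0,
        )
        np.testing.assert_allclose(pat, templates20.midpoint, atol=1e-12)

    def test_positive_theta_noise_off_lands_on_cheating_side(self, templates20):
        state = AgentState(theta=1.0)
        pat = sample_station_pattern(
            state, self.station, templates20, snr=10.0,
            rng=np.random.default_rng(0), noise_sd=0.0,
        )
        proj = (pat - templates20.midpoint) @ templates20.direction
        assert proj > 0

    def test_expected_projection_increases_with_theta(self, templates20):
        projs = []
        for theta in (-1.0, -0.5, 0.0, 0.5, 1.0):
            pat = sample_station_pattern(
                AgentState(theta=theta), self.station, templates20, snr=1.5,
                rng=np.random.default_rng(0), noise_sd=0.0,
            )
            projs.append((pat - templates20.midpoint) @ templates20.direction)
        assert np.all(np.diff(projs) > 0)
        # slope per unit theta is snr * separation / 2
        assert projs[-1] - projs[-2] == pytest.approx(
            1.5 * templates20.separation / 2 * 0.5, abs=1e-10
        )

    def test_sample_mean_matches_expectation(self, templates20):
        """Monte-Carlo oracle: the empirical mean projection over many
        draws sits within 3 SE of the defined expectation."""
        station = StationSpec(station_index=2, start_tr=160, n_trs=6, bias=0.3)
        state = AgentState(theta=0.4)
        rng = np.random.default_rng(99)
        n = 10_000
        projs = np.empty(n)
        for i in range(n):
            pat = sample_station_pattern(state, station, templates20, snr=1.0, rng=rng)
            projs[i] = (pat - templates20.midpoint) @ templates20.direction
        expected = (station.bias + 1.0 * state.theta) * templates20.separation / 2
        se = 1.0 / np.sqrt(n)  # unit noise SD projects to unit SD on the axis
        assert abs(projs.mean() - expected) < 3 * se


class TestTrainingCohort:
    def test_pattern_count_is_participants_by_runs_by_stations(self, templates20):
        cfg = CohortConfig(n_participants=20, n_runs=1, n_features=20, seed=3)
        df = generate_training_cohort(cfg, templates20, default_stations())
        assert len(df) == 20 * 1 * 7
        assert df.groupby("station").size().eq(20).all()
        assert set(df["group"]) == {"cheating", "paranoid"}

    def test_seed_reproduces_cohort_exactly(self, templates20):
        cfg = CohortConfig(n_participants=6, n_runs=2, n_features=20, seed=8)
        a = generate_training_cohort(cfg, templates20, default_stations())
        b = generate_training_cohort(cfg, templates20, default_stations())
        assert a.to_csv(sep="\t") == b.to_csv(sep="\t")

    def test_high_separation_low_noise_is_linearly_separable(self):
        tp = make_templates(20, separation=4.0, seed=4)
        cfg = CohortConfig(n_participants=20, n_runs=2, n_features=20, seed=4)
        df = generate_training_cohort(cfg, tp, default_stations(), noise_sd=0.5)
        models = train_station_models(df)
        feat = [c for c in df.columns if c.startswith("f")]
        from storynf import predict_cheating_probability

        for m in models:
            block = df[df["station"] == m.station_index]
            preds = [
                predict_cheating_probability(m, row) > 0.5
                for row in block[feat].to_numpy()
            ]
            labels = (block["group"] == "cheating").to_numpy()
            assert np.array_equal(np.asarray(preds), labels)


class TestPilotCohort:
    def test_sample_counts_per_station(self, small_config, assets):
        stations, templates, _, models, pilot, _ = assets
        cfg = small_config.pilot_cohort()
        assert pilot.groupby("station").size().eq(cfg.n_participants * cfg.n_runs).all()

    def test_biased_station_shifts_pilot_mean(self):
        """A stimulus bias toward cheating raises that station's pilot
        mean p(c) above the pooled mean of unbiased stations."""
        biases = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.8)
        stations = default_stations(biases)
        tp = make_templates(10, separation=3.0, seed=21)
        train = generate_training_cohort(
            CohortConfig(n_participants=40, n_runs=1, n_features=10, seed=21), tp, stations
        )
        models = train_station_models(train)
        pilot = generate_pilot_cohort(
            CohortConfig(n_participants=500, n_runs=1, n_features=10, seed=22),
            tp, stations, models,
        )
        biased_mean = pilot.loc[pilot["station"] == 6, "p_c"].mean()
        unbiased_mean = pilot.loc[pilot["station"] != 6, "p_c"].mean()
        assert biased_mean > unbiased_mean


class TestQuestionnaireGeneration:
    def test_full_cheating_lean_answers_all_cheating(self):
        resp = generate_questionnaire(
            AgentState(theta=1.0), "cheating", np.random.default_rng(0)
        )
        assert all(a == 1 for a in resp.interpretation_answers)
        assert score_interpretation(resp) == 1.0

    def test_full_paranoid_lean_scores_minus_one(self):
        resp = generate_questionnaire(
            AgentState(theta=-1.0), "paranoid", np.random.default_rng(0)
        )
        assert score_interpretation(resp) == -1.0

    def test_item_rate_matches_binomial_oracle(self):
        """At theta = 0.5 each scored item is +1 w.p. 0.75, so the mean
        +-1 code over many draws is 0.5 within 3 binomial SEs."""
        rng = np.random.default_rng(123)
        state = AgentState(theta=0.5)
        codes = []
        for _ in range(3000):
            resp = generate_questionnaire(state, "cheating", rng)
            codes.extend(
                a for a, ex in zip(resp.interpretation_answers, resp.excluded) if not ex
            )
        codes = np.asarray(codes, float)
        p = 0.75
        se = 2 * np.sqrt(p * (1 - p) / codes.size)  # var of +-1 code = 4p(1-p)
        assert abs(codes.mean() - 0.5) < 3 * se

    def test_neutral_lean_is_symmetric(self):
        rng = np.random.default_rng(7)
        means = [
            score_interpretation(
                generate_questionnaire(AgentState(theta=0.0), "cheating", rng)
            )
            for _ in range(2000)
        ]
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(len(means)) + 0.02

    def test_structure_counts(self):
        resp = generate_questionnaire(
            AgentState(theta=0.2), "cheating", np.random.default_rng(5)
        )
        assert len(resp.comprehension_answers) == 27
        assert len(resp.interpretation_answers) == 12
        assert sum(resp.excluded) == 1
        assert set(resp.empathy) == {"arthur", "lee", "joanie", "the_girl"}
        assert all(1 <= v <= 5 for v in resp.empathy.values())


class TestDegenerateSafety:
    def test_zero_separation_cohort_generates_and_decodes_at_chance(self):
        tp = make_templates(10, separation=0.0, seed=2)
        stations = default_stations((0.0,) * 7)
        df = generate_training_cohort(
            CohortConfig(n_participants=30, n_runs=2, n_features=10, seed=2), tp, stations
        )
        models = train_station_models(df)
        test = generate_training_cohort(
            CohortConfig(n_participants=50, n_runs=2, n_features=10, seed=3), tp, stations
        )
        from storynf import predict_cheating_probability

        feat = [c for c in test.columns if c.startswith("f")]
        hits = [
            (predict_cheating_probability(models[int(r["station"])], r[feat].to_numpy(float)) > 0.5)
            == (r["group"] == "cheating")
            for _, r in test.iterrows()
        ]
        acc = np.mean(hits)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / len(hits))
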