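"""Synthetic experiment generator: design arithmetic, reproducibility,
distributional correctness, and derived per-participant measures."""

import numpy as np
import pytest

from sourcemem import (
    EXP1,
    EXP2,
    DesignConfig,
    JudgmentModel,
    ParameterVector,
    aggregate_frequencies,
    category_probabilities,
    corrected_item_recognition,
    default_config,
    default_theta,
    generate,
    generate_beliefs,
    generate_postdictions,
    judgment_cell_means,
    read_trials,
    simulate_frequency_tables,
    trials_to_frame,
    write_trials,
)

WITHOUT, WITH = "without_judgments", "with_judgments"


def small_config(experiment, seed=3, n=(3, 3), **kw):
    return default_config(experiment, seed=seed, n_per_group=n, **kw)


def uniform_theta(design, **kw):
    defaults = dict(D=0.6, d_A=0.4, d_B=0.4, b=0.3, g=0.5)
    defaults.update(kw)
    return {c: ParameterVector(**defaults) for c in design.conditions}


class TestGenerate:
    def test_same_seed_identical_different_seed_differs(self):
        t1 = trials_to_frame(generate(small_config("exp1", seed=9)))
        t2 = trials_to_frame(generate(small_config("exp1", seed=9)))
        t3 = trials_to_frame(generate(small_config("exp1", seed=10)))
        assert t1.equals(t2)
        assert not t1.equals(t3)

    def test_perfect_memory_gives_diagonal_tables(self):
        theta = {
            c: ParameterVector(1, 1, 1, 0.5, 0.5) for c in EXP1.conditions
        }
        trials = generate(small_config("exp1", theta_by_condition=theta))
        tables, _ = aggregate_frequencies(trials, EXP1)
        for table in tables:
            assert np.all(table.counts == np.diag(np.diag(table.counts)))

    def test_zero_noise_judgments_equal_grand_mean(self):
        jm = JudgmentModel(
            grand_mean=50, jol_expectancy_effect=0, jos_expectancy_effect=0,
            participant_sd=0, residual_sd=0,
        )
        trials = generate(small_config("exp1", judgment_model=jm))
        jols = [t.jol for t in trials if t.jol is not None]
        assert jols and all(j == 50 for j in jols)
        assert all(t.jol is None for t in trials if t.group == WITHOUT)

    def test_exp1_design_arithmetic_per_participant(self):
        trials = generate(small_config("exp1", n=(1, 1)))
        for group in (WITHOUT, WITH):
            sub = [t for t in trials if t.group == group]
            tables, n_total = aggregate_frequencies(sub, EXP1)
            assert n_total == 96
            for table in tables:
                assert table.row_totals.tolist() == [16, 16, 16]

    def test_exp2_design_arithmetic_per_participant(self):
        trials = generate(small_config("exp2", n=(1, 1)))
        sub = [t for t in trials if t.group == WITH]
        tables, n_total = aggregate_frequencies(sub, EXP2)
        assert n_total == 80
        for table in tables:
            assert table.row_totals.tolist() == [10, 10, 20]

    def test_exp1_counterbalancing_rotates_lists(self):
        trials = generate(small_config("exp1", n=(2, 2)))
        # across any 3 consecutive participants each list serves once as
        # Source-A source, once as Source-B source, once as distractor
        roles = {}
        for t in trials:
            if t.phase == "test" and not t.is_buffer:
                role = t.source if t.old else "new"
                roles.setdefault(t.participant_id, {}).setdefault(role, set()).add(t.list_id)
        for pid_base in (0,):
            for role in ("kitchen", "bathroom", "new"):
                served = [roles[pid_base + k][role] for k in range(3)]
                assert all(len(s) == 1 for s in served)
                assert set().union(*served) == {0, 1, 2}

    def test_exp2_study_schema_columns(self):
        trials = generate(small_config("exp2"))
        study = [t for t in trials if t.phase == "study" and not t.is_buffer]
        assert all(t.investment in (15, 30) for t in study)
        for t in study:
            expected_gain = 5 if t.investment == 15 else 10
            assert abs(t.payoff) == expected_gain
            assert (t.payoff > 0) == (t.source == "cooperation")
        test_rows = [t for t in trials if t.phase == "test"]
        assert all(1 <= t.likability <= 6 for t in test_rows)

    def test_buffers_flagged_and_excluded_from_aggregation(self):
        with_buf = generate(small_config("exp1", n=(1, 1)))
        no_buf = generate(small_config("exp1", n=(1, 1), include_buffers=False))
        assert sum(t.is_buffer for t in with_buf) == 4  # 2 per participant
        assert sum(t.is_buffer for t in no_buf) == 0
        t1, n1 = aggregate_frequencies(with_buf, EXP1)
        assert n1 == 192

    def test_cell_proportions_match_model_probabilities(self):
        # law of large numbers at 300 participants per group
        theta = uniform_theta(EXP2)
        trials = generate(
            DesignConfig("exp2", n_per_group=(300, 300), seed=0, theta_by_condition=theta)
        )
        tables, _ = aggregate_frequencies(trials, EXP2)
        probs = category_probabilities(theta[EXP2.conditions[0]]).to_numpy()
        for table in tables:
            observed = table.counts / table.row_totals[:, None]
            se = np.sqrt(probs * (1 - probs) / table.row_totals[:, None])
            assert np.all(np.abs(observed - probs) < 3.5 * np.maximum(se, 1e-3))

    def test_aggregate_matches_manual_tally(self):
        trials = generate(small_config("exp2", n=(2, 2)))
        tables, _ = aggregate_frequencies(trials, EXP2)
        by_label = {t.label: t for t in tables}
        tally = {}
        classes = {"sourceA_old": 0, "sourceB_old": 1, "new": 2}
        resps = {"respA": 0, "respB": 1, "respNew": 2}
        for t in trials:
            if t.phase != "test":
                continue
            key = f"{t.item_type}:{t.group}"
            tally.setdefault(key, np.zeros((3, 3), dtype=int))[
                classes[t.item_class], resps[t.test_response]
            ] += 1
        for label, counts in tally.items():
            assert np.array_equal(by_label[label].counts, counts)

    def test_empty_aggregation_rejected(self):
        with pytest.raises(ValueError):
            aggregate_frequencies([])


class TestSimulateFrequencyTables:
    def test_row_totals_follow_design(self):
        tables, n_total = simulate_frequency_tables(EXP2, default_theta(EXP2), rng=0)
        assert n_total == 185 * 80
        by_label = {t.label: t for t in tables}
        for itype in EXP2.item_types:
            assert by_label[f"{itype}:{WITHOUT}"].row_totals.tolist() == [930, 930, 1860]
            assert by_label[f"{itype}:{WITH}"].row_totals.tolist() == [920, 920, 1840]

    def test_reproducible_with_integer_seed(self):
        t1, _ = simulate_frequency_tables(EXP1, default_theta(EXP1), rng=5)
        t2, _ = simulate_frequency_tables(EXP1, default_theta(EXP1), rng=5)
        assert all(a == b for a, b in zip(t1, t2))


class TestCorrectedItemRecognition:
    def test_perfect_and_yes_sayer_responders(self):
        theta_perfect = {c: ParameterVector(1, 1, 1, 0.5, 0.5) for c in EXP1.conditions}
        trials = generate(small_config("exp1", n=(1, 1), theta_by_condition=theta_perfect))
        rates = corrected_item_recognition(trials)
        assert np.allclose(rates["corrected_hit_rate"], 1.0)

        theta_yes = {c: ParameterVector(0, 0.5, 0.5, 1, 0.5) for c in EXP1.conditions}
        trials = generate(small_config("exp1", n=(1, 1), theta_by_condition=theta_yes))
        rates = corrected_item_recognition(trials)
        assert np.allclose(rates["corrected_hit_rate"], 0.0)

    def test_estimates_item_detection_probability(self):
        # hit = D + (1-D)b, FA = (1-D)b, so the corrected rate estimates D
        theta = uniform_theta(EXP1, D=0.6, b=0.3)
        trials = generate(
            DesignConfig("exp1", n_per_group=(80, 80), seed=2, theta_by_condition=theta)
        )
        rates = corrected_item_recognition(trials)
        se = np.sqrt(0.5 * 0.5 / (32 * 160))
        assert abs(rates["corrected_hit_rate"].mean() - 0.6) < 4 * se


class TestJudgmentGenerators:
    def test_cell_means_shape_and_groups(self):
        trials = generate(small_config("exp1", n=(2, 2)))
        means = judgment_cell_means(trials, "jos")
        assert set(means["group"]) == {WITH}
        assert len(means) == 2 * 4  # 2 with-judgments participants x 4 cells

    def test_postdictions_complete_by_default(self):
        post = generate_postdictions(small_config("exp2", n=(4, 4)))
        assert len(post) == 8 * 4
        assert post["item_postdiction"].between(0, 100).all()
        assert set(post["group"]) == {WITHOUT, WITH}

    def test_beliefs_behavior_effect_direction(self):
        jm = JudgmentModel(behavior_main_effect=10, participant_sd=5, residual_sd=5)
        beliefs = generate_beliefs(n=200, judgment_model=jm, seed=1)
        by_source = beliefs.groupby("source")["source_belief"].mean()
        assert by_source["cheating"] > by_source["cooperation"] + 5


def test_trials_round_trip(tmp_path):
    trials = generate(small_config("exp2", n=(2, 2)))
    path1 = tmp_path / "trials.csv"
    path2 = tmp_path / "trials2.csv"
    write_trials(trials, path1)
    loaded = read_trials(path1)
    write_trials(loaded, path2)
    # serialization is stable and field values survive the round trip
    assert path1.read_bytes() == path2.read_bytes()
    assert len(loaded) == len(trials)
    assert [t.test_response for t in loaded] == [t.test_response for t in trials]
    assert [t.investment for t in loaded] == [t.investment for t in trials]
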