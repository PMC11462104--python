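"""Jump/generator estimation and descriptive transition statistics."""

import numpy as np
import pytest

import ctmcohort as cc
from ctmcohort.estimation import as_percent, round_half_up

# the published 10-state jump-probability table, percent, one decimal,
# absorbing row as 100% self-loop
EXPECTED_JUMP_PERCENT = {
    "MI": [0, 1.2, 51.2, 36, 0, 2.3, 8.1, 1.2, 0, 0],
    "Stroke": [7.6, 0, 56.5, 13.7, 1.5, 6.9, 2.3, 4.6, 5.3, 1.5],
    "Death": [0, 0, 100, 0, 0, 0, 0, 0, 0, 0],
    "CHF": [7.5, 13.4, 54, 0, 1.6, 0, 5.9, 7, 4.8, 5.9],
    "CHMI": [0, 5.6, 44.4, 33.3, 0, 0, 11.1, 0, 0, 5.6],
    "CHST": [7.1, 42.9, 21.4, 28.6, 0, 0, 0, 0, 0, 0],
    "Angina": [8.9, 10.9, 11.9, 38.6, 1, 1, 0, 6.9, 6.9, 13.9],
    "CHANMI": [11.3, 6.5, 16.1, 30.6, 1.6, 0, 21, 0, 6.5, 6.5],
    "ANMI": [5.9, 7.8, 7.8, 29.4, 0, 0, 31.4, 11.8, 0, 5.9],
    "CHAN": [2.3, 4.5, 13.6, 43.2, 4.5, 0, 18.2, 11.4, 2.3, 0],
}


def two_state_counts(n=31, r=16633.0):
    space = cc.StateSpace(states=("MI", "CHF"))
    return cc.TransitionCounts(
        state_space=space,
        N=np.array([[0, n], [0, 0]]),
        R=np.array([[0.0, r], [0.0, 0.0]]),
    )


class TestCountTransitions:
    def test_hand_counted_example(self):
        space = cc.StateSpace(states=("A", "B", "Death"), absorbing=frozenset({"Death"}))
        traj = [cc.PatientTrajectory("p1", [("A", 0), ("B", 10), ("Death", 30)])]
        counts = cc.count_transitions(traj, space)
        assert counts.N[0, 1] == 1 and counts.R[0, 1] == 10
        assert counts.N[1, 2] == 1 and counts.R[1, 2] == 20
        assert counts.N.sum() == 2

    def test_single_visit_contributes_nothing(self):
        space = cc.StateSpace(states=("A", "B"))
        counts = cc.count_transitions([cc.PatientTrajectory("p1", [("A", 3)])], space)
        assert counts.N.sum() == 0 and counts.R.sum() == 0

    def test_unknown_state_errors(self):
        space = cc.StateSpace(states=("A",))
        traj = [cc.PatientTrajectory("p1", [("A", 0), ("Z", 5)])]
        with pytest.raises(KeyError, match="unknown state"):
            cc.count_transitions(traj, space)

    def test_demo_fixture_five_transitions(self, demo_table):
        trajectories, space = cc.build_trajectories(demo_table)
        counts = cc.count_transitions(trajectories, space)
        assert counts.N.sum() == 5


class TestJumpProbabilityMatrix:
    def test_reproduces_published_table_every_cell(self, cvd_counts):
        percent = as_percent(cc.jump_probability_matrix(cvd_counts))
        for i, state in enumerate(cvd_counts.state_space.states):
            assert percent[i].tolist() == pytest.approx(EXPECTED_JUMP_PERCENT[state])

    def test_rows_sum_to_one(self, cvd_counts):
        P = cc.jump_probability_matrix(cvd_counts)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.min() >= 0 and P.max() <= 1

    def test_absorbing_row_conventions(self, cvd_counts):
        i = cvd_counts.state_space.index("Death")
        with_loop = cc.jump_probability_matrix(cvd_counts, absorbing_self_loop=True)
        assert with_loop[i, i] == 1.0
        without = cc.jump_probability_matrix(cvd_counts, absorbing_self_loop=False)
        assert without[i].sum() == 0.0

    def test_single_transition_row_is_unit_vector(self):
        counts = two_state_counts(n=1, r=4)
        P = cc.jump_probability_matrix(counts)
        assert P[0].tolist() == [0.0, 1.0]


class TestEstimateGenerator:
    def test_destination_specific_worked_value(self):
        g = cc.estimate_generator(two_state_counts(), mode="paper")
        assert round(g.Q[0, 1], 6) == 0.001864
        assert g.Q[0, 0] == -g.Q[0, 1]

    def test_single_pair_row(self):
        counts = two_state_counts(n=2, r=4)
        g = cc.estimate_generator(counts, mode="paper")
        assert g.Q[0].tolist() == [-0.5, 0.5]

    def test_three_state_toy_both_modes(self):
        space = cc.StateSpace(states=("A", "B", "C"))
        counts = cc.TransitionCounts(
            state_space=space,
            N=np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]]),
            R=np.array([[0, 2.0, 4.0], [0, 0, 0], [0, 0, 0]]),
        )
        mle = cc.estimate_generator(counts, mode="mle")
        np.testing.assert_allclose(mle.Q[0], [-1 / 3, 1 / 6, 1 / 6])
        paper = cc.estimate_generator(counts, mode="paper")
        np.testing.assert_allclose(paper.Q[0], [-0.75, 0.5, 0.25])

    def test_mle_embeds_the_jump_chain_exactly(self, four_state_generator):
        config = cc.SimulationConfig(
            Q_true=four_state_generator,
            initial_distribution=[1 / 3, 1 / 3, 1 / 3, 0],
            n_patients=300,
            seed=5,
        )
        trajectories, _ = cc.build_trajectories(
            cc.simulate_cohort(config),
            state_order=four_state_generator.state_space.states,
        )
        counts = cc.count_transitions(trajectories, four_state_generator.state_space)
        g = cc.estimate_generator(counts, mode="mle")
        P = cc.jump_probability_matrix(counts, absorbing_self_loop=False)
        for i in range(3):
            row = g.Q[i] / -g.Q[i, i]
            row[i] = 0.0
            np.testing.assert_allclose(row, P[i], atol=1e-12, err_msg=f"row {i}")

    def test_generator_invariants(self, cvd_counts, four_state_generator):
        # any valid generator: off-diagonals >= 0, zero row sums, absorbing zero
        for g in (four_state_generator,):
            g.check()
        with pytest.raises(ValueError, match="wait times"):
            cc.estimate_generator(cvd_counts)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            cc.estimate_generator(two_state_counts(), mode="bayes")


class TestTransitionTimeStats:
    def test_single_sample_sd_zero(self):
        space = cc.StateSpace(states=("MI", "Stroke"))
        traj = [cc.PatientTrajectory("p1", [("MI", 0), ("Stroke", 3)])]
        stats = cc.transition_time_stats(cc.count_transitions(traj, space))
        row = stats.iloc[0]
        assert (row.mean_days, row.sd_days, row.n) == (3.0, 0.0, 1)

    def test_population_sd(self):
        space = cc.StateSpace(states=("A", "B"))
        traj = [
            cc.PatientTrajectory("p1", [("A", 0), ("B", 10)]),
            cc.PatientTrajectory("p2", [("A", 0), ("B", 20)]),
        ]
        stats = cc.transition_time_stats(cc.count_transitions(traj, space))
        row = stats.iloc[0]
        assert (row.mean_days, row.sd_days, row.n) == (15.0, 5.0, 2)

    def test_absent_pairs_not_listed(self):
        space = cc.StateSpace(states=("A", "B"))
        traj = [cc.PatientTrajectory("p1", [("A", 0), ("B", 10)])]
        stats = cc.transition_time_stats(cc.count_transitions(traj, space))
        assert len(stats) == 1


def single_visit_cohort(spec):
    out = []
    k = 0
    for state, count in spec.items():
        for _ in range(count):
            out.append(cc.PatientTrajectory(f"p{k}", [(state, 0)]))
            k += 1
    return out


class TestFirstEpisodeDistribution:
    def test_published_counts_give_published_fractions(self):
        cohort = single_visit_cohort({"CHF": 371, "Stroke": 216, "Angina": 140, "MI": 113})
        dist = cc.first_episode_distribution(cohort)
        shares = dict(zip(dist.state, as_percent(dist.fraction)))
        assert shares == {"CHF": 44.2, "Stroke": 25.7, "Angina": 16.7, "MI": 13.5}
        assert dist.fraction.sum() == pytest.approx(1.0)

    def test_single_patient(self):
        dist = cc.first_episode_distribution(
            [cc.PatientTrajectory("p", [("MI", 5), ("Death", 9)])]
        )
        assert dist.iloc[0].state == "MI" and dist.iloc[0].fraction == 1.0

    def test_restrict_to_changes_denominator(self):
        cohort = single_visit_cohort({"A": 2, "B": 1})
        dist = cc.first_episode_distribution(cohort, restrict_to={"A"})
        assert dist.iloc[0]["count"] == 2 and dist.iloc[0].fraction == 1.0
        with pytest.raises(ValueError, match="restrict_to"):
            cc.first_episode_distribution(cohort, restrict_to={"Z"})


class TestDeathAttribution:
    def test_published_shares(self, cvd_counts):
        att = cc.death_attribution(
            cvd_counts, subset={"CHF", "Stroke", "MI", "Angina"}
        )
        assert att.total_deaths == 262
        shares = dict(zip(att.table.source_state, att.table.share))
        assert round_half_up(100 * shares["CHF"]) == 38.5  # 101/262 = 38.5496%
        assert round_half_up(100 * shares["Stroke"]) == 28.2
        assert round_half_up(100 * shares["MI"]) == 16.8
        assert round_half_up(100 * shares["Angina"]) == 4.6
        assert round_half_up(100 * att.subset_share) == 88.2

    def test_single_death_source(self):
        space = cc.StateSpace(states=("A", "Death"), absorbing=frozenset({"Death"}))
        counts = cc.TransitionCounts(
            state_space=space, N=np.array([[0, 1], [0, 0]])
        )
        att = cc.death_attribution(counts)
        assert att.table.iloc[0].share == 1.0

    def test_empty_subset_and_zero_deaths(self, cvd_counts):
        att = cc.death_attribution(cvd_counts, subset=set())
        assert att.subset_share == 0.0
        space = cc.StateSpace(states=("A", "Death"), absorbing=frozenset({"Death"}))
        empty = cc.TransitionCounts(state_space=space, N=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="no transitions"):
            cc.death_attribution(empty)


class TestFormatting:
    @pytest.mark.parametrize(
        "value,expected", [(51.16279, 51.2), (36.046, 36.0), (0.05, 0.1), (4.545, 4.5)]
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected
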