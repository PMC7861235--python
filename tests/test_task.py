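"""Closed-form decision variables of the card task."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardglm import (
    Deck,
    LearningState,
    TaskDataError,
    Trial,
    accuracy_bits,
    compute_decision_variables,
    confidence,
    dirichlet_update,
    entropy_bits,
    inverse_variance,
    reward_prediction,
    reward_prediction_error,
    surprise_bits,
    win_probability,
)
from cardglm.task import HIGHER, LOWER, true_outcome


def make_trial(card1, card2, bet):
    return Trial(
        session=0,
        index=0,
        card1=card1,
        card2=card2,
        bet=bet,
        outcome=true_outcome(card1, card2, bet),
    )


class TestWinProbability:
    @pytest.mark.parametrize(
        "card1, bet, expected",
        [
            (5, LOWER, 4 / 9),
            (1, HIGHER, 1.0),
            (2, LOWER, 1 / 9),
            (10, HIGHER, 0.0),
            (6, HIGHER, 4 / 9),
        ],
    )
    def test_counts_remaining_favorable_cards(self, card1, bet, expected):
        assert win_probability(card1, bet) == pytest.approx(expected, abs=1e-15)

    def test_higher_and_lower_are_complementary(self, deck):
        # no ties are possible with distinct card values
        for c in deck.values:
            assert win_probability(c, HIGHER, deck) + win_probability(
                c, LOWER, deck
            ) == pytest.approx(1.0, abs=1e-15)

    def test_card_outside_deck_rejected(self):
        with pytest.raises(ValueError, match="not in deck"):
            win_probability(11, HIGHER)

    def test_works_on_nonstandard_deck(self):
        deck = Deck(values=(2, 3, 5, 7))
        assert win_probability(3, HIGHER, deck) == pytest.approx(2 / 3)


class TestInformationQuantities:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.5, 1.0),
            (1.0, 0.0),
            (0.0, 0.0),
            (4 / 9, 0.9910760598382222),  # frozen from an arbitrary-precision oracle
        ],
    )
    def test_entropy_values(self, p, expected):
        assert entropy_bits(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p, expected",
        [(1.0, 0.0), (0.5, -1.0), (8 / 9, -0.5032583347756457)],
    )
    def test_confidence_is_negative_entropy(self, p, expected):
        assert confidence(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p, expected", [(1.0, 0.0), (0.5, 1.0), (4 / 9, 0.9910760598382222)])
    def test_accuracy_is_zero_minus_confidence(self, p, expected):
        assert accuracy_bits(p) == pytest.approx(expected, abs=1e-12)

    def test_accuracy_sign_option(self):
        assert accuracy_bits(0.5, sign=-1.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("p", [-0.1, 1.1, 2.0])
    def test_out_of_range_probability_rejected(self, p):
        with pytest.raises(ValueError):
            entropy_bits(p)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_entropy_symmetric_and_bounded(self, p):
        h = entropy_bits(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(entropy_bits(1.0 - p), abs=1e-12)
        assert accuracy_bits(p) + confidence(p) == pytest.approx(0.0, abs=1e-15)

    def test_entropy_maximized_uniquely_at_half(self):
        grid = np.linspace(0.0, 1.0, 201)
        h = np.array([entropy_bits(p) for p in grid])
        assert np.argmax(h) == 100 and h[100] == pytest.approx(1.0)
        assert np.all(h[np.abs(grid - 0.5) > 1e-9] < 1.0)


class TestSurprise:
    @pytest.mark.parametrize(
        "card1, card2, bet, expected",
        [
            (2, 1, LOWER, math.log2(9)),       # improbable win: 1/9
            (1, 2, HIGHER, 0.0),               # certain win carries no surprise
            (5, 7, LOWER, -math.log2(5 / 9)),  # loss with complement probability
        ],
    )
    def test_observed_outcome_information(self, card1, card2, bet, expected):
        assert surprise_bits(make_trial(card1, card2, bet)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_impossible_outcome_is_inconsistent_data(self):
        # a recorded loss on a certain-win trial cannot occur in the task
        trial = make_trial(1, 2, HIGHER)
        trial.outcome = "loss"
        with pytest.raises(TaskDataError):
            surprise_bits(trial)

    def test_expected_surprise_equals_entropy_for_all_cells(self, deck):
        # links the surprise and entropy definitions over the full deck
        for card1 in deck.values:
            for bet in (HIGHER, LOWER):
                p = win_probability(card1, bet, deck)
                expected_surprise = 0.0
                for card2 in deck.values:
                    if card2 == card1:
                        continue
                    t = make_trial(card1, card2, bet)
                    p_obs = p if t.outcome == "win" else 1 - p
                    if p_obs > 0:
                        expected_surprise += (1 / 9) * surprise_bits(t)
                assert abs(expected_surprise - entropy_bits(p)) < 1e-12


class TestRewardPrediction:
    @pytest.mark.parametrize(
        "card1, bet, expected",
        [(5, LOWER, -1 / 9), (1, HIGHER, 1.0), (10, HIGHER, -1.0)],
    )
    def test_symmetric_payoff_expectation(self, card1, bet, expected):
        assert reward_prediction(card1, bet) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "card1, card2, bet, expected",
        [
            (1, 2, HIGHER, 0.0),         # fully predicted win
            (5, 3, LOWER, 10 / 9),       # 1 − (−1/9)
            (5, 7, LOWER, -8 / 9),       # −1 − (−1/9)
        ],
    )
    def test_rpe_is_outcome_minus_prediction(self, card1, card2, bet, expected):
        trial = make_trial(card1, card2, bet)
        assert reward_prediction_error(trial) == pytest.approx(expected, abs=1e-12)

    def test_rpe_unbiased_over_outcome_distribution(self, deck):
        for card1 in deck.values:
            for bet in (HIGHER, LOWER):
                mean_rpe = np.mean(
                    [
                        reward_prediction_error(make_trial(card1, c2, bet))
                        for c2 in deck.values
                        if c2 != card1
                    ]
                )
                assert abs(mean_rpe) < 1e-12

    def test_nonpositive_stake_rejected(self):
        with pytest.raises(ValueError):
            reward_prediction(5, HIGHER, stake=0.0)


class TestInverseVariance:
    def test_maximal_uncertainty_gives_four(self):
        assert inverse_variance(0.5) == pytest.approx(4.0)

    def test_certitude_explodes_under_epsilon_clipping(self):
        expected = 1.0 / (0.001 * 0.999)
        assert inverse_variance(1.0) == pytest.approx(expected)
        assert inverse_variance(0.0) == pytest.approx(expected)

    def test_not_ordinal_with_negative_entropy_at_certitude(self):
        # the regularized precision at certitude does not scale with the
        # next-highest confidence level, unlike negative entropy
        near = inverse_variance(8 / 9)
        certain = inverse_variance(1.0)
        assert certain / near > 50
        assert confidence(1.0) - confidence(8 / 9) < 1.0

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValueError):
            inverse_variance(0.5, epsilon=0.0)


class TestDirichletCounting:
    @pytest.mark.parametrize(
        "wins, outcomes, expected",
        [(0, 0, 1.0), (3, 10, 4 / 11), (50, 100, 51 / 101)],
    )
    def test_pseudocount_estimate(self, wins, outcomes, expected):
        state = LearningState(wins_so_far=wins, outcomes_so_far=outcomes)
        assert state.p_win_learned == pytest.approx(expected, abs=1e-15)

    def test_update_increments_counts(self):
        state = dirichlet_update(LearningState(), "win")
        assert (state.wins_so_far, state.outcomes_so_far) == (1, 1)
        state = dirichlet_update(state, "loss")
        assert (state.wins_so_far, state.outcomes_so_far) == (1, 2)
        assert state.p_win_learned == pytest.approx(2 / 3)

    def test_converges_to_bernoulli_rate(self):
        theta = 0.35
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            state = LearningState()
            for _ in range(10_000):
                state = dirichlet_update(
                    state, "win" if rng.random() < theta else "loss"
                )
            failures += abs(state.p_win_learned - theta) >= 0.05
        assert failures == 0

    def test_wins_cannot_exceed_outcomes(self):
        with pytest.raises(ValueError):
            LearningState(wins_so_far=2, outcomes_so_far=1)


class TestTrialAndTable:
    def test_identical_cards_rejected(self):
        with pytest.raises(TaskDataError):
            Trial(session=0, index=0, card1=5, card2=5, bet=HIGHER, outcome="win")

    def test_contradictory_outcome_rejected(self):
        with pytest.raises(TaskDataError):
            Trial(session=0, index=0, card1=2, card2=9, bet=HIGHER, outcome="loss")

    def test_variables_table_round_trip(self, small_cohort_trials, tmp_path):
        from cardglm import write_variables_tsv
        import pandas as pd

        table = compute_decision_variables(small_cohort_trials)
        assert len(table) == len(small_cohort_trials)
        resolved = table.dropna(subset=["p_win"])
        assert ((resolved.confidence <= 0) & (resolved.surprise >= -1e-12)).all()
        assert np.allclose(resolved.accuracy, -resolved.confidence)
        path = tmp_path / "variables.tsv"
        write_variables_tsv(table, path)
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(
            back.dropna(subset=["p_win"]).surprise, resolved.surprise, atol=1e-12
        )

    def test_learning_column_tracks_session_outcomes(self):
        trials = [
            make_trial(2, 1, LOWER),   # win
            make_trial(5, 7, LOWER),   # loss
            make_trial(3, 9, HIGHER),  # win
        ]
        for i, t in enumerate(trials):
            t.index = i
        table = compute_decision_variables(trials)
        # prediction *held at* each trial: (wins+1)/(outcomes+1) over earlier trials
        assert list(table.p_win_learned) == pytest.approx([1.0, 2 / 2, 2 / 3])
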