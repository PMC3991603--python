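"""The reinforcement learner: delta rule, reward sets, soft-max/greedy choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpslearn.core import (
    RPS_ALPHABET,
    ContextPattern,
    HypothesisRecord,
    HypothesisSpace,
    STMBuffer,
)
from rpslearn.environment import stationary_bias_schedule
from rpslearn.experiment import run_game
from rpslearn.relph import (
    RELPHAgent,
    RelphParams,
    delta_update,
    greedy_weights,
    init_value,
    outcome_entropy,
    relph_choice_distribution,
    relph_prune,
    relph_update,
    softmax_weights,
)

FULL = ContextPattern.from_mapping({2: "paper", 1: "rock"})


class TestDeltaRule:
    def test_reference_values(self):
        assert delta_update(0.0, 1.0, 0.5) == pytest.approx(0.5)
        assert delta_update(0.7, -1.0, 1.0) == pytest.approx(-1.0)  # pure recency
        assert delta_update(0.7, -1.0, 0.0) == pytest.approx(0.7)  # pure history

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(-1, 1, allow_nan=False),
        st.sampled_from([-1.0, 0.0, 1.0]),
        st.floats(0, 1, allow_nan=False),
    )
    def test_contraction_toward_reward(self, v, r, alpha):
        assert abs(delta_update(v, r, alpha) - r) == pytest.approx(
            (1 - alpha) * abs(v - r), abs=1e-12
        )

    def test_tracks_mean_of_iid_rewards(self, rng):
        """Exponential smoothing settles near the reward mean."""
        mu, alpha = 0.4, 0.1
        v = 0.0
        for r in rng.choice([1.0, 0.0, -1.0], p=[0.6, 0.2, 0.2], size=2000):
            v = delta_update(v, float(r), alpha)
        # stationary sd of the EWMA ~ sd(r) * sqrt(alpha / (2 - alpha))
        assert abs(v - mu) < 3 * 0.8 * np.sqrt(alpha / (2 - alpha))


class TestValueInit:
    def test_range_and_determinism(self):
        vals = [init_value(FULL, s) for s in range(50)]
        assert all(abs(v) <= 0.01 for v in vals)
        assert init_value(FULL, 7) == init_value(FULL, 7)
        assert len(set(vals)) > 40  # seed actually matters

    def test_independent_of_insertion_order(self):
        a = ContextPattern.from_mapping({1: "rock"})
        b = ContextPattern.from_mapping({2: "rock"})
        assert init_value(a, 3) != init_value(b, 3)


class TestUpdate:
    def test_loss_then_win_accumulates_signed_rewards(self):
        """Scissors loses in (paper, rock); paper later wins: paper ends ahead."""
        hs = HypothesisSpace()
        stm = STMBuffer(2, ["paper", "rock"])
        relph_update(hs, stm, "scissors", -1.0, alpha=0.3)
        assert len(hs) == 3
        assert all(r.pset == {"scissors": -1.0} for r in hs.records())
        relph_update(hs, stm, "paper", +1.0, alpha=0.3)
        assert all(r.pset == {"scissors": -1.0, "paper": 1.0} for r in hs.records())
        assert all(max(r.pset, key=r.pset.get) == "paper" for r in hs.records())

    def test_repeated_wins_sum_linearly(self):
        hs = HypothesisSpace()
        stm = STMBuffer(1, ["rock"])
        for _ in range(5):
            relph_update(hs, stm, "paper", +1.0, alpha=0.5)
        (rec,) = hs.records()
        assert rec.pset == {"paper": 5.0}
        assert rec.outcome_counts == {"win": 5}

    def test_value_follows_delta_rule(self):
        hs = HypothesisSpace()
        stm = STMBuffer(1, ["rock"])
        relph_update(hs, stm, "paper", +1.0, alpha=0.5, init_value_fn=lambda p: 0.0)
        (rec,) = hs.records()
        assert rec.value == pytest.approx(0.5)
        relph_update(hs, stm, "paper", -1.0, alpha=0.5)
        assert rec.value == pytest.approx(-0.25)


class TestOutcomeEntropy:
    def test_reference_value(self):
        rec = HypothesisRecord(FULL, outcome_counts={"win": 10})
        assert outcome_entropy(rec) == pytest.approx(0.4395, abs=1e-4)

    def test_inconsistent_outcomes_score_higher(self):
        pure = HypothesisRecord(FULL, outcome_counts={"win": 10})
        mixed = HypothesisRecord(FULL, outcome_counts={"win": 5, "loss": 5})
        assert outcome_entropy(mixed) > outcome_entropy(pure)

    def test_zero_threshold_empties_space(self):
        hs = HypothesisSpace()
        stm = STMBuffer(2, ["paper", "rock"])
        relph_update(hs, stm, "paper", 1.0, alpha=0.3)
        assert relph_prune(hs, 0.0) == 3 and len(hs) == 0


class TestChoice:
    def test_greedy_picks_most_rewarding(self):
        hs = HypothesisSpace()
        rec = hs.lookup_or_insert(FULL)
        rec.pset.update({"scissors": -1.0, "paper": 1.0})  # rock implicitly 0
        stm = STMBuffer(2, ["paper", "rock"])
        dist = relph_choice_distribution(hs, stm, RelphParams(greedy=True))
        assert dist[RPS_ALPHABET.index("paper")] == pytest.approx(1.0)

    def test_softmax_closed_form_and_symmetry(self):
        hs = HypothesisSpace()
        rec = hs.lookup_or_insert(FULL)
        rec.pset.update({"rock": 1.0, "paper": 0.0, "scissors": -1.0})
        stm = STMBuffer(2, ["paper", "rock"])
        dist = relph_choice_distribution(hs, stm, RelphParams(tau=1.0))
        e = np.exp(1)
        z = e + 1 + 1 / e
        assert dist == pytest.approx([e / z, 1 / z, 1 / (e * z)], abs=1e-9)
        # equal totals collapse to uniform
        rec.pset.update({"rock": 2.0, "paper": 2.0, "scissors": 2.0})
        assert relph_choice_distribution(hs, stm, RelphParams(tau=1.0)) == pytest.approx(
            [1 / 3] * 3
        )

    def test_uniform_fallback_without_hypotheses(self):
        dist = relph_choice_distribution(
            HypothesisSpace(), STMBuffer(2, ["rock"]), RelphParams()
        )
        assert np.allclose(dist, 1 / 3)

    def test_small_temperature_recovers_argmax(self, rng):
        tau = 1e-4
        for _ in range(200):
            x = rng.normal(size=3)
            w = softmax_weights(x, tau)
            top, second = np.sort(x)[-1:-3:-1]
            if top - second > 100 * tau:
                assert w == pytest.approx(greedy_weights(x), abs=1e-8)
            else:  # near-tie: the limit is ill-conditioned, argmax still leads
                assert np.argmax(w) == np.argmax(x)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6))
    def test_softmax_is_a_distribution(self, xs):
        w = softmax_weights(np.array(xs), 0.7)
        assert w.sum() == pytest.approx(1.0) and (w >= 0).all()

    def test_choice_depends_only_on_rewards_not_opponent_tallies(self):
        """Outcome tallies (opponent-derived) never enter the choice rule."""
        stm = STMBuffer(2, ["paper", "rock"])
        dists = []
        for oc in ({"win": 3, "loss": 1}, {"tie": 4}):
            hs = HypothesisSpace()
            rec = hs.lookup_or_insert(FULL)
            rec.pset.update({"paper": 2.0, "rock": -1.0})
            rec.value = 0.4
            rec.outcome_counts.update(oc)
            dists.append(relph_choice_distribution(hs, stm, RelphParams(tau=1.0)))
        assert np.allclose(dists[0], dists[1])


class TestAgentBehaviour:
    def test_greedy_converges_to_scissors_against_paper_bias(self):
        """A greedy maximizer locks onto the best reply to an 80% paper bias."""
        sched = stationary_bias_schedule(length=200)
        params = RelphParams(n=2, h_thr=2.28, alpha=0.27, greedy=True)
        hits = 0
        for s in range(20):
            log = run_game("relph-greedy", params, schedule=sched, seed=s)
            hits += (log.iloc[150:]["player_choice"] == "scissors").mean() >= 0.8
        assert hits > 10

    def test_no_edge_against_uniform_opponent(self):
        from rpslearn.environment import OpponentSchedule, PhaseSpec

        sched = OpponentSchedule(
            phases=(PhaseSpec.from_mapping(3000, dict.fromkeys(RPS_ALPHABET, 1 / 3)),)
        )
        log = run_game("relph", RelphParams(), schedule=sched, seed=2)
        assert abs((log["outcome"] == "win").mean() - 1 / 3) <= 0.03

    def test_identical_seed_replays_identical_log(self):
        a = run_game("relph", RelphParams(), seed=11)
        b = run_game("relph", RelphParams(), seed=11)
        assert a.equals(b)
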