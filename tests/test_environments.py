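import json

import numpy as np
import pytest

from dualsys.bayes_core import BetaDist
from dualsys.environments import (
    DEFAULT_PLAYROOM_START,
    Environment,
    GoalSpec,
    PlayroomState,
    make_feeder,
    make_playroom,
    min_steps_to_goal,
    obs_states_for_devaluation,
    observe,
    spec_from_dict,
    spec_to_dict,
    terminal_states_matching,
)

MUSIC_DARK = GoalSpec(music=True, light=False)


def transition_rows_sum_to_one(spec):
    rows = spec.P[~spec.terminal]
    np.testing.assert_allclose(rows.sum(axis=-1), 1.0)


class TestFeeder:
    @pytest.mark.parametrize("variant", ["simple", "moderate"])
    def test_rows_sum_to_one(self, variant):
        transition_rows_sum_to_one(make_feeder(variant))

    def test_press_then_entry_is_rewarded(self):
        spec = make_feeder("simple")
        env = Environment(spec)
        rng = np.random.default_rng(0)
        env.reset(rng)
        env.step(spec.action_index("press"), rng)
        _, _, r, terminal, _ = env.step(spec.action_index("entry"), rng)
        assert terminal and r == 1.0

    def test_entry_first_restarts_unrewarded(self):
        spec = make_feeder("simple")
        env = Environment(spec)
        rng = np.random.default_rng(0)
        env.reset(rng)
        s2, _, r, terminal, _ = env.step(spec.action_index("entry"), rng)
        assert terminal and r == 0.0
        assert spec.state_labels[s2] == "T0"

    def test_chain_route_equivalent_reward(self):
        spec = make_feeder("moderate")
        env = Environment(spec)
        rng = np.random.default_rng(0)
        env.reset(rng)
        env.step(spec.action_index("chain"), rng)
        s2, _, r, terminal, _ = env.step(spec.action_index("entry"), rng)
        assert terminal and r == 1.0
        assert spec.state_labels[s2] == "T+'"  # distinct from the press terminal

    @pytest.mark.parametrize("variant", ["simple", "moderate"])
    def test_episodes_end_within_two_decisions(self, variant):
        spec = make_feeder(variant)
        rng = np.random.default_rng(7)
        env = Environment(spec)
        for _ in range(50):
            env.reset(rng)
            done = False
            steps = 0
            while not done:
                _, _, _, terminal, trunc = env.step(int(rng.integers(spec.n_actions)), rng)
                done = terminal or trunc
                steps += 1
            assert steps <= 2

    def test_observation_is_identity(self):
        spec = make_feeder("simple")
        assert [observe(spec, s) for s in range(spec.n_states)] == list(range(spec.n_states))


class TestPlayroom:
    def test_rows_sum_to_one(self):
        transition_rows_sum_to_one(make_playroom(goal=MUSIC_DARK))

    def test_64_states(self):
        spec = make_playroom()
        assert spec.n_states == 64

    def find(self, spec, hand, eye, light, music):
        return spec.state_labels.index(PlayroomState(hand, eye, bool(light), bool(music)))

    def step_from(self, spec, state, action):
        env = Environment(spec)
        rng = np.random.default_rng(0)
        env.reset(rng)
        env.true_state = state
        env.obs = observe(spec, state)
        return env.step(spec.action_index(action), rng)

    def test_switch_toggles_light(self):
        spec = make_playroom()
        s = self.find(spec, "switch", "switch", 0, 0)
        s2, *_ = self.step_from(spec, s, "use")
        assert spec.state_labels[s2].light is True

    def test_monkey_is_neutral(self):
        spec = make_playroom()
        s = self.find(spec, "monkey", "monkey", 1, 1)
        s2, *_ = self.step_from(spec, s, "use")
        assert s2 == s

    def test_use_requires_hand_and_eye_colocated(self):
        spec = make_playroom()
        s = self.find(spec, "blue_box", "switch", 1, 0)
        s2, *_ = self.step_from(spec, s, "use")
        assert spec.state_labels[s2].music is False

    def test_blue_starts_red_stops_music(self):
        spec = make_playroom()
        s = self.find(spec, "blue_box", "blue_box", 1, 0)
        s2, *_ = self.step_from(spec, s, "use")
        assert spec.state_labels[s2].music is True
        s = self.find(spec, "red_box", "red_box", 1, 1)
        s2, *_ = self.step_from(spec, s, "use")
        assert spec.state_labels[s2].music is False

    def test_eye_to_random_uniform_over_objects(self):
        spec = make_playroom()
        s = self.find(spec, "monkey", "monkey", 1, 0)
        row = spec.P[s, spec.action_index("eye_to_random")]
        assert np.count_nonzero(row) == 4
        np.testing.assert_allclose(row[row > 0], 0.25)

    def test_action_rewards(self):
        spec = make_playroom()
        assert spec.action_rewards[spec.action_index("null")] == pytest.approx(0.005)
        for a in ("use", "eye_to_random", "hand_to_eye"):
            assert spec.action_rewards[spec.action_index(a)] == pytest.approx(-0.02)


class TestObservation:
    def test_lit_observation_injective(self):
        spec = make_playroom()
        lit = [i for i, s in enumerate(spec.state_labels) if s.light]
        obs = [observe(spec, i) for i in lit]
        assert len(set(obs)) == len(lit)

    def test_dark_boxes_indistinguishable(self):
        spec = make_playroom()
        a = spec.state_labels.index(PlayroomState("blue_box", "monkey", False, False))
        b = spec.state_labels.index(PlayroomState("red_box", "monkey", False, False))
        assert observe(spec, a) == observe(spec, b)

    def test_dark_switch_unmerged(self):
        spec = make_playroom()
        a = spec.state_labels.index(PlayroomState("switch", "monkey", False, False))
        b = spec.state_labels.index(PlayroomState("monkey", "monkey", False, False))
        assert observe(spec, a) != observe(spec, b)

    def test_merged_states_share_available_actions(self):
        # all Playroom states offer the same action set; the merge is well formed
        spec = make_playroom(goal=MUSIC_DARK)
        for o in range(spec.n_obs):
            pre = np.flatnonzero(spec.obs_of_state == o)
            terms = {bool(spec.terminal[i]) for i in pre}
            if len(terms) == 2:
                # mixed observed states must be flagged rewarding, not terminal
                assert spec.obs_rewarding[o] and not spec.obs_terminal[o]


class TestGoalReachability:
    def test_proximal_reachable_in_three(self):
        spec = make_playroom(goal=MUSIC_DARK)
        boxes = {"blue_box", "red_box"}
        proximal = terminal_states_matching(
            spec, lambda s: s.hand in boxes and s.eye in boxes
        )
        assert min_steps_to_goal(spec, proximal) == 3

    def test_distal_requires_nine(self):
        spec = make_playroom(goal=MUSIC_DARK)
        distal = terminal_states_matching(
            spec, lambda s: s.hand == "switch" and s.eye == "switch"
        )
        assert min_steps_to_goal(spec, distal) == 9


class TestDevaluationHelpers:
    def test_obs_states_require_full_preimage(self):
        spec = make_playroom(goal=MUSIC_DARK)
        switch_route = terminal_states_matching(
            spec, lambda s: s.hand == "switch" and s.eye == "switch"
        )
        non_switch = terminal_states_matching(
            spec, lambda s: not (s.hand == "switch" and s.eye == "switch")
        )
        obs_non_switch = obs_states_for_devaluation(spec, non_switch)
        obs_switch = obs_states_for_devaluation(spec, switch_route)
        assert set(obs_non_switch).isdisjoint(obs_switch)
        # together they cover every goal-image observed state
        assert set(obs_non_switch) | set(obs_switch) == set(
            np.flatnonzero(spec.obs_rewarding)
        )

    def test_env_devalue_changes_payout(self):
        spec = make_feeder("simple")
        env = Environment(spec)
        rng = np.random.default_rng(3)
        env.devalue([spec.state_index("T+")], BetaDist(1, 15))
        env.reset(rng)
        env.step(spec.action_index("press"), rng)
        _, _, r, terminal, _ = env.step(spec.action_index("entry"), rng)
        assert terminal and 0.0 <= r < 1.0

    def test_devalue_non_terminal_rejected(self):
        spec = make_feeder("simple")
        env = Environment(spec)
        with pytest.raises(KeyError):
            env.devalue([spec.state_index("S0")], BetaDist(1, 15))


class TestGoalSpec:
    def test_requires_some_constraint(self):
        with pytest.raises(ValueError):
            GoalSpec()

    def test_invalid_object_set(self):
        with pytest.raises(ValueError):
            GoalSpec(music=True, eye={"teapot"})

    def test_matching(self):
        g = GoalSpec(music=True, light=False, eye={"blue_box"})
        assert g.matches(PlayroomState("monkey", "blue_box", False, True))
        assert not g.matches(PlayroomState("monkey", "red_box", False, True))


def test_spec_serialization_round_trip(tmp_path):
    spec = make_feeder("moderate")
    spec.terminal_reward[spec.state_index("T+")] = BetaDist(1, 15)
    d = json.loads(json.dumps(spec_to_dict(spec)))
    back = spec_from_dict(d)
    np.testing.assert_allclose(back.P, spec.P)
    assert back.actions == spec.actions
    r = back.terminal_reward[spec.state_index("T+")]
    assert isinstance(r, BetaDist) and (r.alpha, r.beta) == (1, 15)


def test_playroom_default_start_dark_and_quiet():
    s = DEFAULT_PLAYROOM_START
    assert not s.light and not s.music
    assert s.hand == s.eye == "monkey"
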