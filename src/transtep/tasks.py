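"""Generative environments for the three experimental paradigms.

Three tasks are modeled:

* a one-step revaluation task: forced-choice learning of action->state
  frequencies (no rewards), followed by a no-feedback test phase asking which
  action most often produced each state;
* the two-step task: probabilistic first-stage transitions (common 0.7 /
  rare 0.3) to one of two second-stage states, each offering two actions with
  slowly drifting reward probabilities;
* a multi-goal pursuit task: two actions, each with independent drifting
  probabilities of reaching a "reward" state and a "punishment" state, with a
  per-trial instructed goal (seek reward or avoid punishment).

Environments mutate in place and are returned from step functions for
convenience.  All randomness flows through an explicit ``numpy.random
.Generator``.  Two-step and multi-goal environments hold ``n_agents``
independent copies of the schedule so that whole cohorts can be stepped in
parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OneStepRevalSchedule",
    "TwoStepEnv",
    "MultiGoalEnv",
    "simulate_one_step_block",
    "step_two_step",
    "step_multigoal",
    "make_goal_sequence",
]

# condition labels for the five one-step blocks (distractor-image pairings;
# image content itself is not modeled)
ONE_STEP_CONDITIONS = (
    "neutral",
    "negative-common",
    "negative-rare",
    "positive-common",
    "positive-rare",
)


@dataclass(frozen=True)
class OneStepRevalSchedule:
    """Outcome-count schedule for one learning block of the revaluation task.

    Two actions (0 and 1) each lead to one of three states.  Outcome counts
    are exact frequencies out of ``n_per_action`` forced choices, not i.i.d.
    draws.  State layout: state 0 is action 1's common state, state 1 is
    action 0's common state, and state 2 is the rare state shared by both
    actions.  The test phase queries each state once; the rare-state query is
    unscored because neither action is optimal for it.
    """

    counts: tuple[tuple[int, int, int], tuple[int, int, int]] = ((3, 5, 2), (5, 3, 2))
    condition: str = "neutral"

    @property
    def n_per_action(self) -> int:
        return sum(self.counts[0])

    def validate(self) -> None:
        c0, c1 = np.asarray(self.counts[0]), np.asarray(self.counts[1])
        if c0.shape != (3,) or c1.shape != (3,):
            raise ValueError("schedule needs 3 outcome counts per action")
        if np.any(c0 < 0) or np.any(c1 < 0):
            raise ValueError("negative outcome counts")
        if c0.sum() != c1.sum():
            raise ValueError("actions must have equal numbers of forced choices")
        if c0[2] != c1[2]:
            raise ValueError("rare state count must be shared by both actions")

    def optimal_action(self, state: int) -> int | None:
        """Action with the highest probability of producing ``state``.

        Returns None for an unscored query (no unique optimum).
        """
        c = (self.counts[0][state], self.counts[1][state])
        if c[0] == c[1]:
            return None
        return int(np.argmax(c))

    @property
    def queries(self) -> list[dict]:
        out = []
        for s in range(3):
            opt = self.optimal_action(s)
            out.append({"query_state": s, "optimal_action": opt, "scored": opt is not None})
        return out


#: the easy practice round: each action's common state 16/20, others 2 each
PRACTICE_SCHEDULE = OneStepRevalSchedule(counts=((2, 16, 2), (16, 2, 2)), condition="practice")


def default_one_step_blocks() -> list[OneStepRevalSchedule]:
    """The five experimental blocks (standard counts, distinct condition labels)."""
    return [OneStepRevalSchedule(condition=c) for c in ONE_STEP_CONDITIONS]


def simulate_one_step_block(
    schedule: OneStepRevalSchedule, rng_seed: int | np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """Generate one block of forced-choice learning trials plus its test queries.

    Outcomes are an exact permutation of the scheduled counts per action (the
    task presents frequencies, not Bernoulli draws); the two actions'
    forced-choice trials are randomly interleaved.

    Returns (trials, queries): ``trials`` has columns trial/action/state,
    ``queries`` is the schedule's query list.
    """
    schedule.validate()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = schedule.n_per_action
    outcome_lists = []
    for a in (0, 1):
        outs = np.repeat([0, 1, 2], schedule.counts[a])
        rng.shuffle(outs)
        outcome_lists.append(outs)
    order = np.repeat([0, 1], n)
    rng.shuffle(order)
    states = np.empty(2 * n, dtype=int)
    for a in (0, 1):
        states[order == a] = outcome_lists[a]
    trials = pd.DataFrame(
        {
            "trial": np.arange(2 * n),
            "action": order,
            "state": states,
            "condition": schedule.condition,
        }
    )
    return trials, schedule.queries


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (single reflection suffices for small steps)."""
    x = np.where(x > hi, 2 * hi - x, x)
    x = np.where(x < lo, 2 * lo - x, x)
    return np.clip(x, lo, hi)


@dataclass
class TwoStepEnv:
    """Two-step task schedule for ``n_agents`` parallel and independent games.

    First-stage action ``a`` commonly (prob ``common_prob``) leads to
    second-stage state ``a``.  Each second-stage state offers two actions
    whose reward probabilities follow independent Gaussian random walks with
    reflecting bounds.
    """

    n_agents: int = 1
    common_prob: float = 0.7
    drift_sd: float = 0.025
    bounds: tuple[float, float] = (0.25, 0.75)
    reward_probs: np.ndarray = field(default=None)  # (n_agents, 2 states, 2 actions)
    trial: int = 0

    def __post_init__(self):
        if self.reward_probs is None:
            # schedule initialised mid-range; callers wanting random starts
            # pass init_rng via `randomize_rewards`
            self.reward_probs = np.full((self.n_agents, 2, 2), 0.5)
        self.reward_probs = np.asarray(self.reward_probs, dtype=float)
        if self.reward_probs.shape != (self.n_agents, 2, 2):
            raise ValueError("reward_probs must have shape (n_agents, 2, 2)")

    def randomize_rewards(self, rng: np.random.Generator) -> "TwoStepEnv":
        lo, hi = self.bounds
        self.reward_probs = rng.uniform(lo, hi, size=(self.n_agents, 2, 2))
        return self

    def transition(self, first_action: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw second-stage states for a vector of first-stage actions."""
        a = np.asarray(first_action)
        common = rng.random(a.shape) < self.common_prob
        return np.where(common, a, 1 - a)

    def outcome(
        self, second_state: np.ndarray, second_action: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Bernoulli rewards for the chosen second-stage actions; advances drift."""
        idx = np.arange(self.n_agents)
        p = self.reward_probs[idx, second_state, second_action]
        reward = (rng.random(self.n_agents) < p).astype(int)
        self._drift(rng)
        self.trial += 1
        return reward

    def _drift(self, rng: np.random.Generator) -> None:
        if self.drift_sd > 0:
            step = rng.normal(0.0, self.drift_sd, size=self.reward_probs.shape)
            self.reward_probs = _reflect(self.reward_probs + step, *self.bounds)


def step_two_step(
    env: TwoStepEnv, first_action, second_action, rng: np.random.Generator
):
    """One full trial: transition draw, reward draw, reward-probability drift.

    Note the real task reveals the second-stage state before the second
    action is chosen; this one-shot form serves pre-committed probes and
    tests.  Returns (second_state, reward, env).
    """
    a1 = np.atleast_1d(np.asarray(first_action))
    a2 = np.atleast_1d(np.asarray(second_action))
    if not (np.isin(a1, (0, 1)).all() and np.isin(a2, (0, 1)).all()):
        raise ValueError("actions must be 0 or 1")
    s2 = env.transition(a1, rng)
    r = env.outcome(s2, a2, rng)
    if np.isscalar(first_action) or np.ndim(first_action) == 0:
        return int(s2[0]), int(r[0]), env
    return s2, r, env


GOALS = ("seek", "avoid")


def make_goal_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced, block-randomized goal labels (0=seek-reward, 1=avoid-punishment)."""
    half = n_trials // 2
    goals = np.concatenate([np.zeros(half, int), np.ones(n_trials - half, int)])
    rng.shuffle(goals)
    return goals


@dataclass
class MultiGoalEnv:
    """Multi-goal pursuit schedule for ``n_agents`` parallel games.

    Four independent probabilities P(state | action) for 2 actions x
    2 states (0 = reward state, 1 = punishment state), each drifting by a
    bounded Gaussian random walk.  States are reached independently, so a
    trial can reach both states, one, or neither.
    """

    n_agents: int = 1
    drift_sd: float = 0.04
    bounds: tuple[float, float] = (0.1, 0.9)
    probs: np.ndarray = field(default=None)  # (n_agents, 2 actions, 2 states)
    trial: int = 0

    def __post_init__(self):
        if self.probs is None:
            self.probs = np.full((self.n_agents, 2, 2), 0.5)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n_agents, 2, 2):
            raise ValueError("probs must have shape (n_agents, 2, 2)")

    def randomize(self, rng: np.random.Generator) -> "MultiGoalEnv":
        lo, hi = self.bounds
        self.probs = rng.uniform(lo, hi, size=(self.n_agents, 2, 2))
        return self

    def _drift(self, rng: np.random.Generator) -> None:
        if self.drift_sd > 0:
            step = rng.normal(0.0, self.drift_sd, size=self.probs.shape)
            self.probs = _reflect(self.probs + step, *self.bounds)


def step_multigoal(env: MultiGoalEnv, action, goal, rng: np.random.Generator):
    """One trial: independent state-reach draws, points per instructed goal, drift.

    Points are +1 iff the reward state is reached on a seek-reward trial and
    -1 iff the punishment state is reached on an avoid-punishment trial;
    reaching a state the instructions did not refer to has no consequence.
    Returns (reached (n_agents, 2) bool, points (n_agents,), env).
    """
    a = np.atleast_1d(np.asarray(action))
    g = np.atleast_1d(np.asarray(goal))
    if not np.isin(a, (0, 1)).all():
        raise ValueError("action must be 0 (g) or 1 (j)")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("goal must be 0 (seek) or 1 (avoid)")
    idx = np.arange(env.n_agents)
    p = env.probs[idx, a, :]  # (n_agents, 2)
    reached = rng.random(p.shape) < p
    points = np.where(g == 0, reached[:, 0].astype(int), -reached[:, 1].astype(int))
    env._drift(rng)
    env.trial += 1
    if np.isscalar(action) or np.ndim(action) == 0:
        return reached[0], int(points[0]), env
    return reached, points, env
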