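"""Decision models: incremental state-transition learning (ISTL), the
counting-heuristic "Typical" learner, and the multi-goal integrated model.

Two families of agents are implemented.

Two-step task (hybrid model-based / model-free chooser):

* ISTL: the belief P(s|a) for the chosen action moves toward the observed
  transition by a state prediction error scaled by learning rate ``gamma``;
  the complementary probability is set so each row sums to 1; the untaken
  action's beliefs decay toward the initial prior of 0.5.
* Typical: keeps a running count of observed action->state transitions and
  infers, each trial, which of the two candidate 0.7/0.3 transition matrices
  is true (their average on ties).

Either transition learner feeds a model-based value Q_MB(a) = sum_s
P(s|a) max_a' Q2(s,a'), combined with cached model-free values (learning
rate ``alpha``, chosen-value decay 1-alpha, unchosen-value decay ``decay``)
and a choice-perseveration bonus in a softmax policy.

Multi-goal task (four-strategy integrated model): model-based values gate the
learned reach probabilities by the instructed-goal vector ((1,0) on
seek-reward trials, (0,-1) on avoid-punishment trials), goal perseveration
uses the fixed vector (1,-1), a model-free strategy tracks points per action,
and action perseveration favours repeating the previous action.  The
strategies' values are integrated by a weighted sum and passed through a
softmax (temperatures absorbed into the beta weights).

Likelihood evaluation is vectorized over (subjects x parameter samples) so
that hierarchical fitting can weight thousands of parameter draws at once;
simulation is vectorized over agents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tasks import MultiGoalEnv, TwoStepEnv, make_goal_sequence

__all__ = [
    "ParamSpec",
    "AgentParamsTwoStep",
    "AgentParamsTypical",
    "AgentParamsMultiGoal",
    "softmax",
    "istl_update",
    "typical_infer",
    "mf_value_update",
    "two_step_choice_values",
    "multigoal_action_values",
    "TwoStepData",
    "MultiGoalData",
    "TwoStepISTLModel",
    "TwoStepTypicalModel",
    "MultiGoalModel",
    "ISTL",
    "TYPICAL",
    "MULTIGOAL",
    "get_model",
    "simulate_twostep",
    "simulate_multigoal",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class ParamSpec:
    """A model parameter: its name and domain kind.

    kind 'rate' lives in [0,1] (Beta priors), 'pos' in [0, inf) (Gamma
    priors), 'real' on the line (Normal priors).
    """

    name: str
    kind: str

    def __post_init__(self):
        if self.kind not in ("rate", "pos", "real"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")


@dataclass(frozen=True)
class AgentParamsTwoStep:
    """ISTL two-step parameters.

    gamma: transition learning rate; alpha: value learning rate (chosen-value
    decay is its complement 1-alpha); decay: unchosen-value decay D;
    beta_mb / beta_mf: model-based / model-free weights; beta2: second-stage
    inverse temperature; pi_stick: first-stage perseveration weight.
    """

    gamma: float
    alpha: float
    decay: float
    beta_mb: float
    beta_mf: float
    beta2: float
    pi_stick: float

    def __post_init__(self):
        for nm in ("gamma", "alpha", "decay"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")
        if self.beta_mb < 0:
            raise ValueError("beta_mb must be non-negative")


@dataclass(frozen=True)
class AgentParamsTypical:
    """Typical (counting) two-step parameters: as ISTL but without gamma."""

    alpha: float
    decay: float
    beta_mb: float
    beta_mf: float
    beta2: float
    pi_stick: float


@dataclass(frozen=True)
class AgentParamsMultiGoal:
    """Integrated multi-goal model parameters (weights for MB seek/avoid,
    goal-perseveration seek/avoid, model-free, and action-perseveration
    strategies, plus transition learning rate gamma and MF rate alpha_mf)."""

    gamma: float
    alpha_mf: float
    beta_mb_reward: float
    beta_mb_punish: float
    beta_gp_reward: float
    beta_gp_punish: float
    beta_mf: float
    beta_ap: float

    def __post_init__(self):
        for nm in ("gamma", "alpha_mf"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# primitive operations (scalar / broadcast friendly)

def softmax(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax along ``axis``."""
    v = np.asarray(values, dtype=float)
    v = v - v.max(axis=axis, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=axis, keepdims=True)


def istl_update(
    belief: np.ndarray,
    action: int,
    observed,
    gamma: float,
    mode: str = "twostep",
    decay_unchosen: bool = True,
) -> np.ndarray:
    """One incremental transition-learning update.

    ``belief`` is P(state | action) with rows indexed by action.  In
    'twostep' mode ``observed`` is the second-stage state reached and rows
    sum to 1: the observed transition moves toward 1 by gamma times the state
    prediction error and its complement is set so the row sums to 1.  In
    'multigoal' mode ``observed`` is a pair of booleans (reward state
    reached, punishment state reached) and each entry moves independently
    toward its outcome.  Either way the untaken action's entries decay toward
    the initial prior of 0.5.  Returns a new belief array.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma={gamma} outside [0, 1]")
    B = np.array(belief, dtype=float)
    if mode == "twostep":
        s = int(observed)
        B[action, s] += gamma * (1.0 - B[action, s])
        B[action, 1 - s] = 1.0 - B[action, s]
    elif mode == "multigoal":
        out = np.asarray(observed, dtype=float)
        B[action] += gamma * (out - B[action])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if decay_unchosen:
        other = 1 - action
        B[other] += gamma * (0.5 - B[other])
    return B


def typical_infer(counting: np.ndarray, common_prob: float = 0.7) -> np.ndarray:
    """Infer the transition matrix from a running transition tally.

    ``counting[s, a]`` tallies observed action-a -> state-s transitions
    (rows are states, columns actions, matching the tally's conventional
    layout).  Candidate matrix T1 has action a commonly leading to state a;
    T2 is the swap.  T1 is inferred when the diagonal tally exceeds the
    off-diagonal tally, T2 when it is smaller, and their element-wise average
    on a tie.  Returns P(state | action) with rows indexed by action.
    """
    C = np.asarray(counting, dtype=float)
    if C.shape != (2, 2) or np.any(C < 0):
        raise ValueError("counting must be a non-negative 2x2 tally")
    diag = C[0, 0] + C[1, 1]
    off = C[0, 1] + C[1, 0]
    p, q = common_prob, 1.0 - common_prob
    if diag > off:
        return np.array([[p, q], [q, p]])
    if diag < off:
        return np.array([[q, p], [p, q]])
    return np.full((2, 2), 0.5)


def mf_value_update(
    Q: np.ndarray, chosen, target: float, alpha: float, decay: float
) -> np.ndarray:
    """Model-free value update with unchosen-value forgetting.

    The chosen entry moves toward ``target`` with learning rate alpha
    (equivalently Q <- (1-alpha) Q + alpha target, i.e. chosen-value decay is
    the complement of the learning rate); every other entry decays toward 0
    by a factor (1 - decay).  ``chosen`` indexes the updated entry.
    """
    for nm, v in (("alpha", alpha), ("decay", decay)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm}={v} outside [0, 1]")
    Qn = np.asarray(Q, dtype=float) * (1.0 - decay)
    idx = chosen if isinstance(chosen, tuple) else (chosen,)
    Qn[idx] = Q[idx] + alpha * (target - Q[idx])
    return Qn


def two_step_choice_values(
    belief: np.ndarray,
    q2: np.ndarray,
    params: AgentParamsTwoStep | AgentParamsTypical,
    prev_action: int | None,
    q_mf: np.ndarray | None = None,
) -> dict:
    """First- and second-stage policies of the hybrid two-step chooser.

    Q_MB(a) = sum_s P(s|a) max_a' Q2(s, a'); the first-stage policy is a
    softmax of beta_mb Q_MB + beta_mf Q_MF + pi_stick [a == previous action];
    second-stage policies are softmax(beta2 Q2(s, .)).
    """
    B = np.asarray(belief, dtype=float)
    Q2 = np.asarray(q2, dtype=float)
    if not (np.all(np.isfinite(B)) and np.all(np.isfinite(Q2))):
        raise ValueError("non-finite values in belief or Q2")
    QMF = np.zeros(2) if q_mf is None else np.asarray(q_mf, dtype=float)
    V = Q2.max(axis=1)  # (2 states,)
    q_mb = B @ V
    stick = np.zeros(2)
    if prev_action is not None:
        stick[prev_action] = 1.0
    net = params.beta_mb * q_mb + params.beta_mf * QMF + params.pi_stick * stick
    return {
        "q_mb": q_mb,
        "policy1": softmax(net),
        "policy2": softmax(params.beta2 * Q2, axis=1),
    }


#: instructed-goal value vectors (reward-state value, punishment-state value)
GOAL_VECTORS = {0: (1.0, 0.0), 1: (0.0, -1.0)}  # 0 = seek-reward, 1 = avoid-punishment
GP_VECTOR = (1.0, -1.0)


def multigoal_action_values(
    belief: np.ndarray,
    goal: int,
    q_mf: np.ndarray,
    prev_action: int | None,
    params: AgentParamsMultiGoal,
) -> dict:
    """Integrated action values and policy for one multi-goal trial.

    belief[a, s] is the learned P(reach state s | action a) with state 0 the
    reward state and state 1 the punishment state.  Model-based values
    multiply these by the instructed-goal vector, goal-perseveration values by
    the fixed (1, -1) vector; the weighted sum over strategies feeds a
    softmax.
    """
    if goal not in GOAL_VECTORS:
        raise ValueError(f"unknown goal label {goal!r}")
    B = np.asarray(belief, dtype=float)
    gr, gp = GOAL_VECTORS[goal]
    q_mb_reward = B[:, 0] * gr
    q_mb_punish = B[:, 1] * gp
    q_gp_reward = B[:, 0] * GP_VECTOR[0]
    q_gp_punish = B[:, 1] * GP_VECTOR[1]
    q_ap = np.zeros(2)
    if prev_action is not None:
        q_ap[prev_action] = 1.0
    q_int = (
        params.beta_mb_reward * q_mb_reward
        + params.beta_mb_punish * q_mb_punish
        + params.beta_gp_reward * q_gp_reward
        + params.beta_gp_punish * q_gp_punish
        + params.beta_mf * np.asarray(q_mf, dtype=float)
        + params.beta_ap * q_ap
    )
    return {
        "q_mb_reward": q_mb_reward,
        "q_mb_punish": q_mb_punish,
        "q_gp_reward": q_gp_reward,
        "q_gp_punish": q_gp_punish,
        "q_ap": q_ap,
        "q_integrated": q_int,
        "policy": softmax(q_int),
    }


# ---------------------------------------------------------------------------
# stacked trial data

@dataclass
class TwoStepData:
    """Two-step trial logs stacked as (n_subjects, n_trials) arrays.

    ``mask`` is 1 for real trials, 0 for padding when subjects differ in
    trial counts.
    """

    ids: np.ndarray
    a1: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    r: np.ndarray
    mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.a1.shape[0]

    @property
    def n_trials(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)


@dataclass
class MultiGoalData:
    """Multi-goal trial logs stacked as (n_subjects, n_trials) arrays."""

    ids: np.ndarray
    action: np.ndarray
    goal: np.ndarray  # 0 seek, 1 avoid
    reached: np.ndarray  # (S, T, 2) reward/punish reach indicators
    points: np.ndarray
    mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.action.shape[0]


def _stack(df: pd.DataFrame, cols: Sequence[str]):
    ids = df["participant_id"].unique()
    groups = df.sort_values(["participant_id", "trial"]).groupby("participant_id", sort=False)
    T = int(groups.size().max())
    S = len(ids)
    arrays = {c: np.zeros((S, T), dtype=int) for c in cols}
    mask = np.zeros((S, T))
    for i, (_, g) in enumerate(groups):
        n = len(g)
        mask[i, :n] = 1.0
        for c in cols:
            arrays[c][i, :n] = g[c].to_numpy()
    return ids, arrays, mask


def stack_twostep(df: pd.DataFrame) -> TwoStepData:
    """Stack a tidy two-step trial log (see cli_io column dictionary)."""
    required = {"participant_id", "trial", "action", "state", "action2", "reward"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    ids, arrs, mask = _stack(df, ["action", "state", "action2", "reward"])
    return TwoStepData(ids, arrs["action"], arrs["state"], arrs["action2"], arrs["reward"], mask)


def stack_multigoal(df: pd.DataFrame) -> MultiGoalData:
    required = {"participant_id", "trial", "goal", "action", "reached_reward", "reached_punish", "points"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    df = df.copy()
    if df["goal"].dtype == object:
        df["goal"] = df["goal"].map({"seek": 0, "avoid": 1})
        if df["goal"].isna().any():
            raise ValueError("goal labels must be 'seek' or 'avoid'")
    ids, arrs, mask = _stack(df, ["action", "goal", "reached_reward", "reached_punish", "points"])
    reached = np.stack([arrs["reached_reward"], arrs["reached_punish"]], axis=-1)
    return MultiGoalData(ids, arrs["action"], arrs["goal"], reached, arrs["points"], mask)


# ---------------------------------------------------------------------------
# vectorized two-step likelihood

def _bernoulli_loglik(sign: np.ndarray, d: np.ndarray) -> np.ndarray:
    """log P(choice) for a two-option softmax with value difference d;
    sign is +1 when option 1 was chosen, -1 for option 0."""
    return -np.logaddexp(0.0, -sign * d)


def _typical_belief_path(data: TwoStepData, common_prob: float = 0.7) -> np.ndarray:
    """P(s=0 | a) per subject and trial under the counting heuristic,
    evaluated before each trial's choice.  Shape (S, T, 2)."""
    S, T = data.a1.shape
    C = np.zeros((S, 2, 2))  # [state, action]
    out = np.empty((S, T, 2))
    idx = np.arange(S)
    p, q = common_prob, 1.0 - common_prob
    for t in range(T):
        diag = C[:, 0, 0] + C[:, 1, 1]
        off = C[:, 0, 1] + C[:, 1, 0]
        p00 = np.where(diag > off, p, np.where(diag < off, q, 0.5))
        out[:, t, 0] = p00
        out[:, t, 1] = 1.0 - p00
        C[idx, data.s2[:, t], data.a1[:, t]] += data.mask[:, t]
    return out


def _twostep_loglik_core(
    data: TwoStepData,
    *,
    alpha: np.ndarray,
    decay: np.ndarray,
    beta_mb: np.ndarray,
    beta_mf: np.ndarray,
    beta2: np.ndarray,
    pi_stick: np.ndarray,
    gamma: np.ndarray | None = None,
    belief_path: np.ndarray | None = None,
) -> np.ndarray:
    """Summed log choice likelihood, shape (n_subjects, K).

    Either ``gamma`` (ISTL beliefs, evolved per parameter sample) or
    ``belief_path`` (Typical beliefs, data-determined) must be given.
    """
    if (gamma is None) == (belief_path is None):
        raise ValueError("give exactly one of gamma or belief_path")
    S, T = data.a1.shape
    K = alpha.shape[0]
    ar = np.arange(2)
    QMF = np.zeros((S, K, 2))
    Q2 = np.zeros((S, K, 2, 2))  # [state, action]
    ll = np.zeros((S, K))
    rep = np.zeros((S, 1, 2))
    alK = alpha[None, :, None]
    DK = decay[None, :, None]
    alQ = alpha[None, :, None, None]
    DQ = decay[None, :, None, None]
    bmbK = beta_mb[None, :, None]
    bmfK = beta_mf[None, :, None]
    pstK = pi_stick[None, :, None]
    if gamma is not None:
        B = np.full((S, K, 2), 0.5)  # P(s=0 | a), last axis action
        gK = gamma[None, :, None]
    for t in range(T):
        a1 = data.a1[:, t]
        s2 = data.s2[:, t]
        a2 = data.a2[:, t]
        r = data.r[:, t]
        m = data.mask[:, t]
        mS = m[:, None]
        mQ = m[:, None, None]
        mQ2 = m[:, None, None, None]
        if belief_path is not None:
            B = belief_path[:, t, :][:, None, :]
        V = Q2.max(axis=3)  # (S, K, 2) value of each second-stage state
        QMB = B * V[..., 0][..., None] + (1.0 - B) * V[..., 1][..., None]
        net = bmbK * QMB + bmfK * QMF + pstK * rep
        ll += mS * _bernoulli_loglik((2 * a1 - 1)[:, None], net[..., 1] - net[..., 0])
        q2sel = np.where((s2 == 1)[:, None, None], Q2[..., 1, :], Q2[..., 0, :])
        ll += mS * _bernoulli_loglik(
            (2 * a2 - 1)[:, None], beta2[None, :] * (q2sel[..., 1] - q2sel[..., 0])
        )
        # learning
        c1 = (a1[:, None] == ar).astype(float)[:, None, :]  # (S,1,2) chosen one-hot
        if gamma is not None:
            obs0 = (s2 == 0).astype(float)[:, None, None]
            target = c1 * obs0 + (1.0 - c1) * 0.5
            B = B + mQ * gK * (target - B)
        hot2 = (
            (s2[:, None] == ar).astype(float)[:, None, :, None]
            * (a2[:, None] == ar).astype(float)[:, None, None, :]
        )
        rQ = r[:, None, None, None]
        Q2 = Q2 + mQ2 * (hot2 * alQ * (rQ - Q2) - (1.0 - hot2) * DQ * Q2)
        rS = r[:, None, None]
        QMF = QMF + mQ * (c1 * alK * (rS - QMF) - (1.0 - c1) * DK * QMF)
        rep = np.where(mQ > 0, c1, rep)
    return ll


def _multigoal_loglik_core(
    data: MultiGoalData,
    *,
    gamma: np.ndarray,
    alpha_mf: np.ndarray,
    beta_mb_reward: np.ndarray,
    beta_mb_punish: np.ndarray,
    beta_gp_reward: np.ndarray,
    beta_gp_punish: np.ndarray,
    beta_mf: np.ndarray,
    beta_ap: np.ndarray,
    decay_unchosen: bool = True,
) -> np.ndarray:
    S, T = data.action.shape
    K = gamma.shape[0]
    ar = np.arange(2)
    B = np.full((S, K, 2, 2), 0.5)  # [action, state]
    QMF = np.zeros((S, K, 2))
    rep = np.zeros((S, 1, 2))
    ll = np.zeros((S, K))
    gK = gamma[None, :, None, None]
    aK = alpha_mf[None, :, None]
    for t in range(T):
        a = data.action[:, t]
        g = data.goal[:, t]
        reach = data.reached[:, t, :]  # (S, 2)
        pts = data.points[:, t]
        m = data.mask[:, t]
        seek = (g == 0).astype(float)[:, None, None]
        avoid = 1.0 - seek
        Br = B[..., 0]  # P(reward state | a), (S,K,2)
        Bp = B[..., 1]
        q_int = (
            beta_mb_reward[None, :, None] * (Br * seek)
            + beta_mb_punish[None, :, None] * (-Bp * avoid)
            + beta_gp_reward[None, :, None] * Br
            + beta_gp_punish[None, :, None] * (-Bp)
            + beta_mf[None, :, None] * QMF
            + beta_ap[None, :, None] * rep
        )
        ll += m[:, None] * _bernoulli_loglik(
            (2 * a - 1)[:, None], q_int[..., 1] - q_int[..., 0]
        )
        # transition learning: chosen action's reach probabilities move toward
        # the binary outcomes; untaken action's decay toward the 0.5 prior
        cA = (a[:, None] == ar).astype(float)[:, None, :, None]  # (S,1,2,1)
        outc = reach.astype(float)[:, None, None, :]  # (S,1,1,2)
        if decay_unchosen:
            target = cA * outc + (1.0 - cA) * 0.5
            B = B + m[:, None, None, None] * gK * (target - B)
        else:
            B = B + m[:, None, None, None] * gK * cA * (outc - B)
        c1 = cA[..., 0]  # (S,1,2)
        QMF = QMF + m[:, None, None] * c1 * aK * (pts[:, None, None] - QMF)
        rep = np.where(m[:, None, None] > 0, c1, rep)
    return ll


# ---------------------------------------------------------------------------
# model objects (shared protocol used by the fitting module)

def _cols(theta: np.ndarray, n: int) -> list[np.ndarray]:
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != n:
        raise ValueError(f"expected {n} parameter columns, got {theta.shape[1]}")
    return [theta[:, j] for j in range(n)]


class _ModelBase:
    param_specs: tuple[ParamSpec, ...] = ()

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.param_specs]


class TwoStepISTLModel(_ModelBase):
    """Incremental state-transition learner in the hybrid two-step chooser."""

    name = "istl"
    task = "twostep"
    param_specs = (
        ParamSpec("gamma", "rate"),
        ParamSpec("alpha", "rate"),
        ParamSpec("decay", "rate"),
        ParamSpec("beta_mb", "pos"),
        ParamSpec("beta_mf", "real"),
        ParamSpec("beta2", "pos"),
        ParamSpec("pi_stick", "real"),
    )

    def stack(self, df: pd.DataFrame) -> TwoStepData:
        return stack_twostep(df)

    def loglik(self, data: TwoStepData, theta: np.ndarray) -> np.ndarray:
        from . import _kernels

        g, al, D, bmb, bmf, b2, pst = _cols(theta, 7)
        return _kernels.istl_twostep_ll(
            data.a1, data.s2, data.a2, data.r, data.mask, g, al, D, bmb, bmf, b2, pst
        )

    def loglik_reference(self, data: TwoStepData, theta: np.ndarray) -> np.ndarray:
        """Vectorized-numpy evaluation of the same likelihood (for
        cross-checking the compiled kernel)."""
        g, al, D, bmb, bmf, b2, pst = _cols(theta, 7)
        return _twostep_loglik_core(
            data, gamma=g, alpha=al, decay=D, beta_mb=bmb, beta_mf=bmf, beta2=b2, pi_stick=pst
        )

    def simulate(self, theta: np.ndarray, n_trials: int, rng: np.random.Generator, **env_kwargs):
        return simulate_twostep(theta, n_trials, rng, model="istl", **env_kwargs)


class TwoStepTypicalModel(_ModelBase):
    """Counting-heuristic transition inference in the hybrid two-step chooser."""

    name = "typical"
    task = "twostep"
    param_specs = TwoStepISTLModel.param_specs[1:]

    def stack(self, df: pd.DataFrame) -> TwoStepData:
        return stack_twostep(df)

    def loglik(self, data: TwoStepData, theta: np.ndarray) -> np.ndarray:
        from . import _kernels

        al, D, bmb, bmf, b2, pst = _cols(theta, 6)
        path = _typical_belief_path(data)
        return _kernels.typical_twostep_ll(
            data.a1, data.s2, data.a2, data.r, data.mask, path, al, D, bmb, bmf, b2, pst
        )

    def loglik_reference(self, data: TwoStepData, theta: np.ndarray) -> np.ndarray:
        al, D, bmb, bmf, b2, pst = _cols(theta, 6)
        path = _typical_belief_path(data)
        return _twostep_loglik_core(
            data, belief_path=path, alpha=al, decay=D, beta_mb=bmb, beta_mf=bmf,
            beta2=b2, pi_stick=pst,
        )

    def simulate(self, theta: np.ndarray, n_trials: int, rng: np.random.Generator, **env_kwargs):
        return simulate_twostep(theta, n_trials, rng, model="typical", **env_kwargs)


class MultiGoalModel(_ModelBase):
    """Four-strategy integrated model for the multi-goal pursuit task."""

    name = "multigoal"
    task = "multigoal"
    param_specs = (
        ParamSpec("gamma", "rate"),
        ParamSpec("alpha_mf", "rate"),
        ParamSpec("beta_mb_reward", "real"),
        ParamSpec("beta_mb_punish", "real"),
        ParamSpec("beta_gp_reward", "real"),
        ParamSpec("beta_gp_punish", "real"),
        ParamSpec("beta_mf", "real"),
        ParamSpec("beta_ap", "real"),
    )

    def __init__(self, decay_unchosen: bool = True):
        self.decay_unchosen = decay_unchosen

    def stack(self, df: pd.DataFrame) -> MultiGoalData:
        return stack_multigoal(df)

    def loglik(self, data: MultiGoalData, theta: np.ndarray) -> np.ndarray:
        g, amf, bmr, bmp, bgr, bgp, bmf, bap = _cols(theta, 8)
        return _multigoal_loglik_core(
            data, gamma=g, alpha_mf=amf, beta_mb_reward=bmr, beta_mb_punish=bmp,
            beta_gp_reward=bgr, beta_gp_punish=bgp, beta_mf=bmf, beta_ap=bap,
            decay_unchosen=self.decay_unchosen,
        )

    def simulate(self, theta: np.ndarray, n_trials: int, rng: np.random.Generator, **env_kwargs):
        return simulate_multigoal(theta, n_trials, rng,
                                  decay_unchosen=self.decay_unchosen, **env_kwargs)


ISTL = TwoStepISTLModel()
TYPICAL = TwoStepTypicalModel()
MULTIGOAL = MultiGoalModel()

_MODELS = {m.name: m for m in (ISTL, TYPICAL, MULTIGOAL)}


def get_model(name: str):
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(_MODELS)}") from None


# ---------------------------------------------------------------------------
# vectorized simulators (one agent per row of theta)

def _theta_dict(theta, names):
    if isinstance(theta, dict):
        return {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in theta.items()}
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return {nm: theta[:, j] for j, nm in enumerate(names)}


def simulate_twostep(
    theta,
    n_trials: int,
    rng: np.random.Generator,
    model: str = "istl",
    common_prob: float = 0.7,
    drift_sd: float = 0.025,
    bounds: tuple[float, float] = (0.25, 0.75),
    return_frame: bool = True,
):
    """Simulate N two-step agents in parallel (one per parameter row).

    ``theta`` is an (N, P) array in the model's parameter order or a dict of
    per-agent arrays.  Returns a tidy trial-log DataFrame (or raw arrays with
    ``return_frame=False``; the array form also carries total rewards).
    """
    names = (
        ["gamma", "alpha", "decay", "beta_mb", "beta_mf", "beta2", "pi_stick"]
        if model == "istl"
        else ["alpha", "decay", "beta_mb", "beta_mf", "beta2", "pi_stick"]
    )
    p = _theta_dict(theta, names)
    N = len(next(iter(p.values())))
    env = TwoStepEnv(n_agents=N, common_prob=common_prob, drift_sd=drift_sd, bounds=bounds)
    env.randomize_rewards(rng)
    ar = np.arange(2)
    idx = np.arange(N)
    B = np.full((N, 2), 0.5)  # P(s=0 | a) for ISTL
    C = np.zeros((N, 2, 2))  # counting tally [state, action] for Typical
    QMF = np.zeros((N, 2))
    Q2 = np.zeros((N, 2, 2))
    rep = np.zeros((N, 2))
    out = {k: np.empty((N, n_trials), dtype=int) for k in ("action", "state", "action2", "reward", "common")}
    pq = (common_prob, 1.0 - common_prob)
    for t in range(n_trials):
        if model == "typical":
            diag = C[:, 0, 0] + C[:, 1, 1]
            off = C[:, 0, 1] + C[:, 1, 0]
            B = np.where(
                (diag > off)[:, None], [pq[0], pq[1]],
                np.where((diag < off)[:, None], [pq[1], pq[0]], 0.5),
            )
        V = Q2.max(axis=2)  # (N, 2) per state
        QMB = B * V[:, [0]] + (1.0 - B) * V[:, [1]]
        net = p["beta_mb"][:, None] * QMB + p["beta_mf"][:, None] * QMF + p["pi_stick"][:, None] * rep
        prob1 = 1.0 / (1.0 + np.exp(-(net[:, 1] - net[:, 0])))
        a1 = (rng.random(N) < prob1).astype(int)
        s2 = env.transition(a1, rng)
        q2s = Q2[idx, s2, :]
        prob2 = 1.0 / (1.0 + np.exp(-p["beta2"] * (q2s[:, 1] - q2s[:, 0])))
        a2 = (rng.random(N) < prob2).astype(int)
        r = env.outcome(s2, a2, rng)
        out["action"][:, t] = a1
        out["state"][:, t] = s2
        out["action2"][:, t] = a2
        out["reward"][:, t] = r
        out["common"][:, t] = (s2 == a1).astype(int)
        # learning
        c1 = (a1[:, None] == ar).astype(float)
        if model == "istl":
            obs0 = (s2 == 0).astype(float)[:, None]
            target = c1 * obs0 + (1.0 - c1) * 0.5
            B = B + p["gamma"][:, None] * (target - B)
        else:
            C[idx, s2, a1] += 1.0
        hot2 = (s2[:, None] == ar).astype(float)[:, :, None] * (a2[:, None] == ar).astype(float)[:, None, :]
        Q2 = Q2 + hot2 * p["alpha"][:, None, None] * (r[:, None, None] - Q2) \
            - (1.0 - hot2) * p["decay"][:, None, None] * Q2
        QMF = QMF + c1 * p["alpha"][:, None] * (r[:, None] - QMF) \
            - (1.0 - c1) * p["decay"][:, None] * QMF
        rep = c1
    if not return_frame:
        return out
    return _twostep_frame(out, N, n_trials)


def _twostep_frame(out: dict, N: int, T: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(N), T),
            "trial": np.tile(np.arange(T), N),
            "action": out["action"].ravel(),
            "state": out["state"].ravel(),
            "action2": out["action2"].ravel(),
            "reward": out["reward"].ravel(),
            "common": out["common"].ravel(),
        }
    )


def simulate_multigoal(
    theta,
    n_trials: int,
    rng: np.random.Generator,
    drift_sd: float = 0.04,
    bounds: tuple[float, float] = (0.1, 0.9),
    decay_unchosen: bool = True,
    goals: np.ndarray | None = None,
    return_frame: bool = True,
):
    """Simulate N multi-goal agents in parallel (one per parameter row)."""
    names = [
        "gamma", "alpha_mf", "beta_mb_reward", "beta_mb_punish",
        "beta_gp_reward", "beta_gp_punish", "beta_mf", "beta_ap",
    ]
    p = _theta_dict(theta, names)
    N = len(next(iter(p.values())))
    env = MultiGoalEnv(n_agents=N, drift_sd=drift_sd, bounds=bounds).randomize(rng)
    if goals is None:
        goals = make_goal_sequence(n_trials, rng)
    goals = np.asarray(goals, dtype=int)
    ar = np.arange(2)
    idx = np.arange(N)
    B = np.full((N, 2, 2), 0.5)  # [action, state]
    QMF = np.zeros((N, 2))
    rep = np.zeros((N, 2))
    out = {
        k: np.empty((N, n_trials), dtype=int)
        for k in ("action", "goal", "reached_reward", "reached_punish", "points")
    }
    for t in range(n_trials):
        g = goals[t]
        seek = 1.0 if g == 0 else 0.0
        Br, Bp = B[..., 0], B[..., 1]
        q_int = (
            p["beta_mb_reward"][:, None] * (Br * seek)
            + p["beta_mb_punish"][:, None] * (-Bp * (1.0 - seek))
            + p["beta_gp_reward"][:, None] * Br
            + p["beta_gp_punish"][:, None] * (-Bp)
            + p["beta_mf"][:, None] * QMF
            + p["beta_ap"][:, None] * rep
        )
        prob1 = 1.0 / (1.0 + np.exp(-(q_int[:, 1] - q_int[:, 0])))
        a = (rng.random(N) < prob1).astype(int)
        probs = env.probs[idx, a, :]
        reached = rng.random((N, 2)) < probs
        pts = np.where(g == 0, reached[:, 0].astype(int), -reached[:, 1].astype(int))
        env._drift(rng)
        out["action"][:, t] = a
        out["goal"][:, t] = g
        out["reached_reward"][:, t] = reached[:, 0]
        out["reached_punish"][:, t] = reached[:, 1]
        out["points"][:, t] = pts
        cA = (a[:, None] == ar).astype(float)[:, :, None]  # (N,2,1)
        outc = reached.astype(float)[:, None, :]
        if decay_unchosen:
            target = cA * outc + (1.0 - cA) * 0.5
            B = B + p["gamma"][:, None, None] * (target - B)
        else:
            B = B + p["gamma"][:, None, None] * cA * (outc - B)
        c1 = cA[..., 0]
        QMF = QMF + c1 * p["alpha_mf"][:, None] * (pts[:, None] - QMF)
        rep = c1
    if not return_frame:
        return out
    df = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(N), n_trials),
            "trial": np.tile(np.arange(n_trials), N),
            "goal": np.where(out["goal"].ravel() == 0, "seek", "avoid"),
            "action": out["action"].ravel(),
            "reached_reward": out["reached_reward"].ravel(),
            "reached_punish": out["reached_punish"].ravel(),
            "points": out["points"].ravel(),
        }
    )
    return df
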