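"""Model-agnostic behavioral signatures and parameter-trait analyses.

The central signature is "model-basedness": the proportion of post-rare-
transition trials on which behavior follows model-based prescriptions —
switching the first-stage action after a rare transition was rewarded, and
staying after a rare transition went unrewarded.  Stay-probability tables
condition staying on the previous trial's transition type x reward, the
classic 2x2 display.

Also here: OLS regressions of traits on fitted parameters (standardized,
optional covariates), the three-regression mediation test of whether the
model-based weight mediates a learning-rate/trait relation (on log scales),
and learning-rate optimality sweeps that measure average earned reward as a
function of the transition learning rate in stable (two-step) and changing
(multi-goal) environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import agents

__all__ = [
    "model_basedness",
    "StayTable",
    "stay_probability_table",
    "trait_parameter_regression",
    "MediationResult",
    "mediation_analysis",
    "SweepResult",
    "optimality_sweep",
    "group_fixed_params",
]


def _mb_one(g: pd.DataFrame) -> float:
    a = g["action"].to_numpy()
    r = g["reward"].to_numpy()
    common = g["common"].to_numpy().astype(bool)
    stay = a[1:] == a[:-1]
    rare = ~common[:-1]
    rew = r[:-1] == 1
    num = np.sum(rare & rew & ~stay) + np.sum(rare & ~rew & stay)
    den = np.sum(rare)
    return num / den if den > 0 else np.nan


def model_basedness(trial_log: pd.DataFrame):
    """Proportion of model-based-consistent switch/stay behavior after rare
    transitions (switch after rewarded rare, stay after unrewarded rare).

    Returns a float for a single-subject log, else a Series per participant.
    NaN where a subject has no rare transitions (undefined, not an error).
    """
    required = {"trial", "action", "reward", "common"}
    missing = required - set(trial_log.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    if "participant_id" not in trial_log.columns or trial_log["participant_id"].nunique() == 1:
        return _mb_one(trial_log.sort_values("trial"))
    return (
        trial_log.sort_values(["participant_id", "trial"])
        .groupby("participant_id", sort=False)
        .apply(_mb_one, include_groups=False)
        .rename("model_basedness")
    )


@dataclass
class StayTable:
    """Stay probabilities and trial counts for the {common, rare} x
    {rewarded, unrewarded} cells.  Probabilities are means over participants
    of per-participant proportions; counts are pooled."""

    probs: pd.DataFrame  # index common/rare, columns rewarded/unrewarded
    counts: pd.DataFrame


def stay_probability_table(trial_log: pd.DataFrame) -> StayTable:
    """Tabulate P(repeat first-stage action) by the previous trial's
    transition type and reward."""
    if "participant_id" not in trial_log.columns:
        trial_log = trial_log.assign(participant_id=0)
    counts = np.zeros((2, 2))
    per = []
    for _, g in trial_log.sort_values(["participant_id", "trial"]).groupby(
        "participant_id", sort=False
    ):
        a = g["action"].to_numpy()
        r = g["reward"].to_numpy().astype(bool)
        common = g["common"].to_numpy().astype(bool)
        stay = a[1:] == a[:-1]
        cell_p = np.full((2, 2), np.nan)
        for i, tr in enumerate((common[:-1], ~common[:-1])):
            for j, rw in enumerate((r[:-1], ~r[:-1])):
                sel = tr & rw
                counts[i, j] += sel.sum()
                if sel.any():
                    cell_p[i, j] = stay[sel].mean()
        per.append(cell_p)
    probs = np.nanmean(np.stack(per), axis=0)
    idx = pd.Index(["common", "rare"], name="transition")
    cols = pd.Index(["rewarded", "unrewarded"], name="outcome")
    return StayTable(
        probs=pd.DataFrame(probs, index=idx, columns=cols),
        counts=pd.DataFrame(counts.astype(int), index=idx, columns=cols),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant predictor cannot be standardized")
    return (x - x.mean()) / sd


def _ols_table(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )


def trait_parameter_regression(
    estimates, traits, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """OLS of a trait score on parameter estimates (plus covariates), all
    standardized.  ``estimates`` may be a Series (one predictor) or a
    DataFrame.  Returns a coefficient table (coef, se, t, p)."""
    X = pd.DataFrame(estimates).copy()
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates)], axis=1)
    Xz = X.apply(lambda c: _standardize(c.to_numpy().astype(float)))
    yz = _standardize(np.asarray(traits, dtype=float))
    return _ols_table(yz, Xz)


@dataclass
class MediationResult:
    """The three regressions of the mediation test and their verdict.

    alone: trait ~ gamma (+covariates); mediator: trait ~ beta_mb; joint:
    trait ~ gamma + beta_mb.  Verdict 'full mediation' when gamma is
    significant alone but not jointly while beta_mb remains significant.
    """

    alone: pd.DataFrame
    mediator: pd.DataFrame
    joint: pd.DataFrame
    verdict: str
    alpha: float = 0.05


def mediation_analysis(
    gamma_hat,
    beta_mb_hat,
    trait,
    covariates: pd.DataFrame | None = None,
    log_transform: bool = True,
    alpha: float = 0.05,
) -> MediationResult:
    """Test whether the model-based weight mediates a learning-rate/trait
    relation.  Both parameters are log-transformed by default (their relation
    is nonlinear on native scales); non-positive values then raise."""
    g = np.asarray(gamma_hat, dtype=float)
    b = np.asarray(beta_mb_hat, dtype=float)
    if log_transform:
        if np.any(g <= 0) or np.any(b <= 0):
            raise ValueError(
                "log transform requires positive gamma and beta_mb estimates; "
                "pass log_transform=False or drop non-positive values"
            )
        g, b = np.log(g), np.log(b)
    preds = pd.DataFrame({"gamma": g, "beta_mb": b})
    alone = trait_parameter_regression(preds[["gamma"]], trait, covariates)
    mediator = trait_parameter_regression(preds[["beta_mb"]], trait, covariates)
    joint = trait_parameter_regression(preds, trait, covariates)
    g_alone = alone.loc["gamma", "p"] < alpha
    g_joint = joint.loc["gamma", "p"] < alpha
    b_joint = joint.loc["beta_mb", "p"] < alpha
    if g_alone and not g_joint and b_joint:
        verdict = "full mediation"
    elif g_alone and g_joint and b_joint:
        verdict = "partial mediation"
    else:
        verdict = "no mediation"
    return MediationResult(alone, mediator, joint, verdict, alpha)


# ---------------------------------------------------------------------------
# learning-rate optimality

def group_fixed_params(
    estimates: pd.DataFrame,
    high_beta_mb: bool = True,
    skew_z_cut: float = 4.0,
    high_percentile: float = 97.5,
) -> dict:
    """Fix non-swept parameters at group medians for highly skewed
    distributions (|skew-test z| > ``skew_z_cut``) and at group means
    otherwise; optionally set beta_mb to a high value from the tail of its
    distribution (the ``high_percentile`` percentile)."""
    out = {}
    for col in estimates.columns:
        x = estimates[col].to_numpy().astype(float)
        try:
            z = abs(stats.skewtest(x)[0])
        except ValueError:  # too few observations for the test
            z = 0.0
        out[col] = float(np.median(x) if z > skew_z_cut else np.mean(x))
    if high_beta_mb and "beta_mb" in estimates.columns:
        out["beta_mb"] = float(np.percentile(estimates["beta_mb"], high_percentile))
    return out


@dataclass
class SweepResult:
    curve: pd.DataFrame  # gamma, mean_reward, normalized
    refined: pd.DataFrame
    argmax_gamma: float

    def normalized_at(self, gamma: float) -> float:
        i = int(np.argmin(np.abs(self.curve["gamma"].to_numpy() - gamma)))
        return float(self.curve["normalized"].iloc[i])


def _sweep_rewards(task, gamma, n_reps, fixed_params, rng, n_trials):
    theta = dict(fixed_params)
    theta["gamma"] = gamma
    if task == "twostep":
        order = ["gamma", "alpha", "decay", "beta_mb", "beta_mf", "beta2", "pi_stick"]
        full = np.tile([theta[k] for k in order], (n_reps, 1))
        out = agents.simulate_twostep(full, n_trials, rng, return_frame=False)
        return out["reward"].sum(axis=1).mean()
    if task == "multigoal":
        order = ["gamma", "alpha_mf", "beta_mb_reward", "beta_mb_punish",
                 "beta_gp_reward", "beta_gp_punish", "beta_mf", "beta_ap"]
        full = np.tile([theta[k] for k in order], (n_reps, 1))
        out = agents.simulate_multigoal(full, n_trials, rng, return_frame=False)
        return out["points"].sum(axis=1).mean()
    raise ValueError(f"unknown task {task!r}")


def optimality_sweep(
    task: str,
    gamma_grid,
    n_reps: int,
    fixed_params: dict,
    seed: int = 0,
    n_trials: int = 100,
    refine_halfwidth: float = 0.1,
    refine_step: float = 0.025,
) -> SweepResult:
    """Mean total reward earned per transition learning rate, min-max
    normalized to [0, 1], plus a refined grid around the coarse argmax.

    Every rate on the grid plays ``n_reps`` independent games of
    ``n_trials`` trials with all other parameters held at ``fixed_params``.
    """
    gamma_grid = np.asarray(sorted(gamma_grid), dtype=float)
    if gamma_grid.min() < 0 or gamma_grid.max() > 1:
        raise ValueError("gamma grid must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    rewards = []
    for g, child in zip(gamma_grid, ss.spawn(len(gamma_grid))):
        rewards.append(
            _sweep_rewards(task, g, n_reps, fixed_params, np.random.default_rng(child), n_trials)
        )
    rewards = np.asarray(rewards)
    lo, hi = rewards.min(), rewards.max()
    norm = (rewards - lo) / (hi - lo) if hi > lo else np.zeros_like(rewards)
    curve = pd.DataFrame({"gamma": gamma_grid, "mean_reward": rewards, "normalized": norm})
    g_star = float(gamma_grid[np.argmax(rewards)])
    fine = np.arange(
        max(0.0, g_star - refine_halfwidth),
        min(1.0, g_star + refine_halfwidth) + 1e-9,
        refine_step,
    )
    fine_rewards = []
    for g, child in zip(fine, ss.spawn(len(fine))):
        fine_rewards.append(
            _sweep_rewards(task, g, n_reps, fixed_params, np.random.default_rng(child), n_trials)
        )
    refined = pd.DataFrame({"gamma": fine, "mean_reward": fine_rewards})
    return SweepResult(curve=curve, refined=refined, argmax_gamma=g_star)
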