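"""Synthetic cohorts with known ground truth.

Generates complete synthetic studies so that every pipeline stage has a
surface to validate against: latent trait factors with a planted
questionnaire loading structure, covariates, agent parameters coupled to
traits on transformed scales (logit for rates, log for non-negative
weights, identity for signed weights), task behavior simulated from the
generative agents, and block-correctness data for the revaluation study
generated from a logistic ground-truth model.

Every generator stores its planted effects in a ground-truth mapping
sufficient to recompute each effect independently of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import agents
from .tasks import ONE_STEP_CONDITIONS

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_questionnaire",
    "generate_study_behavior",
    "generate_study1_correctness",
    "generate_mediation_cohort",
]

#: base (median) agent parameters on native scales, per model
_BASE_PARAMS = {
    "istl": {
        "gamma": 0.3, "alpha": 0.5, "decay": 0.4, "beta_mb": 3.0,
        "beta_mf": 0.8, "beta2": 2.4, "pi_stick": 0.2,
    },
    "multigoal": {
        "gamma": 0.4, "alpha_mf": 0.5, "beta_mb_reward": 2.0,
        "beta_mb_punish": 2.0, "beta_gp_reward": 1.0, "beta_gp_punish": 1.0,
        "beta_mf": 0.5, "beta_ap": 0.5,
    },
}
_BASE_PARAMS["typical"] = {k: v for k, v in _BASE_PARAMS["istl"].items() if k != "gamma"}

#: spread (s.d.) of each parameter around its base on the transformed scale
_DEFAULT_NOISE = 0.5


def _default_factor_corr() -> np.ndarray:
    c = np.full((3, 3), 0.3)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``couplings`` maps parameter name -> (factor index, slope); slopes act on
    the parameter's transformed scale (logit for rates, log for non-negative
    weights, identity otherwise) per standardized factor unit, so native-
    scale range invariants hold by construction.  ``factor_corr`` is the
    latent trait correlation matrix; questionnaire items load 0.6 on their
    own factor with no cross-loadings and are Likert-discretized.
    """

    n: int = 200
    model: str = "istl"
    factor_corr: np.ndarray = field(default_factory=_default_factor_corr)
    items_per_factor: int = 10
    item_loading: float = 0.6
    likert_thresholds: tuple = (-1.5, -0.5, 0.5, 1.5)
    couplings: dict = field(default_factory=dict)  # name -> (factor_idx, slope)
    param_base: dict = field(default_factory=dict)
    param_noise: float = _DEFAULT_NOISE
    covariates: bool = True
    seed: int = 0

    def validate(self) -> None:
        model = agents.get_model(self.model)
        base = {**_BASE_PARAMS[self.model], **self.param_base}
        kinds = {p.name: p.kind for p in model.param_specs}
        for name, (fidx, _) in self.couplings.items():
            if name not in kinds:
                raise ValueError(f"coupling for unknown parameter {name!r}")
            if not 0 <= fidx < self.factor_corr.shape[0]:
                raise ValueError(f"coupling factor index {fidx} out of range")
        for name, kind in kinds.items():
            v = base[name]
            if kind == "rate" and not 0.0 < v < 1.0:
                raise ValueError(f"base rate {name}={v} must lie strictly in (0, 1)")
            if kind == "pos" and v <= 0:
                raise ValueError(f"base weight {name}={v} must be positive")


def generate_questionnaire(
    n: int,
    rng: np.random.Generator,
    factor_corr: np.ndarray | None = None,
    items_per_factor: int = 10,
    loading: float = 0.6,
    likert_thresholds: tuple = (-1.5, -0.5, 0.5, 1.5),
):
    """Likert questionnaire items from a planted factor model.

    Returns (items DataFrame, factors DataFrame, loading matrix).  Items are
    Gaussian with loading ``loading`` on their own factor, unique variance
    1 - loading^2, discretized at ``likert_thresholds``.
    """
    C = _default_factor_corr() if factor_corr is None else np.asarray(factor_corr)
    k = C.shape[0]
    f = rng.multivariate_normal(np.zeros(k), C, size=n, method="cholesky")
    p = k * items_per_factor
    lam = np.zeros((p, k))
    for j in range(k):
        lam[j * items_per_factor : (j + 1) * items_per_factor, j] = loading
    latent = f @ lam.T + rng.normal(0.0, np.sqrt(1 - loading**2), size=(n, p))
    items = np.digitize(latent, likert_thresholds)
    items_df = pd.DataFrame(items, columns=[f"item_{i:02d}" for i in range(p)])
    factors_df = pd.DataFrame(f, columns=[f"f{j + 1}" for j in range(k)])
    return items_df, factors_df, lam


def _couple_params(spec: CohortSpec, factors: np.ndarray, rng: np.random.Generator):
    model = agents.get_model(spec.model)
    base = {**_BASE_PARAMS[spec.model], **spec.param_base}
    out = {}
    for p in model.param_specs:
        mean_t = {"rate": logit, "pos": np.log, "real": lambda x: x}[p.kind](base[p.name])
        t = mean_t + rng.normal(0.0, spec.param_noise, size=len(factors))
        if p.name in spec.couplings:
            fidx, slope = spec.couplings[p.name]
            t = t + slope * factors[:, fidx]
        out[p.name] = {"rate": expit, "pos": np.exp, "real": lambda x: x}[p.kind](t)
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec):
    """Generate a full cohort: traits, questionnaire items, covariates, and
    trait-coupled agent parameters, plus a separable ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    items, factors, lam = generate_questionnaire(
        spec.n, rng, spec.factor_corr, spec.items_per_factor,
        spec.item_loading, spec.likert_thresholds,
    )
    params = _couple_params(spec, factors.to_numpy(), rng)
    parts = [pd.DataFrame({"participant_id": np.arange(spec.n)}), factors, items, params]
    if spec.covariates:
        parts.append(
            pd.DataFrame(
                {
                    "age": rng.integers(18, 70, size=spec.n),
                    "sex": rng.integers(0, 2, size=spec.n),
                    "iq": rng.normal(100.0, 15.0, size=spec.n).round(1),
                }
            )
        )
    participants = pd.concat(parts, axis=1)
    ground_truth = {
        "model": spec.model,
        "couplings": {k: {"factor": int(f), "slope": float(s)} for k, (f, s) in spec.couplings.items()},
        "loading_matrix": lam.tolist(),
        "factor_corr": np.asarray(spec.factor_corr).tolist(),
        "param_base": {**_BASE_PARAMS[spec.model], **spec.param_base},
        "param_noise": spec.param_noise,
        "seed": spec.seed,
    }
    return participants, ground_truth


def generate_study_behavior(
    participants: pd.DataFrame,
    task: str,
    model: str,
    seed: int,
    n_trials: int = 200,
    **kwargs,
) -> pd.DataFrame:
    """Simulate full trial logs for a cohort whose rows carry the model's
    parameters (columns named as in the model's parameter list)."""
    rng = np.random.default_rng(seed)
    if task in ("twostep", "multigoal"):
        m = agents.get_model(model)
        if m.task != task:
            raise ValueError(f"model {model!r} does not play task {task!r}")
        missing = [n for n in m.param_names if n not in participants.columns]
        if missing:
            raise ValueError(f"participants table missing parameters: {missing}")
        theta = participants[m.param_names].to_numpy()
        log = m.simulate(theta, n_trials, rng, **kwargs)
        ids = participants["participant_id"].to_numpy()
        log["participant_id"] = ids[log["participant_id"].to_numpy()]
        return log
    if task == "one_step":
        return generate_study1_correctness(participants, seed=seed, **kwargs)[0]
    raise ValueError(f"unknown task {task!r}")


def generate_study1_correctness(
    participants: pd.DataFrame,
    effects: dict | None = None,
    baseline_correct: float = 0.6,
    sigma_participant: float = 0.5,
    sigma_condition: float = 0.2,
    conditions=ONE_STEP_CONDITIONS,
    seed: int = 0,
):
    """Per-(participant, block) correctness from a logistic ground truth.

    log-odds of a fully-correct block = logit(``baseline_correct``) +
    participant effect + condition effect + sum of planted trait effects
    (``effects`` maps trait column -> log-odds slope per standardized unit;
    default plants -0.33 on f3).  Returns (data, ground_truth); ``data`` is
    ready for the hierarchical logistic regression.
    """
    if effects is None:
        effects = {"f3": -0.33}
    rng = np.random.default_rng(seed)
    n = len(participants)
    u = rng.normal(0.0, sigma_participant, size=n)
    c = rng.normal(0.0, sigma_condition, size=len(conditions))
    rows = []
    base = logit(baseline_correct)
    trait_term = np.zeros(n)
    for col, slope in effects.items():
        x = participants[col].to_numpy().astype(float)
        trait_term += slope * (x - x.mean()) / x.std(ddof=0)
    for b, cond in enumerate(conditions):
        eta = base + u + c[b] + trait_term
        correct = (rng.random(n) < expit(eta)).astype(int)
        block = pd.DataFrame(
            {
                "participant_id": participants["participant_id"].to_numpy(),
                "condition": cond,
                "block": b,
                "correct": correct,
            }
        )
        for col in effects:
            block[col] = participants[col].to_numpy()
        rows.append(block)
    data = pd.concat(rows, ignore_index=True)
    # carry all trait columns present for downstream regression
    for col in ("f1", "f2", "f3"):
        if col in participants.columns and col not in data.columns:
            data[col] = np.tile(participants[col].to_numpy(), len(conditions))
    ground_truth = {
        "effects": effects,
        "baseline_correct": baseline_correct,
        "sigma_participant": sigma_participant,
        "sigma_condition": sigma_condition,
        "participant_effects": u.tolist(),
        "condition_effects": c.tolist(),
        "seed": seed,
    }
    return data, ground_truth


def generate_mediation_cohort(n: int, chain: str = "full", seed: int = 0) -> pd.DataFrame:
    """Cohort with a planted causal structure for the mediation test.

    chain='full': trait depends only on beta_mb, and beta_mb depends on
    gamma (trait <- beta_mb <- gamma), so the gamma-trait relation should be
    fully mediated.  chain='direct': trait depends directly on gamma and
    beta_mb is independent, so no mediation should be declared.  Columns:
    gamma, beta_mb, trait (parameters positive, suitable for log transform).
    """
    rng = np.random.default_rng(seed)
    lg = rng.normal(-0.8, 0.8, size=n)  # logit-scale gamma
    gamma = expit(lg)
    if chain == "full":
        log_b = 1.0 - 0.7 * (lg - lg.mean()) / lg.std(ddof=0) + rng.normal(0.0, 0.35, size=n)
        zb = (log_b - log_b.mean()) / log_b.std(ddof=0)
        trait = -0.6 * zb + rng.normal(0.0, 0.7, size=n)
    elif chain == "direct":
        log_b = rng.normal(1.0, 0.5, size=n)
        zg = (lg - lg.mean()) / lg.std(ddof=0)
        trait = 0.4 * zg + rng.normal(0.0, 0.8, size=n)
    else:
        raise ValueError("chain must be 'full' or 'direct'")
    return pd.DataFrame({"gamma": gamma, "beta_mb": np.exp(log_b), "trait": trait})
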