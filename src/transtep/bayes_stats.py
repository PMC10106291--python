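"""Inferential engine for the one-step revaluation study.

Covers: scoring of revaluation test blocks; hierarchical Bayesian logistic
regression of block correctness on a grand-mean intercept, participant and
condition random effects, and fixed trait-factor effects, sampled by HMC;
sum-to-zero rescaling of categorical effects; ROPE/HDI hypothesis decisions;
and exploratory factor analysis (maximum-likelihood extraction, promax
rotation, regression factor scores, KMO/Bartlett adequacy, parallel
analysis).

Priors follow the design: intercept Normal(0.6, 1); fixed trait effects
Normal(0, 3); random-effect standard deviations Uniform(0, 3) (sampled on an
unconstrained scale with the appropriate Jacobian, random effects
non-centered).  An effect is deemed credible ("significant") when its 95%
highest-density interval lies wholly outside the region of practical
equivalence, by default 0 +/- 0.01 (10% of the baseline-effect posterior
s.d.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit, log_expit
from sklearn.decomposition import FactorAnalysis

from ._hmc import HMCConfig, sample_hmc

__all__ = [
    "LogisticModelSpec",
    "PosteriorSummary",
    "fit_hierarchical_logistic",
    "sum_to_zero_rescale",
    "hdi",
    "rope_decision",
    "EFAResult",
    "fit_efa",
    "parallel_analysis",
    "score_revaluation_blocks",
    "chance_correct_blocks",
    "chance_correct_blocks_mc",
]


# ---------------------------------------------------------------------------
# hierarchical logistic regression

@dataclass(frozen=True)
class LogisticModelSpec:
    """Design and priors for the block-correctness regression."""

    trait_cols: tuple = ("f1", "f2", "f3")
    intercept_prior_mean: float = 0.6
    intercept_prior_sd: float = 1.0
    fixed_effect_sd: float = 3.0
    sd_upper: float = 3.0  # Uniform(0, sd_upper) hyperprior on random-effect sds
    rope_halfwidth: float = 0.01


class _HierLogisticTarget:
    """Unconstrained posterior target with analytic gradients.

    Parameter vector: [mu, beta (k), z_participant (P), z_condition (C),
    t_u, t_c] with sigma = sd_upper * sigmoid(t) and non-centered random
    effects u = sigma_u * z.
    """

    def __init__(self, y, pidx, cidx, X, spec: LogisticModelSpec):
        self.y = y.astype(float)
        self.pidx = pidx
        self.cidx = cidx
        self.X = X
        self.spec = spec
        self.P = int(pidx.max()) + 1
        self.C = int(cidx.max()) + 1
        self.k = X.shape[1]
        self.ndim = 1 + self.k + self.P + self.C + 2

    def unpack(self, q):
        k, P, C = self.k, self.P, self.C
        mu = q[0]
        beta = q[1 : 1 + k]
        z_u = q[1 + k : 1 + k + P]
        z_c = q[1 + k + P : 1 + k + P + C]
        t_u, t_c = q[-2], q[-1]
        return mu, beta, z_u, z_c, t_u, t_c

    def __call__(self, q):
        sp = self.spec
        mu, beta, z_u, z_c, t_u, t_c = self.unpack(q)
        # clip the sigmoid away from 0/1 so the Jacobian log stays finite
        s_u = np.clip(expit(t_u), 1e-12, 1 - 1e-12)
        s_c = np.clip(expit(t_c), 1e-12, 1 - 1e-12)
        sig_u, sig_c = sp.sd_upper * s_u, sp.sd_upper * s_c
        eta = mu + sig_u * z_u[self.pidx] + sig_c * z_c[self.cidx] + self.X @ beta
        # Bernoulli log-lik: y*eta - log(1 + e^eta), with log(1-p) = log_expit(-eta)
        ll = np.sum(self.y * eta + log_expit(-eta))
        lp = (
            ll
            - 0.5 * (mu - sp.intercept_prior_mean) ** 2 / sp.intercept_prior_sd**2
            - 0.5 * np.sum(beta**2) / sp.fixed_effect_sd**2
            - 0.5 * np.sum(z_u**2)
            - 0.5 * np.sum(z_c**2)
            # Uniform(0, upper) on sigma via logit transform: Jacobian terms
            + np.log(s_u) + np.log1p(-s_u)
            + np.log(s_c) + np.log1p(-s_c)
        )
        p = expit(eta)
        resid = self.y - p
        g = np.empty_like(q)
        g[0] = resid.sum() - (mu - sp.intercept_prior_mean) / sp.intercept_prior_sd**2
        g[1 : 1 + self.k] = self.X.T @ resid - beta / sp.fixed_effect_sd**2
        ru = np.bincount(self.pidx, weights=resid, minlength=self.P)
        rc = np.bincount(self.cidx, weights=resid, minlength=self.C)
        g[1 + self.k : 1 + self.k + self.P] = sig_u * ru - z_u
        g[1 + self.k + self.P : 1 + self.k + self.P + self.C] = sig_c * rc - z_c
        dsig_u = np.dot(ru, z_u)
        dsig_c = np.dot(rc, z_c)
        g[-2] = dsig_u * sp.sd_upper * s_u * (1 - s_u) + (1 - 2 * s_u)
        g[-1] = dsig_c * sp.sd_upper * s_c * (1 - s_c) + (1 - 2 * s_c)
        return lp, g


def hdi(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(samples).ravel())
    n = x.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def rope_decision(posterior_samples, rope_halfwidth: float, prob: float = 0.95) -> str:
    """'significant' if the HDI and [-rope, +rope] are disjoint,
    'not-significant' if the HDI lies inside the ROPE, else 'undecided'."""
    x = np.asarray(posterior_samples).ravel()
    if x.size == 0:
        raise ValueError("empty posterior sample")
    lo, hi = hdi(x, prob)
    r = abs(rope_halfwidth)
    if hi < -r or lo > r:
        return "significant"
    if -r <= lo and hi <= r:
        return "not-significant"
    return "undecided"


def sum_to_zero_rescale(samples: dict, categorical_groups) -> dict:
    """Enforce a sum-to-zero constraint on each categorical family per draw.

    Each group's coefficients have their mean removed; the removed means are
    added to ``intercept``, leaving every linear predictor unchanged.
    """
    out = {k: np.array(v, copy=True) for k, v in samples.items()}
    intercept = out["intercept"]
    for grp in categorical_groups:
        coefs = out[grp]
        mean = coefs.mean(axis=-1)
        out[grp] = coefs - mean[..., None]
        intercept = intercept + mean
    out["intercept"] = intercept
    return out


def _mode(x: np.ndarray) -> float:
    """Posterior mode via a Gaussian KDE on a grid."""
    x = np.asarray(x).ravel()
    if np.ptp(x) < 1e-12:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 256)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class PosteriorSummary:
    """Posterior draws, per-parameter summaries, diagnostics, and ROPE
    decisions from the hierarchical logistic regression."""

    samples: dict  # name -> (chains, draws) or (chains, draws, levels)
    summary: pd.DataFrame  # mode, hdi_low, hdi_high, rhat, ess, decision
    rope_halfwidth: float
    diagnostics: dict
    flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def fit_hierarchical_logistic(
    data: pd.DataFrame,
    spec: LogisticModelSpec | None = None,
    sampler_config: HMCConfig | None = None,
) -> PosteriorSummary:
    """Fit the block-correctness regression by HMC.

    ``data`` has one row per (participant, block): columns ``correct`` (0/1),
    ``participant_id``, ``condition``, and the trait columns named in the
    spec.  Categorical effects are sum-to-zero rescaled before
    summarization.  Convergence problems (r-hat >= 1.1, ESS < 1000,
    divergences) are flagged on the result, never silently dropped.
    """
    spec = spec or LogisticModelSpec()
    cfg = sampler_config or HMCConfig()
    y = data["correct"].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome 'correct' must be binary")
    pids, pidx = np.unique(data["participant_id"].to_numpy(), return_inverse=True)
    conds, cidx = np.unique(data["condition"].to_numpy(), return_inverse=True)
    X = data[list(spec.trait_cols)].to_numpy().astype(float)
    target = _HierLogisticTarget(y, pidx, cidx, X, spec)
    init = np.zeros(target.ndim)
    init[0] = spec.intercept_prior_mean
    draws, infos = sample_hmc(target, init, cfg)
    k, P, C = target.k, target.P, target.C
    s = spec.sd_upper
    sig_u = s * expit(draws[..., -2])
    sig_c = s * expit(draws[..., -1])
    samples = {
        "intercept": draws[..., 0],
        **{t: draws[..., 1 + j] for j, t in enumerate(spec.trait_cols)},
        "participant": sig_u[..., None] * draws[..., 1 + k : 1 + k + P],
        "condition": sig_c[..., None] * draws[..., 1 + k + P : 1 + k + P + C],
        "sigma_participant": sig_u,
        "sigma_condition": sig_c,
    }
    samples = sum_to_zero_rescale(samples, ["participant", "condition"])
    report = ["intercept", *spec.trait_cols, "sigma_participant", "sigma_condition"]
    rows = {}
    azd = {}
    for name in report:
        azd[name] = samples[name]
    for j, cond in enumerate(conds):
        azd[f"condition[{cond}]"] = samples["condition"][..., j]
    idata = az.from_dict(posterior=azd)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    for name in azd:
        x = azd[name]
        lo, hi = hdi(x)
        decision = (
            rope_decision(x, spec.rope_halfwidth)
            if name in spec.trait_cols or name.startswith("condition[")
            else ""
        )
        rows[name] = {
            "mode": _mode(x),
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": float(rhat[name].values),
            "ess": float(ess[name].values),
            "decision": decision,
        }
    summary = pd.DataFrame(rows).T
    flags = []
    n_div = sum(i["divergences"] for i in infos)
    if n_div > 0:
        flags.append(f"{n_div} divergent transitions")
    bad_rhat = summary[summary["rhat"].astype(float) >= 1.1]
    if len(bad_rhat):
        flags.append(f"r-hat >= 1.1 for {list(bad_rhat.index)}")
    bad_ess = summary[summary["ess"].astype(float) < 1000]
    if len(bad_ess):
        flags.append(f"effective sample size < 1000 for {list(bad_ess.index)}")
    for f in flags:
        warnings.warn(f)
    return PosteriorSummary(
        samples=samples,
        summary=summary,
        rope_halfwidth=spec.rope_halfwidth,
        diagnostics={
            "divergences": n_div,
            "accept_rate": float(np.mean([i["accept_rate"] for i in infos])),
            "participants": pids,
            "conditions": conds,
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# exploratory factor analysis

def _promax(varimax_loadings: np.ndarray, power: int = 4):
    """Promax rotation of varimax loadings.

    Returns (pattern matrix, factor correlation matrix).  The oblique target
    is the element-wise signed ``power`` of the varimax solution; the
    transform is its least-squares fit, column-normalized so factors have
    unit variance.
    """
    L = varimax_loadings
    Q = L * np.abs(L) ** (power - 1)
    U = np.linalg.solve(L.T @ L, L.T @ Q)
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d
    pattern = L @ U
    phi = np.linalg.inv(U.T @ U)
    # guard against round-off off the unit diagonal
    sd = np.sqrt(np.diag(phi))
    phi = phi / np.outer(sd, sd)
    return pattern, phi


def _smooth_correlation(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-8:
        return R
    warnings.warn("correlation matrix not positive definite; smoothing eigenvalues")
    w = np.clip(w, 1e-6, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


@dataclass
class EFAResult:
    loadings: pd.DataFrame  # pattern matrix, items x factors
    phi: np.ndarray  # factor correlations
    scores: pd.DataFrame  # regression-method factor scores
    eigenvalues: np.ndarray  # of the item correlation matrix
    bartlett: tuple  # (chi2, p)
    kmo: float


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, float]:
    p = R.shape[0]
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.linalg.slogdet(R)[1]
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


def kmo_adequacy(R: np.ndarray) -> float:
    Rinv = linalg.inv(R)
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    a2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + a2))


def fit_efa(items: pd.DataFrame, n_factors: int, rotation: str = "promax") -> EFAResult:
    """Maximum-likelihood factor analysis with promax (or varimax) rotation.

    Items are standardized; extraction is ML; promax allows correlated
    factors; factor scores use the regression method.  Reports Bartlett's
    sphericity test and the KMO sampling-adequacy index.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if items.isna().any().any():
        raise ValueError("item matrix must be complete")
    Z = items.apply(lambda c: (c - c.mean()) / c.std(ddof=0)).to_numpy()
    n = Z.shape[0]
    R = _smooth_correlation(np.corrcoef(Z, rowvar=False))
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    fa = FactorAnalysis(
        n_components=n_factors,
        rotation="varimax" if rotation in ("varimax", "promax") else None,
        svd_method="lapack",
    )
    fa.fit(Z)
    L = fa.components_.T  # varimax-rotated loadings (items x factors)
    if rotation == "promax" and n_factors > 1:
        pattern, phi = _promax(L)
    else:
        pattern, phi = L, np.eye(n_factors)
    structure = pattern @ phi
    weights = linalg.solve(R, structure, assume_a="pos")
    scores = Z @ weights
    fac = [f"f{i + 1}" for i in range(n_factors)]
    return EFAResult(
        loadings=pd.DataFrame(pattern, index=items.columns, columns=fac),
        phi=phi,
        scores=pd.DataFrame(scores, index=items.index, columns=fac),
        eigenvalues=eig,
        bartlett=bartlett_sphericity(R, n),
        kmo=kmo_adequacy(R),
    )


def parallel_analysis(
    items: pd.DataFrame, n_sims: int = 200, seed: int = 0, quantile: float = 95.0
) -> int:
    """Suggested factor count: leading observed eigenvalues of the item
    correlation matrix exceeding the ``quantile`` percentile of eigenvalues
    from simulated uncorrelated data of the same shape."""
    Z = items.to_numpy().astype(float)
    n, p = Z.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_sims, p))
    for i in range(n_sims):
        sim = rng.normal(size=(n, p))
        null[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
    thresh = np.percentile(null, quantile, axis=0)
    count = 0
    for o, t in zip(obs, thresh):
        if o > t:
            count += 1
        else:
            break
    return count


# ---------------------------------------------------------------------------
# revaluation-test scoring

def chance_correct_blocks(n_blocks: int = 5, n_scored_queries: int = 2) -> float:
    """Expected number of fully-correct blocks for a uniformly random
    responder (each scored query is a binary choice)."""
    return n_blocks * 0.5**n_scored_queries


def chance_correct_blocks_mc(
    n_responders: int,
    rng: np.random.Generator,
    n_blocks: int = 5,
    n_scored_queries: int = 2,
) -> float:
    """Monte-Carlo estimate of :func:`chance_correct_blocks` from simulated
    random responders."""
    correct = rng.random((n_responders, n_blocks, n_scored_queries)) < 0.5
    return float(correct.all(axis=2).sum(axis=1).mean())


def score_revaluation_blocks(test_choices: pd.DataFrame, schedules) -> tuple[pd.Series, float]:
    """Count, per participant, blocks where both scored test queries were
    answered with the schedule's optimal action.

    ``test_choices`` has one row per (participant_id, block, query_state)
    with the chosen ``action``; ``schedules`` is one schedule per block.
    The rare-state query carries no optimal action and is ignored.  A
    missing scored response fails the block (with a warning).  Returns
    (counts out of len(schedules), chance expectation).
    """
    n_blocks = len(schedules)
    counts = {}
    for pid, g in test_choices.groupby("participant_id"):
        n_correct = 0
        for b, sched in enumerate(schedules):
            ok = True
            for q in sched.queries:
                if not q["scored"]:
                    continue
                sel = g[(g["block"] == b) & (g["query_state"] == q["query_state"])]
                if sel.empty:
                    warnings.warn(
                        f"participant {pid} block {b}: missing scored query "
                        f"{q['query_state']}; block marked incorrect"
                    )
                    ok = False
                elif int(sel["action"].iloc[0]) != q["optimal_action"]:
                    ok = False
            n_correct += ok
        counts[pid] = n_correct
    n_scored = sum(q["scored"] for q in schedules[0].queries) if n_blocks else 2
    return (
        pd.Series(counts, name="n_correct_blocks"),
        chance_correct_blocks(n_blocks, n_scored),
    )
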