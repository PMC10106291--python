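"""Bayesian inference utilities: HDI/ROPE logic, sum-to-zero rescaling,
the hierarchical logistic sampler, EFA, parallel analysis, and revaluation
scoring."""

import numpy as np
import pandas as pd
import pytest

from transtep import bayes_stats, synthetic_data, tasks
from transtep._hmc import HMCConfig


class TestHdiRope:
    def test_hdi_of_normal_matches_central_interval(self, rng):
        x = rng.normal(0.0, 1.0, 40000)
        lo, hi = bayes_stats.hdi(x)
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    @pytest.mark.parametrize(
        "interval,expected",
        [((-0.58, -0.05), "significant"),
         ((-0.005, 0.008), "not-significant"),
         ((-0.02, 0.02), "undecided")],
    )
    def test_rope_decisions(self, interval, expected, rng):
        # uniform draws over the interval have that interval as their HDI
        x = rng.uniform(*interval, 20000)
        assert bayes_stats.rope_decision(x, 0.01) == expected

    def test_widening_rope_never_creates_significance(self, rng):
        order = {"significant": 2, "undecided": 1, "not-significant": 0}
        for loc in (-0.3, -0.02, 0.0, 0.05):
            x = rng.normal(loc, 0.1, 4000)
            decisions = [order[bayes_stats.rope_decision(x, r)] for r in (0.005, 0.05, 0.5)]
            assert decisions == sorted(decisions, reverse=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bayes_stats.rope_decision(np.array([]), 0.01)


class TestSumToZero:
    def test_mean_moves_to_intercept(self):
        s = {"intercept": np.array([1.0]), "cond": np.array([[1.0, 2.0, 3.0]])}
        out = bayes_stats.sum_to_zero_rescale(s, ["cond"])
        assert np.allclose(out["cond"], [-1.0, 0.0, 1.0])
        assert out["intercept"][0] == pytest.approx(3.0)

    def test_linear_predictor_unchanged_per_draw(self, rng):
        draws = 50
        s = {"intercept": rng.normal(size=draws), "g": rng.normal(size=(draws, 4))}
        out = bayes_stats.sum_to_zero_rescale(s, ["g"])
        for level in range(4):
            before = s["intercept"] + s["g"][:, level]
            after = out["intercept"] + out["g"][:, level]
            assert np.allclose(before, after, atol=1e-12)

    def test_idempotent_on_centered_coefficients(self, rng):
        g = rng.normal(size=(30, 5))
        g -= g.mean(axis=1, keepdims=True)
        s = {"intercept": rng.normal(size=30), "g": g}
        out = bayes_stats.sum_to_zero_rescale(s, ["g"])
        assert np.allclose(out["g"], g)
        assert np.allclose(out["intercept"], s["intercept"])


class TestHierarchicalLogistic:
    def test_posterior_gradient_matches_finite_differences(self, rng):
        from transtep.bayes_stats import LogisticModelSpec, _HierLogisticTarget

        n, P, C, k = 60, 12, 3, 3
        pidx = rng.integers(0, P, n)
        cidx = rng.integers(0, C, n)
        X = rng.normal(size=(n, k))
        y = rng.integers(0, 2, n).astype(float)
        target = _HierLogisticTarget(y, pidx, cidx, X, LogisticModelSpec())
        q = 0.3 * rng.normal(size=target.ndim)
        lp, grad = target(q)
        eps = 1e-6
        for j in range(target.ndim):
            dq = np.zeros_like(q)
            dq[j] = eps
            num = (target(q + dq)[0] - target(q - dq)[0]) / (2 * eps)
            assert num == pytest.approx(grad[j], rel=1e-4, abs=1e-6)

    def test_intercept_only_recovers_base_rate(self):
        rng = np.random.default_rng(3)
        n, blocks = 120, 5
        data = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(n), blocks),
                "condition": np.tile([f"c{b}" for b in range(blocks)], n),
                "correct": (rng.random(n * blocks) < 0.6).astype(int),
                "f1": np.repeat(rng.normal(size=n), blocks),
                "f2": np.repeat(rng.normal(size=n), blocks),
                "f3": np.repeat(rng.normal(size=n), blocks),
            }
        )
        post = bayes_stats.fit_hierarchical_logistic(
            data, sampler_config=HMCConfig(n_warmup=300, n_draws=300, n_chains=2, seed=1)
        )
        from scipy.special import logit

        intercept = post.samples["intercept"].mean()
        assert intercept == pytest.approx(logit(0.6), abs=0.2)
        # null trait effects should not be declared credible
        for t in ("f1", "f2", "f3"):
            assert post.summary.loc[t, "decision"] != "significant"

    def test_nonbinary_outcome_rejected(self):
        df = pd.DataFrame({"participant_id": [0], "condition": ["a"], "correct": [2],
                           "f1": [0.0], "f2": [0.0], "f3": [0.0]})
        with pytest.raises(ValueError):
            bayes_stats.fit_hierarchical_logistic(df)


def _congruence(a, b):
    return abs(a @ b) / np.sqrt((a @ a) * (b @ b))


class TestEFA:
    def test_planted_three_factor_structure_recovered(self):
        rng = np.random.default_rng(5)
        items, factors, lam = synthetic_data.generate_questionnaire(1000, rng)
        res = bayes_stats.fit_efa(items, 3)
        # match each planted factor to its best-congruent estimated factor
        used = set()
        for j in range(3):
            cs = [(_congruence(lam[:, j], res.loadings.iloc[:, k].to_numpy()), k)
                  for k in range(3) if k not in used]
            c, k = max(cs)
            used.add(k)
            assert c >= 0.9

    def test_orthogonal_factors_give_near_zero_phi(self):
        rng = np.random.default_rng(6)
        items, _, _ = synthetic_data.generate_questionnaire(1500, rng, factor_corr=np.eye(3))
        res = bayes_stats.fit_efa(items, 3)
        off = res.phi[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_single_factor_loadings_proportional(self):
        rng = np.random.default_rng(7)
        lam = np.linspace(0.35, 0.85, 12)
        f = rng.normal(size=(800, 1))
        items = pd.DataFrame(
            f @ lam[None, :] + rng.normal(0, np.sqrt(1 - lam**2), size=(800, 12)),
            columns=[f"item_{i}" for i in range(12)],
        )
        res = bayes_stats.fit_efa(items, 1, rotation=None)
        r = np.corrcoef(lam, res.loadings.iloc[:, 0])[0, 1]
        assert abs(r) >= 0.95

    def test_adequacy_statistics_reported(self):
        rng = np.random.default_rng(8)
        items, _, _ = synthetic_data.generate_questionnaire(600, rng)
        res = bayes_stats.fit_efa(items, 3)
        chi2, p = res.bartlett
        assert chi2 > 0 and p < 0.001
        assert 0 < res.kmo < 1

    def test_incomplete_items_rejected(self):
        items = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            bayes_stats.fit_efa(items, 1)


class TestParallelAnalysis:
    def test_planted_three_factors_detected(self):
        rng = np.random.default_rng(9)
        items, _, _ = synthetic_data.generate_questionnaire(1000, rng)
        assert bayes_stats.parallel_analysis(items, n_sims=100, seed=0) == 3

    def test_pure_noise_yields_at_most_one(self):
        rng = np.random.default_rng(10)
        items = pd.DataFrame(rng.normal(size=(500, 20)))
        assert bayes_stats.parallel_analysis(items, n_sims=100, seed=0) <= 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        items, _, _ = synthetic_data.generate_questionnaire(300, rng)
        a = bayes_stats.parallel_analysis(items, n_sims=50, seed=5)
        b = bayes_stats.parallel_analysis(items, n_sims=50, seed=5)
        assert a == b


class TestRevaluationScoring:
    def _choices(self, mapping):
        rows = []
        for b in range(5):
            for q, a in mapping(b):
                rows.append({"participant_id": 0, "block": b, "query_state": q, "action": a})
        return pd.DataFrame(rows)

    def test_perfect_responder_scores_five(self):
        scheds = tasks.default_one_step_blocks()
        choices = self._choices(lambda b: [(0, 1), (1, 0), (2, 0)])
        counts, chance = bayes_stats.score_revaluation_blocks(choices, scheds)
        assert counts.iloc[0] == 5
        assert chance == 1.25

    def test_one_correct_query_per_block_scores_zero(self):
        scheds = tasks.default_one_step_blocks()
        choices = self._choices(lambda b: [(0, 1), (1, 1), (2, 1)])  # state-1 query wrong
        counts, _ = bayes_stats.score_revaluation_blocks(choices, scheds)
        assert counts.iloc[0] == 0

    def test_rare_query_ignored(self):
        scheds = tasks.default_one_step_blocks()
        # rare-state answer differs but scored queries are right
        choices = self._choices(lambda b: [(0, 1), (1, 0), (2, b % 2)])
        counts, _ = bayes_stats.score_revaluation_blocks(choices, scheds)
        assert counts.iloc[0] == 5

    def test_missing_scored_query_fails_block_with_warning(self):
        scheds = tasks.default_one_step_blocks()
        choices = self._choices(lambda b: [(0, 1)] if b == 0 else [(0, 1), (1, 0)])
        with pytest.warns(UserWarning, match="missing scored query"):
            counts, _ = bayes_stats.score_revaluation_blocks(choices, scheds)
        assert counts.iloc[0] == 4

    def test_monte_carlo_matches_closed_form(self, rng):
        mc = bayes_stats.chance_correct_blocks_mc(100_000, rng)
        assert mc == pytest.approx(bayes_stats.chance_correct_blocks(), abs=0.01)
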