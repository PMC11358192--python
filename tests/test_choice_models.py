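"""Trial covariates, logistic likelihood, model fitting, Savage-Dickey model
comparison, and prediction curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import logsumexp

from knowjudge import (
    InvalidInputError,
    PriorSpec,
    SamplerConfig,
    TrialFeatures,
    WeightVector,
    build_features,
    compare_models,
    false_statement_flip_theta,
    false_statement_net_effect,
    fit_model,
    logistic,
    loglik,
    predict_curves,
)
from knowjudge.choice_models import design_matrix
from knowjudge.knowledge import KnowledgeProfile


def simulate_features(seed, w_true, n_trials, theta_lo=0.3, theta_hi=1.0):
    """Trials drawn from the evaluator choice model itself."""
    rng = np.random.default_rng(seed)
    dn = rng.poisson(2, n_trials) - rng.poisson(2, n_trials)
    dm = rng.poisson(0.6, n_trials) - rng.poisson(0.6, n_trials)
    theta = rng.uniform(theta_lo, theta_hi, n_trials)
    eta = w_true[0] + w_true[1] * dn + w_true[2] * theta * dm
    y = (rng.random(n_trials) < logistic(eta)).astype(int)
    return [TrialFeatures(str(i), int(dn[i]), int(dm[i]), float(theta[i]), 1,
                          int(y[i])) for i in range(n_trials)]


class TestLogistic:
    def test_midpoint(self):
        assert logistic(0.0) == pytest.approx(0.5)

    def test_value_at_one(self):
        assert logistic(1.0) == pytest.approx(0.7310585786, abs=1e-5)

    def test_complementarity(self):
        for x in (-3.0, 0.7, 12.0):
            assert logistic(x) + logistic(-x) == pytest.approx(1.0)

    def test_stable_at_extremes(self):
        assert logistic(700.0) == pytest.approx(1.0)
        assert logistic(-700.0) == pytest.approx(0.0)


def _profile(pid, cat, theta, n_q=10, selection="assigned"):
    k = round(theta * n_q)
    return KnowledgeProfile(pid, cat, tuple([1] * k + [0] * (n_q - k)), selection)


def _toy_tables():
    aggregated = pd.DataFrame([
        # informant, category, image, n_specific_mode, n_false_mode
        ("iA", "c1", "im1", 2, 1), ("iA", "c1", "im2", 1, 0),
        ("iB", "c1", "im1", 1, 1), ("iB", "c1", "im2", 0, 0),
    ], columns=["informant_id", "category_id", "image_id",
                "n_specific_mode", "n_false_mode"])
    trials = pd.DataFrame([
        ("t1", "e1", "c1", "iA", "iB", "im1;im2", 2, "A"),
    ], columns=["trial_id", "evaluator_id", "category_id", "informant_A",
                "informant_B", "image_ids", "n_descriptions", "choice"])
    profiles = {
        ("iA", "c1"): _profile("iA", "c1", 0.9),
        ("iB", "c1"): _profile("iB", "c1", 0.5),
        ("e1", "c1"): _profile("e1", "c1", 0.7),
    }
    return trials, aggregated, profiles


class TestBuildFeatures:
    def test_hand_summed_differences(self):
        trials, aggregated, profiles = _toy_tables()
        (f,) = build_features(trials, aggregated, profiles, "evaluator")
        assert (f.dn, f.dm) == (2, 0)
        assert f.theta == pytest.approx(0.7)
        assert f.outcome == 1  # evaluator chose A

    def test_informant_model_uses_ground_truth(self):
        trials, aggregated, profiles = _toy_tables()
        trials.loc[0, "choice"] = "B"
        (f,) = build_features(trials, aggregated, profiles, "informant")
        assert f.outcome == 1  # A has the higher accuracy regardless of choice
        assert f.theta == 1.0

    def test_identical_counts_give_zero_differences(self):
        trials, aggregated, profiles = _toy_tables()
        aggregated.loc[aggregated.informant_id == "iB",
                       ["n_specific_mode", "n_false_mode"]] = \
            aggregated.loc[aggregated.informant_id == "iA",
                           ["n_specific_mode", "n_false_mode"]].to_numpy()
        (f,) = build_features(trials, aggregated, profiles, "evaluator")
        assert (f.dn, f.dm) == (0, 0)

    def test_equal_accuracy_pair_rejected(self):
        trials, aggregated, profiles = _toy_tables()
        profiles[("iB", "c1")] = _profile("iB", "c1", 0.9)
        with pytest.raises(InvalidInputError):
            build_features(trials, aggregated, profiles, "informant")

    def test_missing_annotation_names_trial(self):
        trials, aggregated, profiles = _toy_tables()
        with pytest.raises(InvalidInputError, match="t1"):
            build_features(trials, aggregated.iloc[:-1], profiles, "evaluator")

    def test_missing_evaluator_theta_rejected(self):
        trials, aggregated, profiles = _toy_tables()
        del profiles[("e1", "c1")]
        with pytest.raises(InvalidInputError, match="e1"):
            build_features(trials, aggregated, profiles, "evaluator")


class TestLoglik:
    def test_all_zero_weights(self):
        feats = simulate_features(0, (0, 0.3, -0.3), 40)
        ll = loglik("evaluator", WeightVector(0, 0, 0), feats)
        assert ll == pytest.approx(40 * np.log(0.5))

    def test_single_trial_hand_computation(self):
        f = TrialFeatures("t", 2, 1, 0.5, 1, 1)
        ll = loglik("evaluator", WeightVector(0.0, 0.32, -0.36), [f])
        assert ll == pytest.approx(np.log(logistic(0.32 * 2 - 0.36 * 0.5 * 1)))

    def test_gradient_matches_finite_differences(self):
        feats = simulate_features(1, (0.1, 0.25, -0.4), 200)
        X, y = design_matrix(feats, "evaluator")
        w = np.array([0.05, 0.2, -0.1])
        # analytic gradient of the Bernoulli log-likelihood
        grad = X.T @ (y - logistic(X @ w))
        eps = 1e-6
        for j in range(3):
            wp, wm = w.copy(), w.copy()
            wp[j] += eps
            wm[j] -= eps
            fd = (loglik("evaluator", wp, feats)
                  - loglik("evaluator", wm, feats)) / (2 * eps)
            assert fd == pytest.approx(grad[j], abs=1e-4)

    def test_nonfinite_weights_rejected(self):
        feats = simulate_features(2, (0, 0.3, -0.3), 60)
        with pytest.raises(InvalidInputError):
            loglik("evaluator", np.array([np.nan, 0.0, 0.0]), feats)


class TestFitModel:
    def test_recovers_generating_weights(self, fast_sampler):
        w_true = (0.0, 0.32, -0.36)
        feats = simulate_features(3, w_true, 20_000)
        _, summary = fit_model("evaluator", feats, sampler=fast_sampler)
        for nm, tv in zip(("w0", "w1", "w2"), w_true):
            assert summary.mean[nm] == pytest.approx(tv, abs=0.05)

    def test_null_slope_covered_by_ci(self, fast_sampler):
        covered = 0
        for seed in range(8):
            feats = simulate_features(100 + seed, (0.0, 0.0, -0.3), 800)
            cfg = SamplerConfig(n_chains=2, burn_in=200, thin=5,
                                draws_per_chain=100, seed=seed)
            _, summary = fit_model("evaluator", feats, sampler=cfg)
            lo, hi = summary.ci95["w1"]
            covered += lo <= 0.0 <= hi
        assert covered >= 6

    def test_informant_model_positive_specificity_effect(self, small_study,
                                                         fast_sampler):
        from knowjudge import aggregate_table, score_knowledge
        from knowjudge.knowledge import profiles_by_key
        agg = aggregate_table(small_study.annotations)
        profiles = profiles_by_key(score_knowledge(small_study.answers))
        feats = build_features(small_study.trials, agg, profiles, "informant")
        _, summary = fit_model("informant", feats, sampler=fast_sampler)
        assert summary.mean["w1"] > 0

    def test_too_few_trials_rejected(self, fast_sampler):
        feats = simulate_features(4, (0, 0.3, -0.3), 10)
        with pytest.raises(InvalidInputError):
            fit_model("evaluator", feats, sampler=fast_sampler)

    def test_informant_and_evaluator_models_agree_at_theta_one(self):
        """With every theta = 1 the two model parameterisations coincide."""
        feats = simulate_features(5, (0.0, 0.3, -0.3), 4000,
                                  theta_lo=1.0, theta_hi=1.0)
        cfg = SamplerConfig(n_chains=2, burn_in=200, thin=5,
                            draws_per_chain=150, seed=2)
        _, s_inf = fit_model("informant", feats, sampler=cfg)
        _, s_eva = fit_model("evaluator", feats, sampler=cfg)
        for nm in ("w0", "w1", "w2"):
            assert abs(s_inf.mean[nm] - s_eva.mean[nm]) < 0.05

    def test_label_swap_symmetry(self, fast_sampler):
        feats = simulate_features(6, (0.15, 0.3, -0.3), 4000)
        swapped = [TrialFeatures(f.trial_id, -f.dn, -f.dm, f.theta,
                                 f.n_descriptions, 1 - f.outcome)
                   for f in feats]
        _, s1 = fit_model("evaluator", feats, sampler=fast_sampler)
        _, s2 = fit_model("evaluator", swapped, sampler=fast_sampler)
        assert s1.mean["w0"] == pytest.approx(-s2.mean["w0"], abs=0.08)
        assert s1.mean["w1"] == pytest.approx(s2.mean["w1"], abs=0.08)
        assert s1.mean["w2"] == pytest.approx(s2.mean["w2"], abs=0.12)


def importance_sampling_log_marglik(X, y, prior_scale=1.0, n_draws=50_000,
                                    seed=1):
    """Marginal likelihood by importance sampling from an inflated Laplace
    approximation of the posterior."""
    d = X.shape[1]

    def neg_log_post(w):
        eta = X @ w
        sp = np.maximum(eta, 0) + np.log1p(np.exp(-np.abs(eta)))
        return -(y @ eta - sp.sum()
                 + stats.norm.logpdf(w, 0, prior_scale).sum())

    res = optimize.minimize(neg_log_post, np.zeros(d), method="BFGS")
    mode, cov = res.x, res.hess_inv * 1.5
    rng = np.random.default_rng(seed)
    W = rng.multivariate_normal(mode, cov, n_draws)
    eta = X @ W.T
    sp = np.maximum(eta, 0) + np.log1p(np.exp(-np.abs(eta)))
    ll = y @ eta - sp.sum(axis=0)
    lp = stats.norm.logpdf(W, 0, prior_scale).sum(axis=1)
    lq = stats.multivariate_normal.logpdf(W, mode, cov)
    return logsumexp(ll + lp - lq) - np.log(n_draws)


class TestCompareModels:
    def test_strong_effects_reported_above_cap(self, fast_sampler):
        feats = simulate_features(7, (0.0, 0.3, -0.5), 20_000)
        bfs = compare_models("evaluator", feats, sampler=fast_sampler)
        assert bfs["w1"].display == ">100"
        assert bfs["w2"].display == ">100"

    def test_null_veracity_weight_mostly_favored(self):
        favored = 0
        for seed in range(10):
            feats = simulate_features(200 + seed, (0.0, 0.3, 0.0), 800)
            cfg = SamplerConfig(n_chains=2, burn_in=200, thin=5,
                                draws_per_chain=100, seed=seed)
            bfs = compare_models("evaluator", feats, sampler=cfg)
            favored += bfs["w2"].bf10 < 1
        assert favored >= 8

    def test_savage_dickey_close_to_importance_sampling_oracle(self):
        """On a 500-trial instance with moderate evidence, the Savage-Dickey
        BF for the veracity term is within 30% of an importance-sampling
        marginal-likelihood ratio."""
        feats = simulate_features(8, (0.0, 0.25, -0.15), 500)
        X, y = design_matrix(feats, "evaluator")
        lm_full = importance_sampling_log_marglik(X, y)
        lm_reduced = importance_sampling_log_marglik(X[:, :2], y)
        bf_is = np.exp(lm_full - lm_reduced)
        samples, _ = fit_model("evaluator", feats,
                               sampler=SamplerConfig(seed=11))
        bf_sd = compare_models("evaluator", feats, samples=samples)["w2"].bf10
        assert bf_sd == pytest.approx(bf_is, rel=0.3)


class TestPredictCurves:
    def test_zero_weights_flat_at_half(self):
        curves = predict_curves("evaluator", WeightVector(0, 0, 0))
        assert np.allclose(curves["p_mean"], 0.5)

    def test_false_statement_effect_flips_at_crossover(self):
        w = WeightVector(0.0, 0.32, -0.36)
        theta_star = false_statement_flip_theta(w)
        assert theta_star == pytest.approx(0.32 / 0.36, abs=1e-12)
        assert false_statement_net_effect(w, theta_star - 0.01) > 0
        assert false_statement_net_effect(w, theta_star + 0.01) < 0

    def test_low_knowledge_evaluators_helped_by_false_statements(self):
        """At theta = 0.5 with the reported weights, adding false statements
        to A raises P(choose A); at theta = 0.9 it lowers it."""
        w = WeightVector(0.0, 0.32, -0.36)
        curves = predict_curves("evaluator", w, theta_grid=(0.5, 0.9))
        fa = curves[(curves.statement_type == "false") & (curves.side == "A")]
        low = fa[fa.theta == 0.5].sort_values("statements_added")["p_mean"]
        high = fa[fa.theta == 0.9].sort_values("statements_added")["p_mean"]
        assert low.is_monotonic_increasing and low.nunique() > 1
        assert high.is_monotonic_decreasing and high.nunique() > 1

    def test_true_statements_monotone_for_positive_w1(self):
        w = WeightVector(0.1, 0.4, -0.2)
        curves = predict_curves("evaluator", w)
        for theta in curves.theta.unique():
            ta = curves[(curves.statement_type == "true")
                        & (curves.side == "A") & (curves.theta == theta)]
            p = ta.sort_values("statements_added")["p_mean"]
            assert p.is_monotonic_increasing and p.nunique() == len(p)

    def test_bands_from_posterior_draws(self, fast_sampler):
        feats = simulate_features(9, (0.0, 0.3, -0.3), 2000)
        samples, _ = fit_model("evaluator", feats, sampler=fast_sampler)
        curves = predict_curves("evaluator", samples)
        assert (curves["p_lo"] <= curves["p_mean"]).all()
        assert (curves["p_mean"] <= curves["p_hi"]).all()
        wide = curves[curves.statements_added > 0]
        assert (wide["p_hi"] - wide["p_lo"] > 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            predict_curves("evaluator", WeightVector(0, 0.3, -0.3),
                           theta_grid=())
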