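"""Bayesian logistic choice models for pairwise knowledgeability judgments.

Two nested models share the linear predictor structure

    informant discriminability:  p(A truly more knowledgeable)
        = f(w0 + w1 (n_A - n_B) + w2 (m_A - m_B))
    evaluator choice:            p(choose A)
        = f(w0 + w1 (n_A - n_B) + w2 theta (m_A - m_B))

where f is the logistic function, n_X the total number of specific statements
and m_X the total number of false statements informant X produced across the
descriptions shown in the trial, and theta the evaluator's own accuracy in the
trial's category.  The evaluator model tests whether knowledgeable evaluators
discount informants who make false statements; the models coincide when
theta = 1.  Posteriors are drawn by slice sampling under independent zero-mean
normal priors, and per-term Bayes factors use the Savage-Dickey density ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    BayesFactorResult,
    InvalidInputError,
    PosteriorSamples,
    PriorSpec,
    SamplerConfig,
    check_convergence,
    credible_interval,
    savage_dickey_bf,
    slice_sample,
)

TRIAL_COLUMNS = ["trial_id", "evaluator_id", "category_id", "informant_A",
                 "informant_B", "image_ids", "n_descriptions", "choice"]

PARAMETER_NAMES = ["w0", "w1", "w2"]


@dataclass(frozen=True)
class WeightVector:
    """Regression weights: intercept, specificity effect, veracity effect."""

    w0: float
    w1: float
    w2: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.w0, self.w1, self.w2])):
            raise InvalidInputError("weights must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.w0, self.w1, self.w2], dtype=float)


@dataclass(frozen=True)
class TrialFeatures:
    """Model covariates for one pairwise trial."""

    trial_id: str
    dn: int          # n_A - n_B, total specific statements
    dm: int          # m_A - m_B, total false statements
    theta: float     # evaluator accuracy (evaluator model; 1.0 otherwise)
    n_descriptions: int
    outcome: int     # informant model: A truly more knowledgeable; evaluator: chose A


def logistic(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def build_features(trials: pd.DataFrame,
                   aggregated: pd.DataFrame,
                   profiles: Mapping[tuple[str, str], "KnowledgeProfile"],
                   model: str) -> list[TrialFeatures]:
    """Assemble TrialFeatures from the trials table and aggregated annotations.

    ``aggregated`` must carry one row per description with n_specific_mode and
    n_false_mode; dn and dm sum over exactly the images shown in each trial.
    The informant model's outcome is the ground truth (which informant has the
    higher multiple-choice accuracy in the category); the evaluator model's
    outcome is the evaluator's actual choice, and theta is the evaluator's own
    accuracy in the trial's category.
    """
    if model not in ("informant", "evaluator"):
        raise InvalidInputError(f"unknown model {model!r}")
    counts = {
        (str(i), str(c), str(g)): (int(n), int(m))
        for i, c, g, n, m in zip(aggregated["informant_id"],
                                 aggregated["category_id"],
                                 aggregated["image_id"],
                                 aggregated["n_specific_mode"],
                                 aggregated["n_false_mode"])}
    feats = []
    for row in trials.itertuples(index=False):
        images = str(row.image_ids).split(";")
        dn = dm = 0
        for side in ("informant_A", "informant_B"):
            inf = getattr(row, side)
            sign = 1 if side == "informant_A" else -1
            for img in images:
                key = (str(inf), str(row.category_id), img)
                nm = counts.get(key)
                if nm is None:
                    raise InvalidInputError(
                        f"trial {row.trial_id}: no aggregated annotation for "
                        f"informant {inf}, image {img}")
                n, m = nm
                dn += sign * int(n)
                dm += sign * int(m)
        pa = profiles.get((str(row.informant_A), str(row.category_id)))
        pb = profiles.get((str(row.informant_B), str(row.category_id)))
        if pa is None or pb is None:
            raise InvalidInputError(
                f"trial {row.trial_id}: missing knowledge profile for an informant")
        if pa.theta == pb.theta:
            raise InvalidInputError(
                f"trial {row.trial_id}: informants have identical accuracy; "
                f"ground truth undefined")
        if model == "informant":
            theta = 1.0
            outcome = int(pa.theta > pb.theta)
        else:
            pe = profiles.get((str(row.evaluator_id), str(row.category_id)))
            if pe is None:
                raise InvalidInputError(
                    f"trial {row.trial_id}: evaluator {row.evaluator_id} has no "
                    f"knowledge profile in category {row.category_id}")
            theta = pe.theta
            outcome = int(str(row.choice) == "A")
        feats.append(TrialFeatures(str(row.trial_id), dn, dm, theta,
                                   int(row.n_descriptions), outcome))
    return feats


def design_matrix(features: Sequence[TrialFeatures], model: str) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with columns (1, dn, dm) or (1, dn, theta*dm)."""
    dn = np.array([f.dn for f in features], dtype=float)
    dm = np.array([f.dm for f in features], dtype=float)
    y = np.array([f.outcome for f in features], dtype=float)
    if model == "evaluator":
        theta = np.array([f.theta for f in features], dtype=float)
        dm = theta * dm
    X = np.column_stack([np.ones_like(dn), dn, dm])
    return X, y


def loglik(model: str, weights: WeightVector | np.ndarray,
           features: Sequence[TrialFeatures]) -> float:
    """Bernoulli log-likelihood of the trial outcomes under the model."""
    w = weights.as_array() if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("weights must be finite")
    X, y = design_matrix(features, model)
    return _loglik_xy(w, X, y)


def _loglik_xy(w: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ w
    # log p = y*eta - softplus(eta); softplus(x) = max(x,0) + log1p(exp(-|x|))
    softplus = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return float(y @ eta - softplus.sum())


@dataclass
class FitSummary:
    """Posterior means and equal-tailed 95% credible intervals per weight."""

    mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rhat: dict[str, float]


def fit_model(model: str, features: Sequence[TrialFeatures],
              prior: PriorSpec | None = None,
              sampler: SamplerConfig | None = None,
              min_trials: int = 50) -> tuple[PosteriorSamples, FitSummary]:
    """Posterior over (w0, w1, w2) by slice sampling log prior + log likelihood."""
    if len(features) < min_trials:
        raise InvalidInputError(
            f"need at least {min_trials} trials, got {len(features)}")
    prior = prior or PriorSpec("normal", 1.0)
    sampler = sampler or SamplerConfig()
    X, y = design_matrix(features, model)
    inv2s2 = 0.5 / prior.scale ** 2
    log_norm = 3 * (-0.5 * np.log(2 * np.pi) - np.log(prior.scale))
    Xty = X.T @ y  # sufficient statistic for the linear term

    def log_post(w: np.ndarray) -> float:
        eta = X @ w
        softplus = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
        return (float(Xty @ w) - float(softplus.sum())
                + log_norm - inv2s2 * float(w @ w))

    samples = slice_sample(log_post, np.zeros(3), sampler,
                           parameter_names=list(PARAMETER_NAMES))
    rhat, ok = check_convergence(samples)
    if not ok:
        raise RuntimeError(
            f"sampler did not converge: R-hat = "
            f"{dict(zip(PARAMETER_NAMES, np.round(rhat, 4)))}")
    summary = FitSummary(
        mean={nm: float(samples.pooled(nm).mean()) for nm in PARAMETER_NAMES},
        ci95={nm: credible_interval(samples.pooled(nm)) for nm in PARAMETER_NAMES},
        rhat={nm: float(r) for nm, r in zip(PARAMETER_NAMES, rhat)},
    )
    return samples, summary


def compare_models(model: str, features: Sequence[TrialFeatures],
                   prior: PriorSpec | None = None,
                   sampler: SamplerConfig | None = None,
                   samples: PosteriorSamples | None = None) -> dict[str, BayesFactorResult]:
    """Savage-Dickey Bayes factors for dropping each slope term.

    For each of w1 (specificity) and w2 (veracity, entering as the
    theta-interaction in the evaluator model) the Bayes factor compares the
    full model against the nested model with that weight pinned at zero.
    """
    prior = prior or PriorSpec("normal", 1.0)
    if samples is None:
        samples, _ = fit_model(model, features, prior, sampler)
    return {nm: savage_dickey_bf(samples.pooled(nm), prior, at=0.0)
            for nm in ("w1", "w2")}


def false_statement_net_effect(weights: WeightVector, theta: float) -> float:
    """Change in the linear predictor when informant A adds one false statement.

    A false statement raises A's specific count and false count together, so
    the net effect is w1 + w2 * theta (w1 + w2 in the informant model with
    theta = 1).  It is positive for evaluators below the crossover
    theta* = w1 / (-w2) and negative above it.
    """
    return weights.w1 + weights.w2 * theta


def false_statement_flip_theta(weights: WeightVector) -> float:
    """Evaluator accuracy at which adding a false statement stops helping A."""
    if weights.w2 == 0:
        raise InvalidInputError("w2 = 0: the net false-statement effect never flips")
    return weights.w1 / (-weights.w2)


def predict_curves(model: str,
                   posterior: PosteriorSamples | WeightVector,
                   theta_grid: Sequence[float] = (0.5, 0.75, 0.9),
                   statement_range: Sequence[int] = range(0, 7),
                   baseline: float = 0.0) -> pd.DataFrame:
    """Independent-effect prediction curves with 95% posterior bands.

    For each theta and each count k of statements added, four curves are
    produced: true or false statements added to informant A or B.  Adding one
    true statement to A moves the linear predictor by +w1; one false statement
    by +(w1 + w2*theta); effects for B are the mirror image.  Bands are 2.5%
    and 97.5% quantiles of the per-draw predicted probabilities (degenerate
    when a fixed WeightVector is supplied).
    """
    if len(list(theta_grid)) == 0:
        raise InvalidInputError("theta grid must be non-empty")
    if isinstance(posterior, WeightVector):
        W = posterior.as_array()[None, :]
    else:
        W = posterior.draws.reshape(-1, posterior.n_parameters)
    w0, w1, w2 = W[:, 0], W[:, 1], W[:, 2]
    if model == "informant":
        theta_grid = [1.0]
    rows = []
    for theta in theta_grid:
        per_true = w1
        per_false = w1 + w2 * theta
        for k in statement_range:
            for stype, per in (("true", per_true), ("false", per_false)):
                for side, sign in (("A", 1.0), ("B", -1.0)):
                    p = logistic(w0 + baseline + sign * k * per)
                    p = np.atleast_1d(p)
                    rows.append({
                        "theta": theta, "statements_added": int(k),
                        "statement_type": stype, "side": side,
                        "p_mean": float(p.mean()),
                        "p_lo": float(np.percentile(p, 2.5)),
                        "p_hi": float(np.percentile(p, 97.5)),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in
                                  ("trial_id", "evaluator_id", "category_id",
                                   "informant_A", "informant_B", "image_ids",
                                   "choice")})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trials table {path} missing columns {missing}")
    if not df["choice"].isin(["A", "B"]).all():
        raise InvalidInputError("choice column must be 'A' or 'B'")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)
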