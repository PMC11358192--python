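"""Synthetic study generator.

Emulates the full two-experiment design: informants answer multiple-choice
questions in four categories (two self-selected, two randomly assigned) and
describe twelve images per category; raters count specific/true/false
statements in each description; evaluators answer the same question battery
and then judge, over 32 pairwise trials with 1/3/6/12 descriptions shown,
which of two informants is more knowledgeable.

The generative assumptions:

* knowledgeability: a participant's latent accuracy in a category is Beta
  distributed with condition-specific mean (self-selected 0.730, assigned
  0.573) and shared concentration; observed accuracy theta is the proportion
  correct of 30 Bernoulli(latent) answers.
* statement production: per description, the number of specific statements is
  Poisson with a log-linear rate in theta, calibrated so the mean count among
  informant-categories with theta > 0.9 is 1.68 and among theta < 0.5 is 0.55
  (the conditional means the study reports).  Each statement is independently
  false with probability 0.14, independent of theta.
* raters: each of 7 raters per description reports the latent counts
  perturbed by a single noise rate (statements missed, spuriously added, or
  veracity-flipped), always satisfying true + false = specific.
* evaluators: choices follow the evaluator choice model exactly, at weights
  (0, 0.32, -0.36) matching the reported posterior means.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .annotations import ANNOTATION_COLUMNS
from .bayes import InvalidInputError
from .choice_models import TRIAL_COLUMNS, WeightVector, logistic
from .knowledge import ANSWER_COLUMNS


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimulationConfig:
    """All generative parameters of a synthetic study.

    Defaults reproduce the study design and its reported summary statistics.
    """

    n_informants: int = 100
    n_evaluators: int = 160
    n_categories: int = 30
    categories_per_participant: int = 4   # 2 self-selected + 2 assigned
    questions_per_category: int = 30
    descriptions_per_informant_category: int = 12
    n_raters: int = 7
    n_rater_groups: int = 3
    theta_selected_mean: float = 0.730
    theta_assigned_mean: float = 0.573
    theta_concentration: float = 10.0
    statement_rate_high: float = 1.68     # mean count, theta > 0.9
    statement_rate_low: float = 0.55      # mean count, theta < 0.5
    false_rate: float = 0.14
    rater_noise: float = 0.12
    evaluator_weights: tuple[float, float, float] = (0.0, 0.32, -0.36)
    trials_per_evaluator: int = 32
    descriptions_shown_levels: tuple[int, ...] = (1, 3, 6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_selected_mean", "theta_assigned_mean",
                     "false_rate", "rater_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.statement_rate_high <= 0 or self.statement_rate_low <= 0:
            raise ConfigError("statement rates must be positive")
        if self.theta_concentration <= 0:
            raise ConfigError("theta_concentration must be positive")
        if self.categories_per_participant % 2 != 0:
            raise ConfigError("categories_per_participant must be even "
                              "(half self-selected, half assigned)")
        if self.categories_per_participant > self.n_categories:
            raise ConfigError("more categories per participant than categories")
        if self.trials_per_evaluator % len(self.descriptions_shown_levels) != 0:
            raise ConfigError("trials_per_evaluator must balance over the "
                              "descriptions-shown levels")
        self.evaluator_weights = tuple(float(w) for w in self.evaluator_weights)
        self.descriptions_shown_levels = tuple(int(v) for v in self.descriptions_shown_levels)

    @property
    def weights(self) -> WeightVector:
        return WeightVector(*self.evaluator_weights)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticStudy:
    """Generated tables plus the latent truth needed for recovery tests."""

    answers: pd.DataFrame
    annotations: pd.DataFrame
    trials: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "answers": out / "answers.csv",
            "annotations": out / "annotations.csv",
            "trials": out / "trials.csv",
            "truth": out / "truth.json",
            "config": out / "config.yaml",
        }
        self.answers.to_csv(paths["answers"], index=False)
        self.annotations.to_csv(paths["annotations"], index=False)
        self.trials.to_csv(paths["trials"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        self.config.to_file(paths["config"])
        return paths


# ---------------------------------------------------------------------------
# statement-rate calibration
# ---------------------------------------------------------------------------

def _theta_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of observed accuracy k/q under the beta-binomial mixture
    of self-selected and assigned categories (equal shares)."""
    q = config.questions_per_category
    nu = config.theta_concentration
    k = np.arange(q + 1)
    pmf = np.zeros(q + 1)
    for mean in (config.theta_selected_mean, config.theta_assigned_mean):
        a, b = mean * nu, (1.0 - mean) * nu
        pmf += 0.5 * stats.betabinom.pmf(k, q, a, b)
    return k / q, pmf


def calibrate_statement_rates(config: SimulationConfig,
                              high_cut: float = 0.9,
                              low_cut: float = 0.5) -> tuple[float, float]:
    """Solve the log-linear rate lambda(theta) = exp(a + b*theta) so that the
    conditional mean rate among theta > high_cut equals statement_rate_high
    and among theta < low_cut equals statement_rate_low."""
    theta, pmf = _theta_pmf(config)
    hi = theta > high_cut
    lo = theta < low_cut
    if pmf[hi].sum() <= 0 or pmf[lo].sum() <= 0:
        raise ConfigError("theta distribution puts no mass in a calibration band")

    def cond_mean_exp(b: float, mask: np.ndarray) -> float:
        w = pmf[mask] / pmf[mask].sum()
        return float(np.sum(w * np.exp(b * theta[mask])))

    target_ratio = config.statement_rate_high / config.statement_rate_low

    def f(b: float) -> float:
        return cond_mean_exp(b, hi) / cond_mean_exp(b, lo) - target_ratio

    b = optimize.brentq(f, -50.0, 50.0)
    a = np.log(config.statement_rate_high) - np.log(cond_mean_exp(b, hi))
    lam_max = np.exp(a + b)  # rate at theta = 1
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ConfigError("statement-rate calibration produced non-positive rates")
    return float(a), float(b)


def statement_rate(theta, a: float, b: float):
    """Poisson rate of specific statements per description at accuracy theta."""
    return np.exp(a + b * np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# simulation stages
# ---------------------------------------------------------------------------

def _simulate_participants(prefix: str, n: int, config: SimulationConfig,
                           rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Answers table rows and per-(participant, category) truth for n
    participants; half the categories are self-selected (higher mean theta)."""
    q = config.questions_per_category
    half = config.categories_per_participant // 2
    nu = config.theta_concentration
    rows = []
    truth = {}
    width = len(str(n))
    for i in range(n):
        pid = f"{prefix}{i + 1:0{width}d}"
        cats = rng.choice(config.n_categories, config.categories_per_participant,
                          replace=False)
        for j, c in enumerate(cats):
            cat = f"c{c + 1:02d}"
            selection = "self_selected" if j < half else "assigned"
            mean = (config.theta_selected_mean if j < half
                    else config.theta_assigned_mean)
            latent = rng.beta(mean * nu, (1.0 - mean) * nu)
            answers = (rng.random(q) < latent).astype(int)
            theta = float(answers.mean())
            truth[(pid, cat)] = {"latent": float(latent), "theta": theta,
                                 "selection": selection}
            for qi, corr in enumerate(answers):
                rows.append((pid, cat, qi, int(corr), selection))
    df = pd.DataFrame(rows, columns=ANSWER_COLUMNS)
    return df, truth


def simulate_informants(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Informant answers plus latent per-description statement counts.

    Returns (answers table, latent description table with columns
    informant_id/category_id/image_id/n_specific/n_true/n_false, truth dict).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a, b = calibrate_statement_rates(config)
    answers, truth = _simulate_participants("inf", config.n_informants, config, rng)
    rows = []
    for (pid, cat), rec in truth.items():
        lam = float(statement_rate(rec["theta"], a, b))
        for d in range(config.descriptions_per_informant_category):
            image_id = f"{cat}_im{d + 1:02d}"
            n = int(rng.poisson(lam))
            m = int(rng.binomial(n, config.false_rate)) if n else 0
            rows.append((pid, cat, image_id, n, n - m, m))
    latent = pd.DataFrame(rows, columns=["informant_id", "category_id",
                                         "image_id", "n_specific", "n_true",
                                         "n_false"])
    truth_out = {
        "rate_intercept": a, "rate_slope": b,
        "informants": {f"{k[0]}|{k[1]}": v for k, v in truth.items()},
    }
    return answers, latent, truth_out


def simulate_raters(latent: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-rater annotation table from latent description counts.

    Descriptions are divided round-robin into ``n_rater_groups`` sets, each
    scored by its own ``n_raters`` raters.  Per rater and description: each
    latent statement is missed with probability rater_noise, one spurious
    statement is added with probability rater_noise / 2, and each observed
    statement's veracity flips with probability rater_noise / 2.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    noise = config.rater_noise
    n_desc = len(latent)
    groups = np.arange(n_desc) % config.n_rater_groups
    nt = latent["n_true"].to_numpy()
    nf = latent["n_false"].to_numpy()
    frames = []
    for r in range(config.n_raters):
        keep_t = rng.binomial(nt, 1.0 - noise)
        keep_f = rng.binomial(nf, 1.0 - noise)
        spur = rng.random(n_desc) < noise / 2.0
        spur_false = rng.random(n_desc) < config.false_rate
        obs_t = keep_t + (spur & ~spur_false)
        obs_f = keep_f + (spur & spur_false)
        t2f = rng.binomial(obs_t, noise / 2.0)
        f2t = rng.binomial(obs_f, noise / 2.0)
        fin_t = obs_t - t2f + f2t
        fin_f = obs_f - f2t + t2f
        df = latent[["informant_id", "category_id", "image_id"]].copy()
        df["rater_id"] = [f"g{g + 1}_r{r + 1}" for g in groups]
        df["rater_group"] = [f"g{g + 1}" for g in groups]
        df["n_specific"] = fin_t + fin_f
        df["n_true"] = fin_t
        df["n_false"] = fin_f
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = ANNOTATION_COLUMNS + ["rater_group"]
    return out[cols].sort_values(
        ["informant_id", "category_id", "image_id", "rater_id"]
    ).reset_index(drop=True)


def simulate_evaluators(evaluator_truth: dict, informant_truth: dict,
                        latent: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Evaluator trials with choices generated from the evaluator choice model.

    Each evaluator runs ``trials_per_evaluator`` trials in their own four
    categories, balanced over the descriptions-shown levels; the informant
    pair is drawn within-category with unequal observed accuracy, and the
    choice is Bernoulli at the model probability with the configured weights.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    w0, w1, w2 = config.evaluator_weights
    # per (informant, category): image -> (n_specific, n_false)
    desc: dict[tuple[str, str], dict[str, tuple[int, int]]] = {}
    for row in latent.itertuples(index=False):
        desc.setdefault((row.informant_id, row.category_id), {})[row.image_id] = (
            int(row.n_specific), int(row.n_false))
    by_cat: dict[str, list[str]] = {}
    for (pid, cat) in informant_truth:
        by_cat.setdefault(cat, []).append(pid)

    eval_keys = sorted(evaluator_truth)
    per_level = config.trials_per_evaluator // len(config.descriptions_shown_levels)
    evaluators = sorted({k[0] for k in eval_keys})
    rows = []
    tid = 0
    for ev in evaluators:
        cats = sorted(c for (e, c) in eval_keys if e == ev)
        levels = list(config.descriptions_shown_levels) * per_level
        # trials split evenly across the evaluator's categories
        per_cat = config.trials_per_evaluator // len(cats)
        for ci, cat in enumerate(cats):
            pool = by_cat.get(cat, [])
            if len(pool) < 2:
                raise ConfigError(
                    f"category {cat} has fewer than 2 informants; cannot "
                    f"form discrimination trials")
            thetas = {p: informant_truth[(p, cat)]["theta"] for p in pool}
            if len(set(thetas.values())) < 2:
                raise ConfigError(
                    f"category {cat} has no informants with distinct accuracy")
            theta_e = evaluator_truth[(ev, cat)]["theta"]
            for k in range(per_cat):
                n_show = levels[ci * per_cat + k]
                for _ in range(1000):
                    a_inf, b_inf = rng.choice(pool, 2, replace=False)
                    if thetas[a_inf] != thetas[b_inf]:
                        break
                else:  # pragma: no cover - guarded by distinct check above
                    raise ConfigError(f"could not draw a distinct pair in {cat}")
                images = sorted(desc[(a_inf, cat)])
                shown = sorted(rng.choice(images, n_show, replace=False))
                dn = dm = 0
                for img in shown:
                    na, ma = desc[(a_inf, cat)][img]
                    nb, mb = desc[(b_inf, cat)][img]
                    dn += na - nb
                    dm += ma - mb
                p = logistic(w0 + w1 * dn + w2 * theta_e * dm)
                choice = "A" if rng.random() < p else "B"
                tid += 1
                rows.append((f"t{tid:05d}", ev, cat, a_inf, b_inf,
                             ";".join(shown), n_show, choice))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_study(config: SimulationConfig,
                   out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study; optionally write it to disk."""
    master = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(4)]
    inf_answers, latent, inf_truth = simulate_informants(config, rngs[0])
    annotations = simulate_raters(latent, config, rngs[1])
    ev_answers, ev_truth = _simulate_participants("eva", config.n_evaluators,
                                                  config, rngs[2])
    trials = simulate_evaluators(ev_truth, _unpack_truth(inf_truth), latent,
                                 config, rngs[3])
    answers = pd.concat([inf_answers, ev_answers], ignore_index=True)
    truth = {
        "rate_intercept": inf_truth["rate_intercept"],
        "rate_slope": inf_truth["rate_slope"],
        "informants": inf_truth["informants"],
        "evaluators": {f"{k[0]}|{k[1]}": v for k, v in ev_truth.items()},
        "weights": list(config.evaluator_weights),
        "latent_descriptions": latent.to_dict(orient="list"),
        "seed": config.seed,
    }
    study = SyntheticStudy(answers=answers, annotations=annotations,
                           trials=trials, truth=truth, config=config)
    if out_dir is not None:
        study.write(out_dir)
    return study


def _unpack_truth(inf_truth: dict) -> dict:
    out = {}
    for key, rec in inf_truth["informants"].items():
        pid, cat = key.split("|")
        out[(pid, cat)] = rec
    return out
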