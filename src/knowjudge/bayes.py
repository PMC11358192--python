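"""Generic Bayesian machinery: slice-sampling MCMC, convergence diagnostics,
credible intervals, Savage-Dickey Bayes factors and prior-robustness curves.

The sampler is a univariate stepping-out/shrinkage slice sampler (Neal 2003)
cycled over coordinates.  The default configuration -- eight chains, 1000
burn-in iterations, every 20th state retained, 100 retained draws per chain --
matches the study design this package analyses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("knowjudge")

#: Bayes factors above this are displayed as ">100".
BF_DISPLAY_CAP = 100.0

#: Split-R-hat threshold for declaring convergence.
RHAT_THRESHOLD = 1.05

#: Hard cap on stepping-out doublings before the sampler gives up.
MAX_STEPOUT = 100


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class NumericalError(RuntimeError):
    """Raised when a numerical procedure fails with diagnostics attached."""


# ---------------------------------------------------------------------------
# configuration / containers
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """MCMC settings.

    Defaults reproduce the analysis configuration: 8 chains, burn-in of 1000
    iterations, 100 retained samples per chain taken every 20th iteration.
    """

    n_chains: int = 8
    burn_in: int = 1000
    thin: int = 20
    draws_per_chain: int = 100
    seed: int = 0
    step_width: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_chains", "burn_in", "thin", "draws_per_chain"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                if name == "burn_in" and v == 0:
                    continue  # zero burn-in is legal for diagnostics work
                raise InvalidInputError(f"{name} must be a positive integer, got {v!r}")
        if not (self.step_width > 0):
            raise InvalidInputError("step_width must be positive")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with chain structure preserved.

    ``draws`` has shape (n_chains, draws_per_chain, n_parameters); ``rhat``
    is the per-parameter split-R-hat computed over the retained draws.
    """

    draws: np.ndarray
    parameter_names: list[str]
    config: SamplerConfig
    rhat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise InvalidInputError("draws must be a chains x draws x parameters array")
        if not np.all(np.isfinite(self.draws)):
            raise InvalidInputError("draws contain non-finite values")

    @property
    def n_parameters(self) -> int:
        return self.draws.shape[2]

    def pooled(self, parameter: int | str = 0) -> np.ndarray:
        """All chains' draws for one parameter, flattened."""
        if isinstance(parameter, str):
            parameter = self.parameter_names.index(parameter)
        return self.draws[:, :, parameter].ravel()

    def save(self, path_prefix: str) -> None:
        """Write draws as .npy with a JSON sidecar of names and config."""
        np.save(path_prefix + ".npy", self.draws)
        sidecar = {
            "parameter_names": self.parameter_names,
            "config": vars(self.config),
            "rhat": None if self.rhat is None else list(map(float, self.rhat)),
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass
class PriorSpec:
    """A proper univariate prior evaluable at any point.

    The default family is a zero-mean normal; ``scale`` is its standard
    deviation.  Savage-Dickey requires the density at the test point to be
    finite and positive, which every supported family satisfies at 0.
    """

    family: str = "normal"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidInputError("prior scale must be positive")
        if self.family not in ("normal", "cauchy", "stretched_beta"):
            raise InvalidInputError(f"unknown prior family {self.family!r}")

    def density_at(self, x: float) -> float:
        if self.family == "normal":
            return float(stats.norm.pdf(x, 0.0, self.scale))
        if self.family == "cauchy":
            return float(stats.cauchy.pdf(x, 0.0, self.scale))
        # stretched beta on (-1, 1): rho = 2*Beta(1/scale, 1/scale) - 1
        a = 1.0 / self.scale
        return float(0.5 * stats.beta.pdf((x + 1.0) / 2.0, a, a))

    def log_density_at(self, x: float) -> float:
        d = self.density_at(x)
        return math.log(d) if d > 0 else -math.inf

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(0.0, self.scale, size)
        if self.family == "cauchy":
            return self.scale * rng.standard_cauchy(size)
        a = 1.0 / self.scale
        return 2.0 * rng.beta(a, a, size) - 1.0


@dataclass
class BayesFactorResult:
    """A Bayes factor with its prior specification and optional robustness curve."""

    bf10: float
    method: str
    prior: PriorSpec | None = None
    capped: bool = False
    robustness: list[tuple[float, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.bf10 > 0):
            raise InvalidInputError("bf10 must be positive")

    @property
    def display(self) -> str:
        """Reporting convention: values above 100 print as '>100'."""
        if self.bf10 > BF_DISPLAY_CAP or self.capped:
            return ">100"
        return format(self.bf10, ".3g")

    @property
    def evidence(self) -> str:
        return classify_bf(self.bf10)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_update_coord(logp: Callable[[np.ndarray], float], x: np.ndarray,
                        fx: float, j: int, w: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One stepping-out/shrinkage slice update of coordinate j in place."""
    x0 = x[j]
    log_y = fx + math.log(rng.random())

    # stepping out
    u = rng.random()
    left = x0 - u * w
    right = left + w

    def logp_at(v: float) -> float:
        x[j] = v
        return logp(x)

    steps = 0
    while logp_at(left) > log_y:
        left -= w
        steps += 1
        if steps > MAX_STEPOUT:
            raise NumericalError(
                f"slice interval expansion exceeded {MAX_STEPOUT} steps at "
                f"coordinate {j} (x={x0!r}, width={w})")
    steps = 0
    while logp_at(right) > log_y:
        right += w
        steps += 1
        if steps > MAX_STEPOUT:
            raise NumericalError(
                f"slice interval expansion exceeded {MAX_STEPOUT} steps at "
                f"coordinate {j} (x={x0!r}, width={w})")

    # shrinkage
    while True:
        x1 = left + rng.random() * (right - left)
        f1 = logp_at(x1)
        if f1 > log_y:
            x[j] = x1
            return x, f1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _run_chain(log_density: Callable[[np.ndarray], float], init: np.ndarray,
               config: SamplerConfig, rng: np.random.Generator) -> np.ndarray:
    d = init.size
    x = init.astype(float).copy()
    fx = float(log_density(x))
    out = np.empty((config.draws_per_chain, d))
    n_iter = config.burn_in + config.thin * config.draws_per_chain
    kept = 0
    for it in range(1, n_iter + 1):
        for j in range(d):
            x, fx = _slice_update_coord(log_density, x, fx, j,
                                        config.step_width, rng)
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out[kept] = x
            kept += 1
    assert kept == config.draws_per_chain
    return out


def slice_sample(log_density: Callable[[np.ndarray], float],
                 init: Sequence[float],
                 config: SamplerConfig,
                 parameter_names: list[str] | None = None,
                 jitter: float = 0.1) -> PosteriorSamples:
    """Draw from ``exp(log_density)`` by coordinate-wise slice sampling.

    Each chain starts at ``init`` perturbed by N(0, jitter) noise (so that
    R-hat has between-chain information) and retains ``draws_per_chain``
    states after burn-in, keeping every ``thin``-th state.
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    f0 = float(log_density(init))
    if not np.isfinite(f0):
        raise InvalidInputError(f"log density is not finite at init {init!r}")
    d = init.size
    if parameter_names is None:
        parameter_names = [f"w{j}" for j in range(d)]

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        start = init + (jitter * rng.standard_normal(d) if jitter else 0.0)
        if not np.isfinite(log_density(start)):
            start = init.copy()
        chains.append(_run_chain(log_density, start, config, rng))
    draws = np.stack(chains)
    samples = PosteriorSamples(draws, parameter_names, config)
    samples.rhat = split_rhat(draws)
    return samples


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for a chains x draws x parameters array."""
    draws = np.asarray(draws, dtype=float)
    c, n, p = draws.shape
    half = n // 2
    # split each chain into halves -> 2c chains of length half
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n2 = split.shape[0], half
    chain_means = split.mean(axis=1)                       # (m, p)
    w = split.var(axis=1, ddof=1).mean(axis=0)             # within
    b = n2 * chain_means.var(axis=0, ddof=1)               # between
    var_plus = (n2 - 1) / n2 * w + b / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)


def check_convergence(samples: PosteriorSamples,
                      threshold: float = RHAT_THRESHOLD) -> tuple[np.ndarray, bool]:
    """Split-R-hat per parameter; passes iff all values are below threshold."""
    if samples.draws.shape[0] < 2:
        raise InvalidInputError("convergence check requires at least 2 chains")
    rhat = split_rhat(samples.draws)
    samples.rhat = rhat
    return rhat, bool(np.all(rhat < threshold))


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval (linear interpolation convention)."""
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level must lie in (0, 1), got {level}")
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise InvalidInputError("need at least 100 retained draws for a CI")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Savage-Dickey Bayes factors
# ---------------------------------------------------------------------------

def savage_dickey_bf(draws: np.ndarray, prior: PriorSpec,
                     at: float = 0.0) -> BayesFactorResult:
    """Bayes factor for a point null by the Savage-Dickey density ratio.

    BF10 = prior density at the null / posterior density at the null, the
    posterior density estimated by a Gaussian KDE with Silverman bandwidth.
    When the KDE and a normal approximation to the posterior disagree by more
    than 25% a warning is logged; when the estimated posterior density
    underflows, the result is capped at the display threshold and flagged
    rather than reported as infinite.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    prior_d = prior.density_at(at)
    if not (np.isfinite(prior_d) and prior_d > 0):
        raise InvalidInputError("prior density at the test point must be positive")
    if np.ptp(draws) == 0:
        post_d = math.inf if draws[0] == at else 0.0
    else:
        kde = stats.gaussian_kde(draws, bw_method="silverman")
        post_d = float(kde(at)[0])
        mu, sd = draws.mean(), draws.std(ddof=1)
        norm_d = float(stats.norm.pdf(at, mu, sd))
        if post_d > 0 and norm_d > 0 and not (0.75 < post_d / norm_d < 1.25):
            logger.info(
                "Savage-Dickey KDE density %.3g vs normal approximation %.3g "
                "at %.3g differ by >25%%", post_d, norm_d, at)
    if post_d <= 1e-300:  # posterior mass vanishes at the null
        return BayesFactorResult(bf10=BF_DISPLAY_CAP + 1.0,
                                 method="savage_dickey", prior=prior,
                                 capped=True)
    if not np.isfinite(post_d):  # degenerate posterior sitting on the null
        return BayesFactorResult(bf10=1e-12, method="savage_dickey", prior=prior)
    bf10 = prior_d / post_d
    return BayesFactorResult(bf10=float(bf10), method="savage_dickey", prior=prior)


def classify_bf(bf10: float) -> str:
    """Evidence category under the conventional Bayes-factor bands.

    Boundary values (1/10, 1/3, 3, 10) resolve toward the weaker claim.
    """
    if not (bf10 > 0):
        raise InvalidInputError("bf10 must be positive")
    if bf10 > 10:
        return "strong evidence against null"
    if bf10 > 3:
        return "moderate evidence against null"
    if bf10 < 0.1:
        return "strong evidence for null"
    if bf10 < 1 / 3:
        return "moderate evidence for null"
    return "inconclusive"


def bf_robustness(fit: Callable[[float], BayesFactorResult],
                  prior_scales: Sequence[float]) -> list[tuple[float, float | None]]:
    """Re-evaluate a Bayes factor across prior scales.

    ``fit`` maps a prior scale to a BayesFactorResult.  A failing scale is
    recorded as (scale, None); the curve is always returned.
    """
    scales = list(prior_scales)
    if len(scales) < 2:
        raise InvalidInputError("robustness check needs at least 2 prior scales")
    curve: list[tuple[float, float | None]] = []
    for s in scales:
        try:
            curve.append((float(s), float(fit(s).bf10)))
        except Exception as exc:  # single-point failure must not kill the curve
            logger.warning("robustness fit failed at scale %s: %s", s, exc)
            curve.append((float(s), None))
    return curve
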