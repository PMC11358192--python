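# knowjudge

A Bayesian analysis pipeline for studies of **knowledgeability judgment**:
how well people can tell, from nothing but a few image descriptions, which of
two strangers knows more about a topic.

The package covers the full quantitative workflow for a two-experiment design:

1. **Informants** answer multiple-choice general-knowledge questions in
   several categories (some self-selected, some randomly assigned) and write
   short descriptions of images from those categories.
2. **Raters** count, for every description, the *specific statements* it
   contains (information beyond what is visible in the image) and mark each
   statement's *veracity* (true or false).
3. **Evaluators** answer the same question battery, then repeatedly judge
   which of two informants is more knowledgeable after seeing 1, 3, 6 or 12
   descriptions from each.

`knowjudge` provides the rater-aggregation and reliability step, the
knowledgeability scoring, two Bayesian logistic choice models with full MCMC
posteriors and Bayes-factor model comparison, default-prior Bayes-factor
tests, a seeded synthetic-study generator for end-to-end validation, and a
CLI that runs everything and writes a structured report.

## The models

Knowledgeability θ is a participant's accuracy on a category's
multiple-choice questions. For a trial comparing informants A and B, let
`dn = n_A − n_B` be the difference in total specific statements across the
shown descriptions and `dm = m_A − m_B` the difference in false statements.

Two nested logistic models are fitted by slice-sampling MCMC:

- **Informant discriminability** (Eq. 1) — is the signal in the descriptions
  sufficient in principle?

  ```
  p(A truly more knowledgeable) = f(w0 + w1·dn + w2·dm)
  ```

- **Evaluator choice** (Eq. 2) — do evaluators use it, and does using the
  veracity cue require knowledge of one's own?

  ```
  p(evaluator chooses A) = f(w0 + w1·dn + w2·θ·dm)
  ```

  where θ is the evaluator's own accuracy in the trial's category.

For each slope the package reports the posterior mean, an equal-tailed 95%
credible interval, and a Savage–Dickey Bayes factor against the point null
that the weight is zero, plus a prior-robustness curve. A notable algebraic
consequence of Eq. 2: the net effect of one extra *false* statement on
choosing its author is `w1 + w2·θ`, so false statements *help* an informant
with evaluators whose accuracy is below the crossover `θ* = w1 / (−w2)` and
hurt above it (`false_statement_flip_theta`).

Also included:

- **Annotations**: per-description mode aggregation over raters and ICC(2,1)
  inter-rater reliability (two-way random effects, absolute agreement).
- **Knowledge**: self-selected vs. assigned accuracy contrast with a paired
  JZS Bayes factor, and a Monte-Carlo **split-half discrimination ceiling** —
  the accuracy attainable by predicting which pair member scores higher on an
  unseen half of the questions from the seen half.
- **Default Bayes factors**: JZS t-test BF (Cauchy(0, √2/2) prior on the
  standardized effect) and the default Pearson-correlation BF (stretched-beta
  prior, uniform on (−1, 1) at width 1), both by numerical integration of the
  exact marginal likelihoods.
- **Synthetic generator**: a seeded simulator of the complete design whose
  evaluator choices follow Eq. 2 exactly, used for parameter-recovery and
  calibration tests.

## Tests

```bash
pytest
```

The suite validates every numerical component against an independent oracle:
ICC against `pingouin`, the default Bayes factors against brute-force
trapezoid quadrature, Savage–Dickey ratios against conjugate closed forms and
an importance-sampling marginal-likelihood estimator, the slice sampler
against known targets with χ² histogram checks, and the split-half ceiling
against exhaustive split enumeration. `tests/test_acceptance.py` holds the
end-to-end acceptance criteria, including a ten-replicate parameter-recovery
study (a few minutes of runtime).

## Quickstart

Run the whole pipeline on a freshly simulated study:

```bash
knowjudge all --seed 42 --out-dir out
```

or from Python, at a reduced scale:

```python
from knowjudge import SimulationConfig, run_pipeline

config = SimulationConfig(n_informants=24, n_evaluators=10, n_categories=8,
                          trials_per_evaluator=8, seed=42)
report = run_pipeline(config, "out", ceiling_splits=2000)
```

This writes `out/report.json`, `out/report.md`, the aggregated annotation and
reliability tables, per-model prediction curves, and the simulated study
itself under `out/study/`. The run above (generating weights
`(0, 0.32, −0.36)`) produces exactly:

```
## Knowledge
- self-selected vs assigned accuracy: 0.705 vs 0.621 (BF = 5.38)

## Evaluator accuracy
- 1 descriptions: 0.450
- 3 descriptions: 0.500
- 6 descriptions: 0.650
- 12 descriptions: 0.700
- paired BF (1 vs 12 descriptions): 0.839
- split-half ceiling: 0.801

## Evaluator model
- w0: M = -0.397, 95% CI = [-0.890, 0.071]
- w1: M = 0.324, 95% CI = [0.168, 0.511]
- w2: M = -0.071, 95% CI = [-0.777, 0.587]
- BF for dropping w1: >100 (strong evidence against null)
- BF for dropping w2: 0.387 (inconclusive)
```

Ten evaluators are far too few to resolve the small veracity interaction
`w2` — its Bayes factor is rightly inconclusive — while the specificity
effect `w1` is already decisive. At the full default scale (160 evaluators ×
32 trials) the fitted posteriors recover the generating weights; that check
is `test_criterion_3_parameter_recovery_over_replicates` in the test suite.

The CLI also exposes the stages individually: `knowjudge simulate`,
`knowjudge aggregate`, `knowjudge score`, `knowjudge fit` and
`knowjudge report` (run any of them with `--help`).

## Package layout

| Module | Contents |
| --- | --- |
| `knowjudge.annotations` | rater tables, mode aggregation, ICC reliability |
| `knowjudge.knowledge` | θ scoring, selection contrast, split-half ceiling |
| `knowjudge.bayes` | slice sampler, split-R̂, credible intervals, Savage–Dickey BFs |
| `knowjudge.default_bf` | JZS t-test and stretched-beta correlation BFs |
| `knowjudge.choice_models` | Eq. 1 / Eq. 2 logistic models, fitting, curves |
| `knowjudge.synthetic` | seeded generator of complete synthetic studies |
| `knowjudge.pipeline` | stage orchestration, report writing, validation |
| `knowjudge.cli` | `knowjudge` command-line entry point |

See `docs/methods.md` for the statistical methods, generator assumptions and
numerical choices in detail.

## Method references

- Neal, R. M. (2003). Slice sampling. *Annals of Statistics*, 31(3), 705–767.
- Rouder, J. N., Speckman, P. L., Sun, D., Morey, R. D., & Iverson, G.
  (2009). Bayesian t tests for accepting and rejecting the null hypothesis.
  *Psychonomic Bulletin & Review*, 16, 225–237.
- Ly, A., Verhagen, J., & Wagenmakers, E.-J. (2016). Harold Jeffreys's
  default Bayes factor hypothesis tests. *Journal of Mathematical
  Psychology*, 72, 19–32.
- Dickey, J. M., & Lientz, B. P. (1970). The weighted likelihood ratio,
  sharp hypotheses about chances, the order of a Markov chain. *Annals of
  Mathematical Statistics*, 41(1), 214–226.
- Gelman, A., et al. (2013). *Bayesian Data Analysis* (3rd ed.) — split-R̂
  convergence diagnostic.
- Shrout, P. E., & Fleiss, J. L. (1979). Intraclass correlations: uses in
  assessing rater reliability. *Psychological Bulletin*, 86(2), 420–428.
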