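# Methods

This note documents the statistical models, the synthetic-data generator's
assumptions, and the numerical choices made in `knowjudge`, at the level of
detail needed to audit or extend the package.

## 1. Data model

Three tables describe a study:

- **answers** — one row per (participant, category, question):
  `participant_id, category_id, question_index, correct (0/1), selection
  (self_selected | assigned)`. Unanswered (timed-out) questions are recorded
  as incorrect.
- **annotations** — one row per (description, rater): `informant_id,
  category_id, image_id, rater_id, n_specific, n_true, n_false`, with the
  invariant `n_true + n_false = n_specific` enforced at read time.
- **trials** — one row per evaluator judgment: `trial_id, evaluator_id,
  category_id, informant_A, informant_B, image_ids (";"-separated),
  n_descriptions, choice (A | B)`.

## 2. Annotation aggregation and reliability

Each description's statement counts are collapsed over its raters by the
**mode**; ties take the smallest tied value (a deterministic, conservative
convention), and descriptions whose per-type modes are mutually inconsistent
(`true-mode + false-mode ≠ specific-mode`) are flagged. Inter-rater
reliability is **ICC(2,1)** — two-way random effects, absolute agreement,
single rater — computed from the ANOVA mean squares of the rater × description
rating matrix. ICC(3,1) (consistency) is available for comparison. The test
suite checks both against `pingouin` to 1e-10.

## 3. Knowledgeability

θ for a (participant, category) is the proportion correct over that
category's questions (30 by default). Two derived analyses:

- **Selection contrast** — each participant's mean accuracy in self-selected
  vs. assigned categories, compared with a paired JZS Bayes factor. If the
  paired differences have zero variance the t statistic is degenerate; the
  package then reports BF = 1e-6 (exact null) or a capped ">100" (perfect
  separation) rather than failing.
- **Split-half discrimination ceiling** — for each informant pair appearing
  in trials (pairs with identical total accuracy are excluded, since the
  ground truth is undefined), random half-splits of the question indices are
  drawn; the member ahead on the seen half is predicted to lead on the unseen
  half. Seen-half or unseen-half ties earn 0.5 credit. The ceiling is the
  mean credit over splits, averaged over pairs (each pair weighted once,
  regardless of how many trials used it). This bounds the accuracy any
  evaluator could reach if descriptions perfectly transmitted half of an
  informant's knowledge.

## 4. Choice models

With `dn` and `dm` the specific- and false-statement count differences summed
over exactly the images shown in a trial and f the logistic function:

- Eq. 1 (informant discriminability): `p = f(w0 + w1·dn + w2·dm)`, outcome =
  [informant A has higher θ] — a property of the stimuli, independent of the
  evaluator.
- Eq. 2 (evaluator choice): `p = f(w0 + w1·dn + w2·θ·dm)`, outcome =
  [evaluator chose A], θ = the evaluator's own accuracy in the trial's
  category. The θ-interaction encodes the hypothesis that discounting false
  statements requires enough knowledge to recognise them. The models coincide
  when θ ≡ 1.

Weights get independent N(0, 1) priors (scale configurable). The
log-likelihood uses the numerically stable softplus form
`y·η − Σ[max(η,0) + log1p(exp(−|η|))]` with the sufficient statistic `Xᵀy`
precomputed.

### Posterior sampling

Coordinate-wise **slice sampling** with stepping-out and shrinkage
(Neal 2003), width 1, step-out capped at 100 doublings. The production
configuration is 8 chains × (1000 burn-in + 100 kept draws at thinning 20),
giving 800 pooled draws. Chains start from the supplied initial point with
N(0, 0.1²) jitter; per-chain RNG streams are spawned from one `SeedSequence`,
so results are exactly reproducible given the seed and independent across
chains. Convergence requires split-R̂ < 1.05 on every coordinate; a fit that
fails raises rather than silently reporting.

### Model comparison

Dropping a slope is tested with the **Savage–Dickey density ratio**:
BF₁₀ = prior density / posterior density at 0, the posterior density
estimated by a Gaussian KDE (Silverman bandwidth) over the pooled draws. The
implementation logs a warning when the KDE estimate disagrees with a
moment-matched normal approximation by more than 25% (a sign the 800-draw
density estimate is strained), returns a capped ">100" result when the
posterior mass at 0 underflows, and reports BF values above 100 as ">100"
with evidence bands (3, 10) / (1/10, 1/3) for moderate/strong labels.
Robustness curves refit the model at prior scales (0.5, 1, 2); a failing
scale is recorded as missing rather than aborting. The suite validates
Savage–Dickey against conjugate closed forms (within 10%) and against an
importance-sampling marginal-likelihood oracle (within 30% on a
moderate-evidence instance — the Savage–Dickey estimator is itself Monte
Carlo, so exact agreement is not expected).

### Derived effects

The net linear-predictor change from one extra false statement by informant A
is `w1 + w2·θ` (a false statement is also a specific statement). It is
positive below `θ* = w1/(−w2)` and negative above; at the generating weights
(0, 0.32, −0.36), θ* = 8/9 ≈ 0.889. `predict_curves` produces
independent-effect curves (true/false statements added to A or B, over a θ
grid) with 95% bands taken pointwise over posterior draws.

## 5. Default-prior Bayes factors

- **JZS t test**: BF₁₀ = ∫ nct(t; df, δ√N_eff) Cauchy(δ; 0, √2/2) dδ /
  t(t; df), with N_eff = n (paired) or n₁n₂/(n₁+n₂) (independent). The
  integrand peaks at the effect-size MLE t/√N_eff with width ~1/√N_eff, so the
  integral is computed after the substitution δ = MLE + width·tan(u), which
  keeps adaptive quadrature accurate at any n. Regions where scipy's
  noncentral-t density under- or overflows contribute 0.
- **Pearson correlation**: the exact sampling density of r given ρ
  (hypergeometric form) integrated over a stretched-beta prior
  ρ = 2·Beta(1/w, 1/w) − 1; the default width 1 makes the prior uniform on
  (−1, 1). Integration points at ρ = r and ρ = 0 are supplied to the
  quadrature.

Both match independent brute-force trapezoid oracles to 4 significant figures
across grids of (statistic, n) in the test suite.

## 6. Synthetic-study generator

The generator emulates the full design; its problem sizes are package
defaults chosen to match the intended study scale: 100 informants, 160
evaluators, 30 categories with 4 per participant (2 self-selected +
2 assigned), 30 questions per category, 12 descriptions per
informant-category, 7 raters per description in 3 rater groups, 32 trials per
evaluator balanced over description levels {1, 3, 6, 12}.

Generative assumptions, stage by stage:

1. **Knowledge**: latent accuracy is Beta with mean 0.730 (self-selected) or
   0.573 (assigned) and concentration 10; observed θ is the proportion of 30
   Bernoulli(latent) answers. The contrast means are generator parameters;
   the concentration controls between-participant spread.
2. **Statement production**: per description, the specific-statement count is
   Poisson with the log-linear rate λ(θ) = exp(a + b·θ). The two rate
   parameters are solved (Brent's method on the slope) so that the
   **conditional means over the θ distribution** — E[λ | θ > 0.9] and
   E[λ | θ < 0.5] under the beta-binomial θ pmf — equal the configured group
   targets 1.68 and 0.55. Calibrating the conditional group means (rather
   than the pointwise rates λ(0.9), λ(0.5)) makes the simulated group
   statistics match the targets directly, which is what the calibration
   acceptance check measures. Each statement is false independently with
   probability 0.14, independent of θ.
3. **Raters**: a single noise rate (default 0.12) drives three perturbations
   per rater and description — each latent statement is missed with
   probability `noise`, one spurious statement is added with probability
   `noise/2`, and each observed statement's veracity flips with probability
   `noise/2`. Reported counts always satisfy true + false = specific. The
   value 0.12 was chosen a priori to put the synthetic ICCs in a realistic
   0.6–0.85 band; it is a free config parameter.
4. **Evaluators**: choices are exact Eq. 2 responders at weights
   (0, 0.32, −0.36): the trial's Bernoulli probability is computed from the
   latent (noise-free) statement counts, the informant pair is drawn
   within-category with distinct observed θ, and the shown images are a
   uniform subset of the level's size.

Four independent RNG streams (informants, raters, evaluators' answers,
trials) are spawned from the master seed, so each stage is reproducible in
isolation. The generator writes the three analysis tables plus `truth.json`
(latent parameters for recovery tests) and the config.

What the generator deliberately does **not** emulate: rater-specific bias or
skill differences (one shared noise rate), category difficulty differences,
informant writing-style confounds, evaluator learning across trials,
response times, and any dependence of statement veracity on θ. It is a
validation harness for the pipeline, not a cognitive model of raters or
evaluators.

## 7. Pipeline and reporting

Stages: **ingest** (simulate or read the three tables) → **aggregate**
(mode aggregation + reliability) → **score** (θ profiles, selection contrast,
accuracy by description level with a paired JZS BF between the fewest- and
most-description levels, split-half ceiling) → **fit** (both models, Bayes
factors, robustness, prediction curves) → **report** (`report.json` validated
against a shipped schema, `report.md`, CSV tables). Each stage failure raises
a `PipelineError` naming the stage. The report's `provenance` block records
the config SHA-256, master seed, sampler settings and package version.

## 8. Numerical conventions and limitations

- Credible intervals are equal-tailed, linear-interpolation percentiles,
  requiring ≥ 100 draws.
- BF values above 100 display as ">100"; the numeric value is preserved
  unless the computation itself was capped.
- The Savage–Dickey KDE is the analysis's main Monte-Carlo bottleneck: with
  800 pooled draws its density estimate at 0 carries a few-percent error for
  well-behaved posteriors and degrades when the null lies far in the
  posterior tail (where the BF is capped anyway).
- Slice sampling is serial per chain; the default fit of ~5000 trials takes
  tens of seconds on one CPU core. All heavy likelihood work is vectorised
  over trials.
- Trials whose informant pair has exactly equal θ are rejected during feature
  construction (ground truth undefined); the generator never emits them.
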