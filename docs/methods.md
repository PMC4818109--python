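# Methods

## Model

The Extended Condorcet Model treats each cell of an N×M ternary response
matrix as one pass through a processing tree.  Respondent *i* knows the
consensus answer Z_k of item *k* with probability
D_ik = logit⁻¹(θ_i − δ_k); knowing, they report it.  Not knowing, they
guess with probability b_i — "True" with probability g_i, "False"
otherwise — or mark "Don't know" with probability 1 − b_i.  Cells are
conditionally independent given the parameters, so the likelihood is a
product of categorical probabilities over the three response options.
Missing cells (supported even though a clean survey export has none) are
dropped from the likelihood; they are distinct from "Don't know", which is
an informative observed response.

The θ/δ scale is translation-invariant, so the mean item difficulty is
pinned to zero.  Person parameters get a hierarchical structure that doubles
as the latent regression: with standardized covariates x_i,

- θ_i   = x_i'β_θ + ε_i,           ε_i ~ Normal(0, σ_θ²)
- logit b_i = x_i'β_b + ε_i,       ε_i ~ Normal(0, σ_b²)
- logit g_i = x_i'β_g + ε_i,       ε_i ~ Normal(0, σ_g²)

with an intercept always present (covariates optional; the intercept-only
model is the plain hierarchical prior).  A residual term is essential: the
linear predictor alone would force persons with equal covariates to be
identical.  The probability parameters are regressed on the logit scale so
they remain in (0, 1).  Estimating the coefficients inside the joint
posterior ("one-step") propagates the uncertainty of the person parameters
into the coefficient posteriors; regressing point estimates in a second
stage misstates that uncertainty (the package's test suite demonstrates the
two procedures disagree measurably).

Priors are proper but diffuse: β ~ Normal(0, 10²) elementwise,
δ_k ~ Normal(0, σ_δ²), every scale (σ_θ, σ_b, σ_g, σ_δ) half-Normal(0, 5),
and Z_k ~ Bernoulli(0.5) a priori (configurable via `prior_true`).  Both
prior scales are arguments of `fit_ecm` for sensitivity analyses.

## Sampler

`fit_ecm` runs a Gibbs-within-Metropolis sweep (no external PPL; the
sampler is part of the package):

1. **Z_k** — exact Bernoulli full conditional via the two-term Bayes rule
   per item ("Don't know" responses carry no information about Z).
2. **θ_i, δ_k, logit b_i, logit g_i** — coordinate-wise random-walk
   Metropolis, vectorized over persons/items (rows and columns are
   conditionally independent).  Proposal scales adapt per coordinate by
   Robbins–Monro toward 44% acceptance during burn-in only, so the
   post-burn-in kernel is a fixed, valid Markov transition.
3. **Scale identification** — after the δ update, δ is recentered to sum
   zero with the same shift applied to θ, leaving θ − δ (hence the
   likelihood) unchanged.  The regression intercept absorbs the shift
   through its own update.  Two consequences worth recording: (a) the
   recentered δ lives on an (M−1)-dimensional subspace, so the σ_δ update
   must use M−1 degrees of freedom — using M makes σ_δ drift to zero; (b)
   in prior-only mode (below) there is no likelihood to keep invariant and
   the θ-shift would leak a random walk into the intercept, so only δ is
   recentered there.
4. **β** — conjugate multivariate-normal Gibbs update per target.
5. **Scales** — Metropolis on log σ (with the log-transform Jacobian),
   steps adapted during burn-in like the other blocks.

Chains are seeded from a single `SeedSequence` spawn, so any fit is
bit-reproducible from its `McmcConfig`.  Defaults are 8 chains × (1000
burn-in + 1000 draws), convergence flagged against split-chain R̂ < 1.1,
computed for every continuous scalar (the discrete key is monitored through
the continuous parameters it drives).  A non-converged run is returned with
`converged=False` and a `ConvergenceWarning`, never silently.

**Label switching.** The model has a global reflection mode (flip all Z,
negate θ−δ contrasts, swap g).  Chains are initialized at the per-item
majority-vote key with θ near 0, which targets the data-supported mode; in
all test conditions the reflected mode is never visited after burn-in.

**Prior-only mode.** `fit_ecm(..., prior_only=True)` removes the
likelihood so the chain must reproduce the prior — a sampler-correctness
diagnostic.  With no likelihood the full conditionals of θ, δ and the
logits *are* their priors and are drawn exactly (random-walk moves mix
poorly through the funnel geometry of a hierarchical prior, which is also
why the correctness test uses moderate prior scales: at the very diffuse
defaults the β↔θ Gibbs cycle has an autocorrelation time in the thousands
and no finite run estimates its mean usefully).

**Degenerate inputs.** Category probabilities are floored at 1e-300 before
logs; an observed response with probability exactly zero sends the exposed
`log_likelihood` to −inf with a warning.  Items answered only with
Don't-know get an undefined (NaN) raw mean, flagged.  An exact posterior
tie P(Z_k = 1) = 0.5 is labelled by the item's raw mean.

## Synthetic data generator

`generate_dataset` draws from the model's own generative process and is the
ground-truth source for every recovery test.  Defaults emulate a
150-respondent × 53-item consensus survey:

| parameter | default | rationale |
|---|---|---|
| ability θ | Normal(0.43, 1.49²) | population mean/sd of person knowledge estimates typical of a lay-knowledge consensus survey |
| difficulty δ | Normal(0, 1.65²), recentered | satisfactory coverage of easy-to-hard items; identification |
| logit b | Normal(2.7, 1.6²) | willingness-to-guess mean ≈ 0.87; jointly calibrated (quadrature over the logit-normal) so the overall Don't-know rate lands near 5% of responses |
| logit g | Normal(−0.19, 1.83²) | guess-bias mean 0.47, sd 0.30 (exact logit-normal solution) |
| covariates | one balanced binary + one continuous, standardized | demographic-style design; slopes −0.27 (ability), +0.50 (willingness logit), −0.46 (guess-bias logit) per sd — effect sizes typical for demographic predictors of latent traits |
| consensus prior | 0.5 | uninformative key |

A willingness calibration that reproduces a probability-scale mean of
exactly 0.85 with sd 0.21 implies a ≈6.3% Don't-know rate; the chosen
(2.7, 1.6) favours the observed-data constraint (≈5% Don't-know) at the
cost of a slightly higher willingness mean — consistent with the fact that
reported willingness summaries are shrunken posterior means.  Covariate
slopes are carved out of the configured marginal sd (residual sd
= √(sd² − Σβ²)), so the marginal spread of each latent parameter does not
depend on the design.

What the generator does **not** emulate: item clustering by topic (real
consensus items are correlated in content, the generator's difficulties are
exchangeable), attention lapses, respondent dropout patterns, and any
multi-culture structure (available only through explicit constructions in
the tests).  Passing recovery tests therefore show the estimator works when
the model is true at realistic sizes and signal — not that any real survey
satisfies the model.

## Posterior predictive check

The statistic is the eigenvalue scree of the respondent-by-respondent
Pearson correlation matrix.  Responses are coded True = 1, False = 0,
Don't-know = 0.5; the intermediate value is the symmetric choice and keeps
every complete row, but it is a package convention, not a canonical rule —
it is configurable, and conclusions should be checked under alternatives
(e.g. dropping Don't-know pairs).  Zero-variance respondents are excluded
with a warning (correlation undefined), so each scree sums to the retained
respondent count.  Replicates (default 500) are simulated from parameter
draws taken evenly across the pooled chains; the envelope is the per-rank
min/max of the replicate screes, and model adequacy is read off ranks 1–2:
a single consensus gives a first eigenvalue several times the second with
the observed scree inside the envelope, while a second culture pushes the
observed second eigenvalue above it.

## Problem sizes in the shipped checks

The test suite balances depth against a laptop-friendly runtime: unit-level
fits use 20–60 respondents, 10–40 items and 2 chains × (250–300 + 250–300)
iterations; the study-scale recovery check fits 150 × 53 with 4 chains ×
(500 + 500) and scores slope-sign recovery over 10 reduced refits; the PPC
checks use 80–150 replicates.  The full default settings (8 × 2000) are
reserved for real analyses.

## Known limitations

- Single-culture model only: the PPC can *flag* a second culture but the
  package does not fit mixture answer keys.
- Random-walk updates mix slowly when person parameters are weakly
  identified (e.g. g_i for respondents who almost never guess); the
  hyper-scales of the guess-bias hierarchy are usually the last parameters
  to converge, and short exploratory runs may flag them.
- The Don't-know coding of the PPC correlation (0.5) and the exclusion of
  Don't-know from raw item means are conventions, documented rather than
  derived.
- R̂ is the classical split-chain PSRF, not the rank-normalized variant;
  the test suite cross-checks it against an independent implementation on
  well-mixed chains.
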