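# Methods

## Model and classification rule

An LQAS survey classifies each supervision area (SA) by sampling `n`
individuals and counting successes `X ~ Binomial(n, p)`, where `p` is the
SA's true coverage.  The area is classified as achieving the benchmark when
`X > d` and failing otherwise; `d = −1` (always accept) and `d = n` (never
accept) are admitted as degenerate rules.  A design `(n, d)` is evaluated
against four parameters: thresholds `p_l < p_u` delimiting the grey region,
and risk caps `α, β` for the two misclassification events

    alpha = P(X <= d | p = p_u)      (true high classified low)
    beta  = P(X >  d | p = p_l)      (true low classified high)

Both are binomial tail probabilities and are computed with the regularised
incomplete beta function (scipy's `binom.cdf`/`binom.sf`), never by naive
factorial summation.

### Design search

`solve_design` scans `n = 1, 2, …, n_max` (default 1000) and returns the
first `n` admitting any feasible `d`; among feasible rules at that `n` it
picks the `d` minimising `max(alpha, beta)`, ties toward smaller `d`.  Two
non-obvious facts about this search, both exercised in the tests:

* Feasibility is **not monotone in n** (a saw-tooth): for thresholds
  0.35/0.65 with 10% risks, n = 17 is feasible (risks 0.0994), n = 18 is
  not, n = 19 is again (risks 0.0875).  The solver's contract is *minimal*
  n, so it returns (17, 8) for these inputs.
* Field practice often fixes `n = 19` by convention and only solves for
  `d`; the bundled Nepal follow-up survey is such a design.  The package
  therefore carries the surveyed rule `(19, 9)` as `NEPAL_DESIGN`,
  distinct from the solver's minimal answer.

The risk curve assigns the boundary point `p = p*` to the "classified low
is an error" branch (`P(X ≤ d | p)`); the choice is conventional and
affects a set of prior measure zero.

## Bayesian accuracy (conjugate closed form)

True coverage across SAs is modelled as `p ~ Beta(a, b)`.  Marginally `X`
is beta-binomial and the posterior given `X = k` is `Beta(a+k, b+n−k)`, so
every accuracy summary is a finite sum; writing `bb(k)` for the
beta-binomial pmf and `T_k(x) = P(p > x | X = k)` for the posterior tail:

    PPV(p*)  = sum_{k>d} bb(k) T_k(p*) / sum_{k>d} bb(k)
    NPV(p*)  = sum_{k<=d} bb(k) (1 − T_k(p*)) / sum_{k<=d} bb(k)

and analogously for the grey-region mass given the classification and for
the Bayesian risks `α_B = P(p ≥ p_u | X ≤ d)`, `β_B = P(p ≤ p_l | X > d)`.
This closed form is the implementation; adaptive quadrature of the defining
integrals serves only as an independent oracle in the test suite, where the
two routes agree to 1e−8 across the full prior grid.  "High coverage" is
strict `p > p*` and "low" strict `p < p*`; the mixed weak inequalities in
the Bayesian risks are kept as conventionally stated — all boundaries carry
zero prior mass.  Conditioning on an event of probability zero (a rule that
never accepts or never rejects) raises an error rather than returning NaN.

Reports are computed at full precision and rendered to 3 decimals.

## Prior elicitation and fitting

`beta_from_mean_sd` moment-matches `a + b = m(1−m)/s² − 1`, `a = m(a+b)`,
rejecting spreads with `s² ≥ m(1−m)` (no Beta distribution has them).
`shift_prior` re-elicits with a new mean and/or scaled sd.

`fit_beta` offers four routes, because "the best-fitting Beta" is genuinely
method-dependent on small surveys:

* **betabinomial_moments** (default): match the pooled proportion and the
  population (m-denominator) variance of the *counts* to the beta-binomial
  moments; the variance inflation over the binomial identifies the
  intraclass correlation `ρ = 1/(a+b+1)`.  Closed form, no optimizer; it
  deconvolves the within-SA binomial noise, so the implied Beta spread is
  that of the coverages themselves.  It requires a common `n` and genuine
  overdispersion — underdispersed data (common in small bootstrap
  resamples) raise a convergence error, which the bootstrap counts as a
  failed replicate.  This route is the default because, applied to the
  bundled baseline counts, it reproduces the bundled Nepal reference analysis end to end (the
  ~Beta(9.66, 8.69) baseline fit and the 34.2% grey-region estimate below).
* **betabinomial_mle**: Nelder–Mead on the log-shape parameters of the
  beta-binomial likelihood, started at the moment fit; optimizer failure
  raises, never a silent fallback.
* **proportions_mle**: Beta MLE on the observed proportions clipped to
  `[1e−6, 1 − 1e−6]` — a proportion of exactly 1 (present in the follow-up
  data) otherwise makes the log-likelihood diverge.  Note the clipped
  boundary point still dominates: on the follow-up survey this route gives
  a J-shaped fit with far less grey mass than the count-level routes.
* **moments**: moment-match the mean and (m−1)-denominator sd of the
  proportions; exactly `beta_from_mean_sd` of the empirical moments.

## Post-survey density estimation

Observed proportions `p̂_i = X_i/n_i` feed three estimators of the coverage
distribution:

* **Histogram**: the empirical fraction of `p̂_i` in an interval, half-open
  `[lo, hi)` so a partition sums to exactly one; an interval ending at 1 is
  closed so `p̂ = 1` is kept.  With bin edges anchored at the thresholds
  this is the "crude" estimate (3/7 = 42.9% grey on the follow-up data).
* **Gaussian kernel**: bandwidth `0.9·min(s, IQR/1.34)·m^(−1/5) · m^(−0.3)`
  — Silverman's rule of thumb (sample sd, linearly interpolated quartiles)
  shrunk by an extra `m^(−0.3)` to prioritise small bias over smoothness on
  few SAs.  Interval mass is the exact normal-CDF sum; the mixture is
  deliberately untruncated and unrenormalised on [0, 1] (a boundary-spike
  like `p̂ = 1` spills mass past 1).  On the follow-up data this gives
  36.9% grey with bandwidth 0.0668.
* **Parametric Beta**: interval mass of a `fit_beta` result (34.2% grey
  with the default moment fit).

Bootstrap standard errors resample **SAs (rows) with replacement**,
recomputing the bandwidth and refitting the Beta per replicate; a mandatory
seed makes summaries exactly reproducible.  Failed replicates (degenerate
spread for the kernel, non-convergent fits for the Beta) are counted and
excluded from the sd.  The histogram's bootstrap sd converges on the
binomial closed form `sqrt(p̂(1−p̂)/m)` — 18.7% on the follow-up data.

## Synthetic data and the bias study

`generate_survey` draws `p_i ~ Beta(a, b)` then `X_i ~ Binomial(n, p_i)` —
exactly the exchangeable two-stage structure the accuracy calculations and
post-survey estimators assume.  It does **not** emulate spatial correlation
between SAs, within-SA clustering of respondents, covariate-driven
coverage differences, or imperfect measurement, so passing tests certify
the estimators under the model's own assumptions, not under field
conditions.

`simulation_study` replays the three estimators over `reps` synthetic
surveys for the probabilities below `p_l`, in the grey region, and above
`p_u`, against the generating prior's closed-form truths.  A single root
`SeedSequence` spawns one substream per replicate, so results are
independent of execution order.  Defaults mirror the Nepal geometry
(m = 7, n = 19); per-replicate bootstrapping is available but off by
default (`B = 0`) since bias needs no bootstrap.  Two structural findings
are frozen into tests:

* At fixed `n`, the histogram's expectation is the beta-binomial *smear*
  `P(p̂ ∈ interval)` — independent of `m` — so its bias does not vanish
  with more SAs (for ~Beta(9.6, 8.7) at n = 19 it is −0.136 for the grey
  mass, at any m).
* The count-level Beta fit deconvolves the binomial noise, so its bias
  does shrink with `m` at fixed `n`; and all three estimators' biases
  shrink when `m` and `n` grow jointly.  The packaged study uses 500
  replicates at (m = 7, n = 19) vs (m = 50, n = 190) — sizes chosen to
  show the contrast clearly at interactive runtimes.

## Interfaces

Survey tables travel as `sa_id,successes,sampled` CSV with row-indexed
validation errors; curves as two-column CSV; reports as CSV (3 dp) and
full-precision JSON.  Priors are accepted as `"a,b"` or `"mean=…,sd=…"`
strings on the CLI and in YAML/JSON configs; config validation reports the
offending field path.  The `lqas` CLI wraps the library thinly
(`design`, `evaluate`, `posthoc`, `simulate`, `reproduce`) with structured
logs to stderr and non-zero exits on any error.

## Known limitations

* Binomial sampling only: no hypergeometric small-population correction,
  and no Poisson/normal outcome models.
* Single Beta priors only; mixtures (for bimodal coverage landscapes) are
  out of scope.
* The kernel estimator's untruncated-Gaussian convention is simple and
  matches the package's reference analysis, but it leaks mass outside
  [0, 1] when point estimates sit near the boundary.
* The design evaluator scores a *given* frequentist rule under priors; it
  does not optimise `(n, d)` against a Bayesian loss.
* With very few SAs all three density estimators are materially biased
  (see the bias study); interval probabilities from m = 7 areas should be
  read as rough descriptions, not measurements.
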