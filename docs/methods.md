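# Methods

## The model

`emanet` analyses intensive longitudinal self-report data — ecological
momentary assessment (EMA) series in which each participant rates six
psychological-process items (negative/positive affect, negative/positive
cognition, rigidity, variation) on a 0–100 scale at five semi-random prompts
per day over three weeks — with a two-step multilevel vector autoregression
of order 1.

**Step 1 (temporal network).** For each node *k*, score `y_k(t)` is regressed
on the within-person-centered scores of all six nodes at the previous prompt:

    y_k(i,t) = b_0k + Σ_j β_jk (y_j(i,t−1) − ȳ_j(i)) + Σ_j γ_jk ȳ_j(i) + u(i) + ε_k(i,t)

where `i` indexes persons, `ȳ_j(i)` is person *i*'s mean of the lagged
predictor *j*, `u(i)` are person-level random terms, and the fixed effects
`β_jk` form the directed temporal matrix (edge *j* → *k*). Within-person
centering plus the person-mean covariates `γ` separates within- from
between-person variance; only the within-person network is reported.
Lag pairs are formed only between adjacent answered prompts of the same
person-day; a missed prompt breaks the chain and no pair spans the night.

**Step 2 (contemporaneous network).** Step-1 residuals are regressed
node-wise on the other five same-prompt residuals (random intercept per
person under the mixed options). The two directed coefficients of each pair
(j,k) are combined into a partial correlation by a sign-consistent geometric
mean, `sign(b_jk)·√(b_jk·b_kj)` when the signs agree and 0 otherwise; pair
p-values are combined conservatively as the maximum of the two
(`symmetrization="and"`; `"or"` takes the minimum).

**Centrality.** In-strength IS(j) = Σ_k |β_kj|, out-strength
OS(j) = Σ_k |β_jk| (autoregressive self-loops excluded by default; a toggle
includes them), strength S(j) = Σ_k |pcor_jk|. Centralities are computed on
the full estimated matrices; an `on_filtered` switch computes them after
zeroing non-significant edges instead. Both conventions are exposed because
published centrality tables do not always state which was used.

**Stability.** The case-drop bootstrap removes `round(0.2·N)` participants
without replacement, refits the whole two-step model on the remainder, and
records which node ranks *strictly* first per index; exact ties credit no
node (conservative and deterministic — ties have measure zero for continuous
estimates). Frequencies are counts over successful replications.

## Random-effects options and the downgrade ladder

`random_effects` controls the person-level terms of the node-wise
regressions:

- `fixed` — pooled least squares, no random terms. With
  within-person-centered predictors and person-mean covariates, person
  intercepts are already absorbed, so this is the exact model whenever
  person-specific coefficient matrices do not vary (τ_B = 0). It is also the
  configuration under which the estimator provably equals pooled per-node
  least squares, which the test suite checks to 1e−6.
- `orthogonal` — random intercept plus uncorrelated random lagged slopes
  (variance components).
- `correlated` (default) — random intercept and slopes with a full
  covariance matrix.

Mixed models are estimated by REML (statsmodels `MixedLM`, up to 200
iterations), first with L-BFGS and, if that fails to converge with finite
standard errors, with Powell's method. A node whose fit still fails is
downgraded one rung (`correlated` → `orthogonal` → `fixed`) and every
downgrade is logged in the network's provenance metadata. Edge p-values are
Wald tests on the fixed effects with no multiple-testing correction by
default (a Bonferroni switch exists in the display filter), matching the
plain-significance convention of group-level EMA network reports.

## Preprocessing

- **Compliance.** Participants need at least `min_count = 73` completed
  prompts (70% of the 105 scheduled). The count is the operational rule; the
  percentage is derived from it.
- **Relative speed index.** Completion speed relative to the participant's
  own median duration. Default convention `rsi = median/duration`, so values
  above 2 flag implausibly fast (careless) completion; the literal ratio
  `duration/median` is available as `rsi_convention="literal"`. Prompts with
  rsi > 2 are converted to missed prompts. Their durations are retained so
  the per-person median — and therefore the filter — is unchanged when the
  filter is reapplied; this is what makes filtering idempotent.
- **Detrending.** Per person and per item, OLS of the score on a linear day
  term and categorical occasion-of-day effects. The day slope is t-tested and
  the occasion block F-tested at α = 0.05; only significant terms are
  subtracted (mean-centred, preserving the person's grand mean). Series with
  fewer than 10 answered prompts pass through with a warning. Degenerate
  cases: an exactly deterministic trend (zero residual) is removed with p = 0;
  a constant series is untouched. Descriptive statistics are computed on
  filtered but *un*-detrended data.

## Synthetic study generator

The generator is the package's ground truth: person-specific VAR(1)
coefficient matrices `B_i = B + N(0, τ_B)` (rescaled to spectral radius 0.9
whenever a draw is explosive, preserving the sign pattern), person means
`μ_i ~ N(μ, τ_μ)`, person-level linear day slopes, occasion-of-day offsets,
multivariate-normal innovations with covariance Σ, and a prompt schedule of
3-hour anchors centred in an 08:00–23:00 waking window with N(0, 0.63 h)
jitter, re-jittered until all gaps are ≥ 30 min. The waking window is a
fixture choice (self-reported windows are not modelled). The VAR chain
restarts from its stationary distribution (discrete Lyapunov solution) each
morning, mirroring the estimator's overnight-lag exclusion. Missingness is
completely at random per prompt at a per-person compliance drawn from a Beta
distribution with mean 0.93 and SD 0.08 (clipped to [0.4, 1]), matching the
reported compliance of the study design emulated. Completion durations are
per-person log-normal around a 3.5-minute assessment with an optional
"speeder" contamination fraction (default 3% in the realistic model, durations
divided by 8) to exercise the RSI filter.

Default population parameters (means from the emulated study's descriptives,
a temporal matrix in which rigidity has the largest out-strength with
positive edges into negative processes and negative edges into positive
ones, and an innovation correlation with same-valence positive blocks) are
realism choices for fixtures; recovery tests instead use homogeneous models
(τ = 0, trends off, clipping off) where the estimator's assumptions hold
exactly.

Clipping scores to [0, 100] is off by default because truncation biases
linear-model recovery; the realistic fixtures switch it on. Consequently,
passing recovery tests demonstrate correctness of the estimator under its
own assumptions — they do not quantify the (small) bias that bounded scales,
non-normal innovations, or non-random missingness would add in real data.

## Problem sizes and numerical choices

Validation runs use: recovery at 100 persons × 21 days × 5 prompts (8 400
lag rows; β mean absolute error and max partial-correlation error both come
out below 0.02–0.03), null calibration over 200 studies of 30 persons × 50
prompts (edge false-positive rate within [0.03, 0.07]), bootstrap separation
at 60 persons with 100 replications, and exact-agreement checks (pooled OLS
to 1e−6, brute-force centrality sums, lag-pair enumeration). The realistic
end-to-end scenario enrols 125 participants with six externally flagged, as
in the study design emulated. These sizes are the package's validation
conditions; heavier simulations behave identically in expectation.

All randomness flows from one root seed split with
`numpy.random.SeedSequence.spawn` in stage order (persons, schedule,
responses; and per-stage in the pipeline), so identical configurations and
seeds give byte-identical outputs. Ties in "ranks first" require a strict
maximum. Partial correlations outside [−1, 1] (possible numerically under
mixed fits) are clamped with a warning. Spectral radii are computed from
eigenvalues; stationary covariances via `scipy.linalg.solve_discrete_lyapunov`
on the transposed coefficient matrix.

## Known limitations

- Group-level (nomothetic) networks only; person-specific networks are
  internal to the mixed model and not a deliverable.
- The 120-minute prompt expiry is represented only as answered/missed, not
  as a latency process; missingness is MCAR by construction.
- The `correlated` random-effects option is expensive for long panels and
  frequently downgrades on small samples; that is by design (logged), but it
  means small-sample runs often reduce to the orthogonal or fixed model.
- Detrending tests each series independently; no pooling across persons and
  no correction for testing 6 items × 2 terms per person.
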