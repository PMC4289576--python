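# Methods

## The index

Eleven self-report questions map onto six binary frailty-risk indicators
and six binary robustness-resource indicators (see
`faindex.questionnaire`). The outdoor-walking frequency question is doubly
weighted: answering "never or 1–2 days/week" fires risk 5, any higher
frequency fires resource 2, so `risk_5 + resource_2 == 1` always and
`risk_score + resource_score <= 11`; the corner (6, 6) is unreachable.
"Able to walk 500 m" counts as a resource only for an unqualified yes —
"with difficulty / a device / help" collapses with "no" (the raw category
is kept for audit). Classification needs only the two sums: risks 0–2 with
resources 3–6 → Robust, risks 3–6 with resources 3–6 → postRobust, risks
0–2 with resources 0–2 → preFrail, risks 3–6 with resources 0–2 → Frail.
postRobust + preFrail are pooled as Transient in transition analyses. For
rank correlations the four classes are encoded ordinally
Robust = 0 … Frail = 3; the relative order of postRobust and preFrail in
that encoding is an assumption (the two middle classes are conceptually
parallel, not ordered) and is documented as such.

**Missing answers.** A record with any missing or invalid answer is
unscorable and excluded from every denominator (complete-case analysis).
No partial scoring, no imputation — scores remain comparable across
respondents, and each pipeline stage logs its exclusions because
denominators legitimately shift between tables. One coding scheme is used
for all waves (later-wave rephrasings of the activity questions are
ignored).

**Rounding.** Every printed percentage is rounded half away from zero to
one decimal; each table cell carries its numerator/denominator pair so the
percentage is reproducible.

## Synthetic cohort generator

The generator exists so that the full analysis chain — scoring, survival,
transitions — can be exercised end to end without restricted cohort data.
Design choices, with defaults:

* **Latent-trait item model.** Frailty is a scalar trait
  `z ~ N(0, 1)`. Indicative-risk answers fire with probability
  `logistic(a_r + b z)` per item, indicative-resource answers with
  `logistic(a_s − b z)`; resource 2 is the complement of risk 5. A
  latent-variable model was chosen over per-class item tables because
  item-level prevalences were not available to copy, and because it makes
  class membership *emergent* from generated raw answers scored through
  the real scoring path, testing that path end to end. Concrete answer
  categories within a binary side (e.g. "never" vs "1–2") are split by
  fixed cosmetic shares that never change a score.
* **Calibration.** The three free parameters `(a_r, a_s, b)` are solved
  (80-node Gauss–Hermite quadrature over `z`, `scipy.optimize.root`,
  residual tolerance 1e-10) against the three independent cells of the
  target 2×2 class table; the fourth cell follows. The default mixture is
  60.9 / 13.1 / 10.2 / 15.8 %, reproduced exactly in population
  probability (defaults: `b ≈ 0.905`, `a_r ≈ −1.004`, `a_s ≈ 0.343`). An
  unreachable mixture (e.g. mass concentrated on postRobust, which this
  one-trait family cannot produce) raises a calibration error with
  diagnostics. A useful emergent property: the generated risk and resource
  scores are negatively rank-correlated (≈ −0.56 at defaults) for any
  loading of consistent sign — the sign structure real cohorts show.
* **Demographics.** Conditional on the emergent class: age from truncated
  normals by rejection sampling (Robust 70.0 ± 6.2 y on [61.2, 91.9] …
  Frail 77.7 ± 7.8 y on [61.4, 96.8]; the published spreads are treated as
  SDs), sex and five binary covariates (living alone, fair/poor health,
  chronic pain, depressed mood, poor vision) from per-class prevalences.
* **Event times.** Constant (exponential) hazards per class and endpoint,
  `λ = −ln(1 − f)/horizon` with horizon 93 months. Death fractions `f` are
  9.5 / 22.3 / 27.3 / 35.8 %. Nursing-care onset has no directly published
  class-specific incidence, so its fractions (2.5 / 3.6 / 10.7 / 22.5 %)
  are a loose, order-preserving calibration borrowed from wave-2 survivor
  percentages; treat nursing-care magnitudes as qualitative. A Weibull
  shape hook is present in the config for non-constant hazards
  (default 1 = exponential).
* **Wave-2 reconciliation.** Death is decided by the hazard model (event
  time ≤ horizon) and has priority. Among survivors, lost-to-follow-up and
  refusal are drawn at four-class granularity with conditional
  probabilities renormalised so the *unconditional* class fractions hit
  their targets; remaining survivors draw a class destination (or a small
  unscorable remainder) from the pooled-class transition row renormalised
  over non-terminal outcomes. When hazards, censoring and transition rows
  are mutually consistent — as the defaults are — the composite reproduces
  the full transition rows exactly in expectation; when a user makes them
  inconsistent, the hazard wins for death. The raw, unreconciled row draw
  is retained in `wave2_outcome_raw` for audit. The stay-probabilities of
  the Transient and Frail rows are row remainders (not directly
  published); the Robust row includes a 0.9 % unscorable remainder so its
  published fractions sum to 100 %.
* **Censoring.** Lost-to-follow-up censors both endpoints at a
  Uniform(0, horizon) time. Refusal at wave 2 does **not** censor the
  survival endpoints, because death and nursing-care status are modelled
  as registry-ascertained at the reference date for everyone still in the
  study; refusal only removes the wave-2 questionnaire. Death before
  nursing-care onset censors the nursing endpoint at the death time
  (simple censoring; competing-risks modelling is out of scope, so
  nursing-care survival curves are interpretable as cause-specific).
* **Wave-2 questionnaires** are regenerated by accept–reject: redraw
  `z' ~ N(0,1)`, generate answers, score, accept when the scored pooled
  class matches the drawn destination (capped at 200 vectorised rounds; a
  class the item model cannot reach raises a calibration error rather than
  looping forever).
* **Determinism.** One global seed spawns six named substreams (latent
  trait, items, demographics, events, transitions, wave-2 records), so a
  (config, seed) pair yields byte-identical CSV output and stages can be
  re-run independently.

What the generator does *not* emulate: item-level heterogeneity beyond the
shared intercepts, non-proportional hazards and the late divergence of the
middle classes, correlation between covariates given class, informative
censoring, and any intervention effect. Passing tests on simulated cohorts
therefore demonstrate that the machinery is correct and that *calibrated*
structure is recovered — not that real-cohort magnitudes (a specific
log-rank chi-square, a specific rank correlation) would be reproduced.

## Statistical machinery

* **Life-table analysis** defaults to the product-limit (Kaplan–Meier)
  estimator (wrapping `lifelines`); an actuarial interval estimator with
  the half-interval censoring adjustment is exported as the alternative,
  since "life table" is ambiguous. An all-censored sample returns
  S(t) ≡ 1 with a warning flag rather than an error.
* **Log-rank test.** In-package O/E/V computation (the result type
  reports per-group observed and expected events, which wrapper libraries
  do not expose), statistic `(O−E)ᵀ V⁻¹ (O−E)` on k−1 components against
  chi-square(k−1); a singular covariance falls back to a flagged
  generalized inverse. Cross-checked in tests against both a brute-force
  loop implementation and `lifelines.statistics.multivariate_logrank_test`.
* **Cox regression** wraps `statsmodels` `PHReg` (Newton/quasi-Newton on
  the partial likelihood). Efron tie handling by default, Breslow by flag.
  The class factor enters as three dummies against Robust; its
  likelihood-ratio test compares the adjusted model with and without the
  dummies (3 df) — i.e. the class factor is added *last*, on top of age,
  sex and self-reported health. Monotone likelihood (complete separation)
  is reported as a convergence error when any |log HR| exceeds 15;
  rank-deficient designs and event-free samples are rejected up front.
* **Exact tests.** 2×2 Fisher via the hypergeometric distribution
  (scipy); 2×k via exact enumeration of all tables with the observed
  margins when the grand total is ≤ 200, otherwise a Monte-Carlo exact
  test sampling fixed-margin tables (`scipy.stats.random_table`, fixed
  substream seed, MC standard error reported). Two-sided p sums the
  probabilities of tables no more probable than the observed one (with a
  1e-9 log-scale tie tolerance).
* **Spearman / Welch.** Mid-rank Spearman with t-approximation p-values
  and complete-case pair handling; Welch t with Satterthwaite df. Zero
  variance is flagged as degenerate rather than silently propagated.

## Problem sizes

The validation battery uses: an exhaustive 2048-vector sweep for the
classification grid; n = 10,000 for generator calibration (binomial SE
≈ 0.5 pp on the largest share, comfortably inside the ±2 pp band);
n = 20,000 uncensored draws for the product-limit closed-form check
(sup-error ≲ 0.01); 2000 null simulations at 50/group for the log-rank
type-I error (95 % envelope 0.050 ± 0.0096); and 2000/group for Cox
recovery of log HR = ln 2 within ±0.1. The Monte-Carlo Fisher
cross-check uses 3 × 10⁵ draws, giving an MC standard error well below the
agreement tolerance.

## Known limitations

Constant hazards cannot reproduce the observed late divergence of the
preFrail and Frail survival curves; the transition model is memoryless in
the pooled three-class space; nursing-care incidence is calibrated
loosely; and the ordinal class encoding for correlations is an assumption.
These are deliberate simplifications of a validation harness, not claims
about the underlying cohort.
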