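# Methods

## Model

The postoperative death hazard is modelled as a join-point (change-point)
function of days since surgery `t`:

    h(t) = b + (a − b)(τ − t)/(τ − t₀)   for t₀ ≤ t ≤ τ,
    h(t) = b                             for t > τ,

with acute rate `a`, background rate `b` (`a ≥ b ≥ 0`, events per
person-day internally; ×1000 at reporting boundaries only), join point
`τ > t₀`, and origin `t₀ = 3` days. The decline is linear on the hazard
scale. The origin is a fixed configuration value, not an estimated
parameter: the empirical daily hazard of cohorts like this peaks on days
3–5, and deaths on days 0–2 are excluded from modelling (they are
overwhelmingly intra- and immediately post-operative deaths with a
different generating mechanism). The cumulative hazard has a closed
quadratic/linear form, and its inverse (quadratic root on the declining
segment, linear continuation beyond) drives inverse-transform simulation.

Assumptions worth stating: the hazard is non-increasing (an increasing
acute segment is outside scope and the constraint `a ≥ b` is hard);
follow-up ends administratively at the horizon (180 days; 360 for the
late-window check); deaths on the same registry day enter the likelihood
as independent exact ties (continuous model, daily data, no tie
correction); and all subjects in a fitted stratum share one parameter
triple (no covariate effects — heterogeneity is handled by stratified
refits, not regression).

## Likelihood and fitting

For subject `i` with follow-up `t_i ≥ t₀` and event flag `δ_i`, the
right-censored, left-truncated-at-origin log-likelihood contribution is
`δ_i log h(t_i) − H(t_i)` with `H` the cumulative hazard from `t₀`.
Early deaths must be excluded upstream; the likelihood refuses times
before the origin rather than silently truncating.

At a fixed `τ`, writing `d = a − b ≥ 0` and `w_i` for the normalized
decline weight, the likelihood is concave in `(b, d)`; it is maximized by
a safeguarded Newton iteration with an explicit KKT check for the flat
boundary `d = 0` (where `b` has the closed form events/person-days).
Following a deliberately deterministic multi-start (the overall event
rate, doubled and halved) guards the line search. `τ` itself is profiled:
a 0.5-day grid over (origin, horizon] with warm-started inner fits, then
bounded scalar refinement to 0.01 days. The grid-plus-refine design
reflects that the profile in `τ` is only piecewise smooth (kinks where
`τ` crosses an observed event time), so derivative-based search from one
start is not trustworthy. Convergence is declared when the refinement
bracket is below 0.01 day; a fit is flagged `boundary` when the join
point lands at a search edge or when the constant-hazard submodel lies
within the χ²₂ 95% band of the maximum — in that case the decline is not
identified and the triple should not be over-interpreted (an unpenalized
change-point MLE happily absorbs a short noise spike near the origin).

## Confidence intervals and tests

Intervals invert the likelihood-ratio test: the 95% interval for one
parameter collects values whose profile log-likelihood (other parameters
re-maximized, including `τ` when a rate is profiled) stays within
χ²₁(0.95)/2 = 1.921 nats of the maximum. Endpoints are found by stepping
out from the MLE until the profile drops below the threshold, then Brent
root-finding; a side that never crosses before its search bound (0 for
rates, origin/horizon for `τ`) is flagged unbounded. Profile intervals
are asymmetric, which matches how change-point uncertainty behaves.
Inside CI profiling the `τ` scan uses a coarser 2-day grid (still refined
to 0.01 day) — the nuisance profile is smooth enough that this loses
nothing measurable and cuts cost fourfold.

Group comparisons are nested LRTs: the *overall test* compares one shared
triple against free triples per level (df = 3(k−1)) and gates everything
downstream, mirroring the analysis discipline of testing overall
heterogeneity before parameter-wise contrasts; *parameter equality tests*
share one named parameter across levels with the rest free (df = k−1),
the shared value found by bounded scalar maximization of the summed
per-level profiles. The χ² reference is used for the phase-shift tests as
well, despite the change-point parameter's non-regularity; the
calibration simulations below measure how that works out in practice
(answer: size ≈ 0.04–0.05 at these event counts), which is why no
bootstrap calibration is wired in.

## Synthetic cohorts

The generator emulates a registry extract: per subject it draws a stratum
(site × ASA by default, weights and join-point parameters transcribed
from the published benchmark fits), an event time by inverse-transform
sampling of the stratum's cumulative hazard conditional on survival to
day 3, and covariates (sex, age band, period, stage) from published
per-site margins, independently of each other. On top it plants
day-0–2 deaths (uniform over {0,1,2}, decoupled from the join-point
model), an emergency-surgery fraction, an unknown-status fraction and
sporadic ASA/age missingness at the published rates, and censors
administratively at the horizon. A ground-truth sidecar carries each
subject's stratum, true parameters and latent continuous event time.

Two views of the same draw are exposed deliberately:

- the **registry view** (the CSV): survival recorded as whole days
  (`floor` of the latent time), which is how registries record death
  dates. Re-fitting on this view shows a recording bias of roughly
  −1 day in `τ` and +3% in `a` at these sample sizes — real and worth
  knowing about, and it travels through the pipeline/CLI tests;
- the **model-exact view** (`model_exact_cohort`): latent continuous
  times with only administrative censoring. Estimator-calibration
  experiments (recovery, CI coverage, test size) use this view, because
  they ask whether the estimator behaves as advertised *under the model*;
  mixing in discretization would measure the sum of two effects.

What the generator does not emulate: registry cross-tabulations beyond
the stratifying variables (margins are independent), cause-of-death
structure, long-term survival beyond 360 days, or the smooth empirical
transition around the join point seen in real data (synthetic cohorts are
exactly join-point shaped, so goodness-of-fit diagnostics look cleaner
here than they would on a registry). Passing tests therefore certify the
estimation machinery and pipeline bookkeeping, not the biological
adequacy of the linear-decline shape.

## Empirical diagnostics

Daily empirical hazard: deaths/at-risk per integer day, at-risk defined
so that a subject with follow-up day `d` is still at risk on day `d`
(death/censoring at end of day); days with an empty risk set are
undefined, not zero. Nelson–Aalen cumulative hazard is the running sum of
daily increments with the standard log-transformed normal pointwise
interval (variance Σ deaths/at-risk²); it matches `lifelines` exactly at
event days. No smoothing is applied by default. The 180–360-day check
fits a constant rate (events/person-days) and tests constancy by a
two-segment LRT split at the window midpoint (df = 1, α = 0.05).

## Pipeline conventions

Exclusions run elective → known survival status → truncate at the
horizon; the chain is reported and conserved. Categorization uses the
published inclusive boundaries (ages 0–69/70–79/80+, periods
2007–2011/2012–2016/2017–2020, ASA I/II/III–IV with IV merged into III).
Descriptive percentages use complete-case denominators per factor, with
missingness reported separately; headline fatality percentages are given
under both windowing conventions (deaths on days 3–180, and all deaths to
day 180 including the pre-origin ones), because the two differ and both
are in circulation. Subgroup fits are gated: per-parameter tests and
per-level intervals are produced only when the overall test rejects at
5%, with an explicit `force` override for exploration. Origin and horizon
are configuration values so the pipeline transfers to other procedures
and populations.

## Problem sizes and numerical tolerances

The shipped experiments use: recovery, 20 replicates at n = 56 096;
CI coverage, 200 replicates (tests) / 100 (acceptance script) at
n = 20 000; LRT size, 200/100 replicate pairs at n = 10 000 per arm —
sizes at which the relevant rates are estimated to a few percent while a
full run stays in the minutes range on one core. Closed-form vs
quadrature agreement is asserted at 1e-8–1e-10; the cumulative-hazard
inverse round-trips to 1e-9; inner Newton iterations stop at relative
log-likelihood changes below ~1e-13.

## Known limitations

The linear-on-hazard decline is an interpretability choice; real cohorts
show smoother transitions (documented lack of fit around the join), and
the model offers no alternative shapes. The χ² calibration of phase-shift
inference is asymptotic and checked here only at the simulated event
counts. Day-level recording bias is characterized but not corrected (an
interval-censored likelihood would be the principled fix). Stage in the
default preset is independent of the hazard stratum, so the stage-IV
sensitivity analysis on preset data exercises plumbing more than
epidemiology; the dedicated test plants a genuinely different stage-IV
hazard to verify the direction of the effect.
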