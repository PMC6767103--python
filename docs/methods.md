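# Methods

## Model and update rule

Each strand n estimates μ_{i,b}, the failure probability at gate t_n for a
baseline patient, from a stream of risk-adjusted Bernoulli outcomes.  The
underlying state model is "mean steady": a priori E[μ_i] = E[μ_{i−1}] while
the prior precision decays by a factor κ per step, P[μ_i] = κ·P[μ_{i−1}].
The posterior mean under this model is the EWMA

    m_i = κ m_{i−1} + (1−κ)(y_{i,j} − μ̂_{i,j} + μ̂_{i,b}),

and the posterior precision tends to the steady state 1/(1−κ), which we use
from the first monitoring update (no transient precision schedule — the
steady-state simplification keeps the credible limits a fixed-width function
of m alone).

Risk adjustment assumes proportional odds across risk scores at each gate:
a patient with score z has odds exp(β(z−z_b)) times the baseline odds.  The
current baseline rate is taken to be the previous chart value m_{i−1}, so
the patient prediction is

    μ̂_{i,j} = odds/(1+odds),  odds = m_{i−1}/(1−m_{i−1}) · e^{β̂(z_j−z_b)},

which is exactly m_{i−1} when z = z_b or β̂ = 0.  The adjusted value
y − μ̂_{i,j} + μ̂_{i,b} is unbiased for the baseline rate when the risk model
is correct; it may legitimately fall outside [0, 1].

Credible limits are percentiles of the conjugate Beta with mean m_i and
precision (shape sum) 1/(1−κ): shapes a = m/(1−κ), b = (1−m)/(1−κ).  A
strand signals "up" when the target lies strictly below the lower percentile
and "down" when strictly above the upper one; a target exactly on a bound
does not signal (a measure-zero event, resolved conservatively).  Signals
are reported per strand; there is no combined-alarm rule.

## Event scheduling and patient ordering

Strand n updates for patient j at calendar time surgery_time_j + t_n,
carrying y = 1 exactly when a death occurred at or before t_n (inclusive
boundary; censored survivors contribute y = 0 at every gate).  Scheduling on
the surgery clock is what preserves surgery ordering within each strand in
continuous time: a patient who dies within minutes of surgery still enters
the 30-day strand only 30 days after their surgery, by which time the
longer survivals of neighbouring patients are ready to be weighed in
against the early failure.  Within a strand, simultaneous surgeries keep
their input order (stable sort).  Events whose calendar time exceeds the
observation horizon are omitted rather than imputed — their outcome is
simply unresolved.  A consequence tested explicitly: a strand with gate t_n
is blind to anything that happens after t_n days post-surgery.

The per-strand update index i counts that strand's own updates, not global
events.

## Calibration

* **Baseline score z_b** — the median pilot risk score, shared by all
  strands.  For an even pilot count the mean of the central pair is rounded
  half-up so the baseline remains a valid integer score.
* **Per-gate logistic fits** — maximum likelihood of the gate-failure
  indicator on (z − z_b) (statsmodels `Logit`).  m0 is the fitted
  probability at z = z_b (inverse-logit of the intercept), not the raw
  pilot failure fraction.  Perfect separation or a constant score raises a
  calibration error advising a wider pilot window; a `penalize=True` flag
  switches to a weak ridge fit for tiny pilots instead of failing.
* **κ selection** — default is the guide formula κ = 0.993 − 0.192·m0,
  which was developed for processes with small failure rates; alternatively
  κ can be chosen per strand by minimising the one-step prediction MSE of
  the EWMA replayed over the risk-adjusted pilot stream on a grid (default
  0.900 … 0.999 in steps of 0.001).  For Bernoulli-like data the MSE curve
  flattens as κ → 1, so ties (within 1e−12) are broken toward the larger κ.
  The MSE replay adjusts pilot outcomes relative to the fixed pilot rate m0;
  this decouples stream construction from the κ being scored.
* **Targets** — default to each strand's m0; overridable per strand.
  Credible percentiles default to the symmetric 95% pair (0.025, 0.975);
  asymmetric pairs (e.g. 0.05/0.975 to emphasise deterioration) are a
  configuration choice.

## Numerical choices

* m is clamped to [1e−6, 1 − 1e−6] after every update, because adjusted
  values are unbounded and the Beta mean must lie strictly inside (0, 1).
  At the clamp the Beta shapes become extreme and both percentiles can
  underflow toward the same endpoint; the interval stays ordered (lo ≤ hi).
* Chart CSVs are written with 17 significant digits and read back with
  round-trip float parsing, so write∘read is the identity on all numeric
  fields.
* Censored records are normalised to survival_time = d on write; records
  censored *before* d (early loss to follow-up) are rejected at validation
  time rather than silently interpreted — the model has no notion of early
  drop-out.

## Synthetic-data generator

`synth_cohort` emulates the structure of post-cardiac-surgery monitoring
data: homogeneous Poisson arrivals (default 3.2 patients/day, roughly 7 000
patients over six years); integer risk scores from a negative-binomial pmf
(shape 1.5, mean 7) truncated to 0–70, giving the long right tail typical of
Parsonnet scores; a 30-day death indicator whose odds scale as
exp(β_true(z − z_ref)) from a baseline rate m30 (defaults β_true = 0.07,
m30 = 0.05 at z_ref = 7, within the small-failure-rate regime the chart is
designed for); conditional death times from a Weibull(shape 0.5, scale 30)
truncated to (0, 30], front-loading deaths into the first days after
surgery so that the short gates carry rates near 1% and the 30-day gate
near 5%.  Process deterioration divides death times by an acceleration
factor q ≥ 1 (accelerated-failure-time convention).

What the generator does **not** emulate: correlations between consecutive
patients, seasonal or secular drift in case-mix, miscalibrated risk models
(the generating model and the fitted model share the logistic form, so
calibration tests measure estimation error only), discrete bursts of
arrivals, or early loss to follow-up.  Passing tests on this generator
therefore demonstrate correctness of the chart mechanics and calibration
machinery, not robustness to risk-model misspecification on real data.

`bootstrap_stream` instead resamples observed (survival time, score) pairs
without replacement from a supplied cohort, reshuffling and continuing when
more patients are requested than the source holds.  Deaths are accelerated
by q; a source record censored at d stays censored — its true survival
beyond d is unknown, so acceleration cannot honestly turn it into a death.
A recorded death remains a death when its accelerated time is within the
window (inclusive at d, consistent with the inclusive gate boundary).

## Run-length evaluation

A run feeds one fresh stream through the chart (state starting at m0 with
steady-state precision — no per-run pilot replay) and records the first
signal across all strands.  The default unit "patients" counts the patients
whose surgery precedes (≤) the first signal's calendar time; unit "days"
records that calendar time itself.  Both are computed because the natural
unit of a continuous-time chart's run length is genuinely ambiguous.  Runs
with no signal are censored at the horizon and treated as ≥ horizon when
taking the median; the censored fraction is always reported and the median
is flagged when at least half the runs were censored.  The q-grid evaluator
reuses one base seed across q values (common random numbers), pairing runs
so that monotonicity comparisons are low-variance.

Default problem sizes: the acceptance script uses 50 000-patient pilots,
300 chart runs of 1 000 patients per q for the STRAND chart and 150 for the
uEWMA; the test suite's run-length study uses 500 paired runs of 1 000
patients per q.  These sizes give Monte-Carlo error comfortably below the
effects being tested while keeping a full run in tens of seconds.

## uEWMA comparator

The comparator weights each patient's current contribution by recency of
surgery: S_t = Σ_r k(1−k)^r · S_{J−r,t} over patients ordered by surgery
time.  Defaults follow the 30-day-survival variant: k = 0.01, lower
reflecting barrier h_l = 0.01 applied to the aggregate statistic
(S ← max(S, h_l)), upper signal barrier h_u = 0.048, initial value
S_0 = 0.025.  Two choices here were genuinely open and are this package's
own:

* the per-patient score is the risk-adjusted 30-day death indicator
  y − μ̂_j + μ̂_b (sharing the STRAND adjustment convention, with μ̂ computed
  from the fixed pilot rate m0), and an unresolved patient contributes its
  null expectation μ̂_b until its 30-day status is known.  Note a resolved
  survivor's score is ≈ 0, so an all-survivor stream's statistic decays
  after the censoring window passes;
* the initial value enters the recomputed cross-sectional sum as a fading
  remnant (1−k)^{J_t}·S_0, so S equals S_0 before any patient and the
  geometric closed forms hold in the limit.

Because the original score construction for this chart lives outside the
scope of this package, its run-length curves are a self-consistent
benchmark rather than an exact reproduction of published uEWMA values.
The weighted sum may be truncated to the most recent `block` patients; the
default block keeps the neglected tail weight below 1e−12.

## Known limitations

* Single-covariate (scalar score) risk models only; no time-varying
  covariates, competing risks, or recalibration drift correction.
* No CUSUM-based strands and no frequentist control-limit variant.
* Mid-window loss to follow-up is rejected, not modelled.
* The in-control signal rate is governed entirely by credible-interval
  width and placement; users tuning for a specific false-alarm rate should
  widen or narrow the percentile pair until the pilot stream shows few or
  no signals, rather than simulating run lengths under point hypotheses.
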