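# Methods

This note records the models implemented in `fermsense`, the assumptions
behind them, the parameter choices that matter, and what the synthetic
data can and cannot demonstrate.

## Signal conditioning

Probe channels in a sparged, stirred reactor are corrupted by gas bubbles,
so both raw channels are smoothed before any transform with an unweighted
**trailing** moving average over a 0.2 h window. The window is trailing
(half-open, `(t − w, t]`) because the sensor feeds a real-time controller:
a centered window would require future samples. Partial windows at run
start average whatever samples exist; no padding. The smoother exists in
two forms — vectorized (`moving_average`, cumulative-sum based) and
incremental (`StreamingMovingAverage`, deque based) — which agree to
float precision; the closed loop uses the incremental form.

The probe sampling interval is not a physical constant of the problem; we
default to 30 s and expose it (`SimConfig.dt`). Smoothing is applied to
the raw channels first and the inverse transform second. The inverse
transform guards against `T ≤ 1e−9` detector units (opaque culture or
sensor dropout) with an explicit `DegenerateSignalError` rather than an
infinity.

Antifoam is tracked as the **dosed volume of diluted antifoam solution**
as a percentage of the current fermenter volume. The apparent OD of an
antifoam emulsion is strongly dilution-dependent, so volume fraction, not
optical assay of the stock, is the reproducible predictor. We use the
current (simulated) volume at each timestamp, not nominal volume.

## Calibration model

Predictors: `1/MA(T)`, `MA(R)`, antifoam %vol, and the single product
interaction `1/MA(T) × MA(R)`. The interaction form is the minimal one
consistent with transmission–reflection cross-terms contributing to the
fit; higher-order products are deliberately excluded.

Fitting is by closed-form least squares on z-scored predictors (z-scoring
makes coefficient magnitudes comparable across channels whose raw units
differ by orders of magnitude, and makes the ridge penalty meaningful).
The intercept is never penalized; because the standardized design is
column-centered, it decouples and equals the training mean of the target.
Numerically we solve the (augmented) least-squares system rather than the
normal equations verbatim — the identical solution without squaring the
condition number of a nearly collinear design. Rank deficiency at λ = 0
is detected by pivoted QR and reported with the names of the offending
columns. Zero-variance predictors are rejected for either estimator.

The default ridge penalty is λ = 1 on standardized features; it is a
conventional mild-shrinkage default, not an optimized value, and is
exposed everywhere. Variable importance is the normalized absolute
standardized coefficient — the simplest importance notion that is
well-defined for a linear model; no claim is made that it matches any
proprietary AutoML importance metric.

Evaluation uses a single uniformly random 80/20 train/test split
(train size `floor(0.8 n)`), reproducible under a seed. Residuals are
`predicted − observed`; the residual SD uses the unbiased (n−1)
denominator. Train, test, and pooled metrics are all computed; the
portable model artifact stores the **test** metrics, and the prediction
band `y + residual_mean ± residual_sd` is built from them. Predictions
are clamped below at zero: an uninoculated fermenter reads inline OD 0,
never a small negative number. Note the clamp is applied after the linear
map, so clamped predictions are not used inside the fitting itself.

The pooled operator variability (`percent_deviation`) is the coefficient
of variation — 100 × sample SD / grand mean — over all operator × sample
readings. It sets the accuracy floor any inline model should be compared
against: repeated human measurements of the same broth already disagree
at the few-percent level.

## Simulator

The simulator is forward Euler at the sampling interval `dt` (default
30 s). The dynamics at these time constants (hours) are far slower than
the step, and tests verify key outcomes against a 10×-finer independent
integration; an adaptive ODE solver would add nothing.

Phases and kinetics:

* **waiting** (default 1 h): no biomass; channels sit at their
  clean-medium levels. Inoculation is time-based.
* **batch**: Monod growth `dX/dt = μ_max X S/(K_s + S)` with
  `dS/dt = −(1/Y_xs) dX/dt`. Defaults: `od0 = 0.2`, `μ_max = 0.6 /h`,
  `s0 = 20 g/L`, `K_s = 0.1 g/L`, `Y_xs = 1.25 OD per g/L` — a typical
  glucose-limited *E. coli* batch that exhausts at OD ≈ 25 after ≈ 8 h.
* **fed-batch**: exponential feed `F = F0 · e^{μ_set (t − t_feed)}`
  (`F0 = 15 mL/h`, `μ_set = 0.15 /h`); biomass grows at `μ_set`; volume
  integrates feed plus antifoam boluses. Substrate is not tracked in
  fed-batch — the feed law *is* the growth-rate controller.
* **induction**: growth continues at `μ_set × induction_mu_factor`
  (default 0.8, a modest attenuation typical of soluble, non-toxic
  products).

Dissolved oxygen is algebraic: `DO = clip(100 − g · μX, 5, 100)` with
`g = 3.2` %-points per (OD/h) of uptake. This is the simplest model that
produces the load-bearing phenomenology: DO sags as uptake rises, and
when glucose runs out uptake collapses and DO snaps back — the
exhaustion spike. With the defaults the batch-end spike is a ≈ 45-point
rise within ≈ 0.1 h, and the induction-time growth attenuation produces
only a ≈ 10-point rise, so the 20-point spike detector fires exactly
once per run. Oxygen transfer (kLa), pH, and acetate overflow are out of
scope.

Optics: `T = c_t / (1 + k_t (OD + γ·AF%))` and `R = r0 + r1 OD + r2 AF%`
with defaults `c_t = 100`, `k_t = 0.5`, `r0 = 2`, `r1 = 1.2`, `r2 = 5`.
The reciprocal transmission law is chosen so that `1/T` is *exactly*
linear in OD — which makes noiseless parameter recovery a sharp,
machine-precision test of the whole pipeline rather than an approximate
one. γ (equivalent OD per antifoam %vol on the transmission channel)
defaults to 3 and is overridden per antifoam stock (see below); the
antifoam optical effect is a free parameter of the generator, not a
calibrated fact.

Noise: per-sample multiplicative Gaussian noise (SD 2 %) on each channel,
plus bubble artifacts with probability 0.01 per sample that multiply
transmission by U(0.6, 0.9) (a dip) and reflection by U(1.5, 2.5) (a
flare). Bubbles scatter strongly, so they hit the backscatter channel
harder — this asymmetry is what makes inverse transmission the
highest-importance predictor in pooled fits, and it motivates the moving
average in the first place. Offline references get absolute Gaussian
noise (SD 2.0 OD600, floored at 0): offline OD at harvest densities
requires serial dilution, and that assay plus operator spread is the
dominant error source. Under these settings a variance budget puts the
feature-side error near 1 OD — below the offline noise floor — so
held-out RMSE lands near, and below, the mid-2s.

Probe-to-probe variation multiplies every optical coefficient by an
independent factor in 1 ± `probe_jitter`. The default is ±1 %: a pooled
multi-probe model shows probe-invariant accuracy only if probe optics are
repeatable to well under the offline noise floor (a ±10 % coefficient
spread would put probe-systematic errors near 8 % of reading — an order
of magnitude above what a pooled model with mid-2s RMSE at OD ≈ 100 can
tolerate). The field repeatability of factory-calibrated optical density
probes is consistent with the ±1 % default.

### Training-corpus campaign

`generate_training_corpus` emulates a realistic calibration campaign:
15 runs round-robin across 5 jittered probes; two antifoam stocks
alternate across runs (concentrated: 2 mL boluses, γ = 3; dilute: 6 mL
boluses, γ = 1) with boluses every 1.5 h through the fed phase; induction
targets spread linearly over 55–120 OD so the corpus spans true OD 0 to
above 140; and offline sampling excludes simulated hours 3–14 (the
overnight gap), clustering references at run start and from the next
morning to harvest. 159 offline points are allocated round-robin across
runs.

### What the synthetic data does not capture

Probe fouling and drift, filamentation or other morphology changes (which
alter the optics–biomass relationship), undefined/cloudy media,
scale-dependent hydrodynamics, and real bubble statistics. Passing the
synthetic acceptance battery shows the *pipeline* is correct and that the
stated accuracy is achievable under the modeled noise processes — it is
not evidence about any particular real reactor/probe pair.

A structural consequence worth knowing: on noiseless constant-OD plateau
data the four-term predictor set is exactly collinear (inverse
transmission, reflection and antifoam %vol are all affine in the two
underlying factors OD and AF%), and the fit correctly refuses it as
singular. Machine-precision parameter recovery is therefore demonstrated
on the minimal identifiable pair (inverse transmission + reflection);
the redundancy of the full set is broken only by measurement noise.

## Controller

Feed trigger: a trailing DO minimum over a 0.1 h window; a rise of ≥ 20
percentage points above that minimum within the window marks glucose
exhaustion and starts the feed, once.

Induction trigger: after feed start, a counter of consecutive
evaluations with inline OD ≥ target; any sub-target evaluation resets it.
At `debounce_n` (default 3) the controller fires, atomically and in
order: `INDUCTION_TRIGGER`, `BI_SAMPLE` (volume withdrawal; the stored
sample is how the trigger OD gets verified offline the next morning), an
optional condition-adjustment hook (no-op by default), `IPTG_ADD`
(volume addition; the simulation switches to the induction phase). All
events are latched single-shot; stepping a harvested run is an error.
The debounce is a deliberate robustness addition over a bare threshold
rule — a single bubble artifact must not induce a reactor — and
`debounce_n = 1` recovers the bare rule exactly. Harvest is emitted at
the configured run end, not on an OD criterion.

`control_dt` can thin controller evaluations below the sampling rate;
by default every sample is evaluated.

## Numerical and interface choices

* Trailing-window boundary half-open `(t − w, t]`; ties impossible on a
  strict time grid.
* Times are hours (floats); CSVs use `.` decimals, no thousands
  separators; schemas are header-name keyed, order-independent; parse
  errors carry file line numbers.
* Model artifacts are JSON with a schema version; version mismatches are
  explicit errors, and round-trips preserve coefficients bit-exactly.
* Run bundles carry `{seed, config SHA-256, schema version}` so any
  simulated artifact is regenerable bit-identically from one command.
* All stochastic paths draw from one `numpy` Generator per run, seeded
  from the config; noiseless configs skip the generator entirely, so
  noiseless outputs are identical across seeds.

## Problem sizes used in the shipped checks

The acceptance battery uses the full campaign geometry (15 runs / 159
offline points / 5 probes) and aggregates over ten seeds, which keeps the
whole battery in the tens-of-seconds range on one core; single-run tests
use shorter horizons (2–21 h at 30 s sampling). These sizes are the
package's own test design; all of them are parameters, not limits.

## Known limitations

* The calibration is a global linear model; it inherits every
  transferability caveat of OD itself (extinction-coefficient changes,
  cell-shape changes under stress, instrument-to-instrument
  spectrophotometer differences).
* The prediction band is a mean ± SD residual summary, not a calibrated
  predictive distribution.
* The simulator's DO is algebraic (no gas-transfer dynamics), its feed
  law is ideal, and its bubble model is i.i.d.; none of these are claims
  about real reactors.
* One 80/20 split, as in the modeled workflow — no cross-validation
  machinery is provided.
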