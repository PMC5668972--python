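# Methods

## Model and identification

The package treats the respiratory system as a single compartment whose
airway pressure balances elastic, resistive and baseline terms,

    P(t) = Σᵢ Eᵢ φᵢ(P(t)) V(t) + Σⱼ Rⱼ V̇(t−j) + P₀(t),

with i = 1..M basis functions of pressure and j = 0..L flow lags at the
50 Hz sampling rate. Two configurations are used: M = 4, L = 170 (the
nonlinear NARX model, 175 coefficients, 3.4 s of flow history) and
M = 1 (constant basis), L = 0 — which is exactly the first-order model
P = R V̇ + E V + P₀. The lag sum is implemented over j = 0..L inclusive
(L + 1 terms); `NarxConfig.include_lag_zero=False` switches to the
alternative reading in which L counts the resistive terms (lags 1..L).

The four basis shapes (constant, linear `P/50`, exponential `e^(−0.04P)`,
sigmoid centred at 28 cmH2O with slope 0.25) are frozen; only their
weights are fitted. Together they can represent the elastance profiles
seen across a recruitment manoeuvre: a recruitment-dominated fall at low
pressure (exponential), a distension-dominated rise at high pressure
(sigmoid and linear). No sign constraints are imposed on any coefficient;
negative weights are legitimate and are surfaced in the model JSON.

Both models are linear in their coefficients once measured pressure is
substituted into the basis functions, so a training window gives a linear
system **Ax = b** with b = P − P₀. Design-matrix rows whose lag history
would cross the record start are dropped, not zero-padded (padding would
bias the resistance kernel). P₀ is piecewise constant at the nominal PEEP
of each sample's detected PEEP step.

### Solving the system, and when to truncate

`identify` solves by SVD pseudoinverse with a relative singular-value
cutoff of 1e-10 by default: deterministic minimum-norm behaviour on the
heavily collinear lagged-flow block, and exact recovery on clean,
consistent data (verified to ~1e-13 relative on noiseless full-rank
round trips).

On noisy recordings a different hazard appears. Over the ~15 cmH2O
pressure range of a short training window the four basis functions are
nearly affinely dependent, so the elastance block contributes a
near-null singular direction. Measurement noise (and, for real lungs,
model mismatch) projects onto that direction amplified by 1/σ, producing
mutually cancelling coefficients of order 10³ whose *interpolation* is
fine but whose *extrapolation* is absurd — sometimes steep enough that
the implicit pressure equation has no solution at all. The protocol
runner therefore defaults to a discrepancy-based truncation
(`rcond="adaptive"`): keep the fewest leading singular directions whose
training residual is within 2% of the full solution's. On clean data
every direction earns its keep and nothing is truncated; on noisy data
exactly the noise-amplified directions are dropped (their removal changes
the training fit in the third decimal). A fixed larger cutoff does not
work: 1e-4 fails to track the noise level as the window grows, and 1e-3
discards genuinely informative elastance directions.

## Forward prediction

Prediction runs the identified model generatively on the flow measured at
the target PEEP step (the model is a transfer function from flow to
pressure; no ventilator settings are used). Volume is re-integrated from
the target-step flow with drift compensation, and P₀ is the target PEEP.
Because elastance depends on the pressure being computed, each sample
requires solving P = E(P)·V + (resistive term) + P₀. The solver brackets
±30 cmH2O around the previous sample's pressure, scans a 25-point grid
for sign changes (widening up to [−120, 250] cmH2O if needed), picks the
sign change nearest the previous pressure when several exist, and
refines with Brent's method (xtol 1e-12, ≤ 200 iterations). Agreement
with a dense-grid (0.001 cmH2O) root-search oracle is ≤ 0.001 cmH2O.

When the identified elastance term outruns pressure across the entire
search range the equation has no root; the per-sample solver raises
`SolverError` carrying the sample index and the divergence direction.
The protocol runner converts that divergence into a *saturated*
prediction at the search-range edge (150 cmH2O high, −20 low) and flags
the result: a model predicting off-scale-high pressure is, clinically, a
positive prediction, and discarding such cases would silently bias the
cohort metrics.

Predicted PIP uses the same aggregation as measured PIP: the median of
per-breath pressure maxima over the step (robust to the transient breaths
right after a PEEP change; the choice of median over max/mean/last-breath
is a documented package decision — the aggregation used in the original
clinical analysis is not stated). Breaths whose lag history is not
available (only possible at the very start of a record) are excluded from
the median.

## Waveform preprocessing

* **Breath segmentation**: inspiration onset at an upward flow crossing of
  +0.02 L/s, accepted only after flow has dipped below −0.02 L/s since the
  previous onset (hysteresis against sensor noise); inspiration ends at
  the first crossing below −0.02 L/s. A trailing breath is kept when its
  expiration has begun. Indices are 0-based, intervals half-open.
* **Volume**: cumulative trapezoidal integration of flow with a linear
  ramp subtracted per breath so volume is exactly 0 at each breath's first
  and last sample — the simplest scheme meeting the clinical convention of
  re-zeroing volume at PEEP.
* **PEEP steps**: consecutive breaths group while their end-expiratory
  baseline (median pressure over the final 10% of the breath) stays within
  1.0 cmH2O (half a step) of the group's running median; the step's PEEP
  is the median baseline, its PIP the median of per-breath maxima.

## Virtual patients

The simulator emulates the clinical protocol: PEEP staircase in 2 cmH2O
steps (start 8–16 cmH2O, 5–9 steps), ~10 breaths per step at ~18
breaths/min, 50 Hz, no end-inspiratory pause. Volume-controlled breaths
use square inspiratory flow over the first third of the cycle and a
passive exponential expiration whose amplitude is adjusted per breath so
the within-breath trapezoidal flow integral is exactly zero (volume
returns to 0 every breath). The expiratory time constant is R·C capped at
T_exp/8 (≈ 0.28 s — physiological for stiff ARDS lungs) so exhalation is
complete at end-expiration; residual expiratory flow would otherwise bias
the measurable PEEP baseline by R·V̇ and make the training system
systematically inconsistent. Pressure-controlled breaths prescribe a
square pressure target (with a 3-sample rise) and integrate
V̇ = (P − E(P)V − PEEP)/R by a midpoint rule.

True elastance is either an `ElastanceCurve` (inside the identification
basis span — used for exact round-trip tests) or a sigmoid-plus-quadratic
`RecruitmentElastance` deliberately *outside* it, so model-vs-truth
comparisons are honest. Elastance must be positive over the simulated
range, and cohort draws keep the distension steepness max dE/dP below
~1.3 cmH2O/L per cmH2O: with tidal volumes near 0.5 L a steeper
pressure-parameterised E(P) makes the quasi-static balance
P = E(P)V + R V̇ + PEEP genuinely rootless — a known breakdown of the
pressure (rather than volume) parameterisation, not a plausible patient.

Stochastic elements, all drawn from one seeded `numpy` PCG64 generator
per simulation: Gaussian pressure noise (sd 0.5 cmH2O, on the recorded
pressure only), Gaussian flow-sensor noise (sd 0.005 L/s, on the
*recorded* flow only — the lung is driven by clean flow), per-breath
tidal-volume/driving-pressure jitter (3%) and breath-timing jitter
(±0.08 s). The jitter matters beyond realism: on exactly periodic flow
the lagged-flow regressors span every breath-phase signal, making the
elastance columns collinear with them within a single PEEP step and the
identification degenerate; real ventilator data is never exactly
periodic. The flow noise similarly keeps the lag block numerically
well-conditioned, as real pneumotach data is.

The cohort generator draws baseline elastance U(10, 22) cmH2O/L, sigmoid
rise U(15, 45) centred U(32, 46) cmH2O, quadratic term U(0, 6),
resistance U(5, 20) cmH2O·s/L, tidal volume U(0.35, 0.55) L, driving
pressure U(10, 18) cmH2O, and ventilates each patient in
pressure-controlled mode with probability 0.6 (else volume-controlled),
approximating the 7:3 clinical ratio. These ranges put roughly half the
datasets across the 40 cmH2O line. If an outcome class is entirely
absent, the last patient is redrawn with shifted baseline elastance.

### What the simulator does not capture

Single-compartment mechanics with breath-wise-constant parameters: no
intra-tidal recruitment dynamics, no patient–ventilator asynchrony, no
airway secretions or auto-PEEP, no multi-compartment heterogeneity, and
noise that is i.i.d. Gaussian rather than structured. Passing tests
therefore demonstrate correctness of the identification/extrapolation
machinery and the *direction* of the NARX-vs-FOM comparison under
plausible nonlinear elastance — not clinical performance figures.

## Classification metrics

Positive means PIP strictly greater than the 40 cmH2O threshold (a
prediction exactly at the threshold is negative). ROC curves sweep the
discrimination threshold over every distinct predicted-PIP value plus
±∞, with AUC by trapezoid over the operating points — equal, to
1e-12, to the Mann–Whitney pairwise concordance with ties counted ½.
Optimal thresholds by closest-to-(0,1) and by Youden's J are tie-broken
toward the higher threshold. ROC and Bland–Altman default to the
single-step (+2 cmH2O) predictions, with a flag for pooled-horizon
curves, since the single-step case is the clinically actionable one.
Reported rates are rounded to two decimals, half away from zero, with
full precision kept alongside; zero-denominator rates are NaN markers,
not exceptions. Bland–Altman summarises d = measured − predicted by its
mean and 25th/50th/75th percentiles (linear interpolation between order
statistics).

## Problem sizes and tolerances

Exact-recovery checks use 2000-sample (first-order) and 2600-sample
(nonlinear, 175-coefficient) records; regression-equivalence uses 100
random records of 50–400 samples; solver and ROC oracles use 100 and 200
random cases. The cohort evaluation uses 50 virtual patients (a few
hundred thousand implicit solves, a few minutes on one CPU) — larger than
the 16-dataset clinical cohort to stabilise the sensitivity comparisons
while remaining quick to run. Tolerances: 1e-9/1e-6 relative for
first-order/nonlinear coefficient recovery, 1e-10 for regression
equivalence, 0.002 cmH2O against the dense-grid solver oracle, 0.05 cmH2O
for noiseless in-class PIP round trips, 1e-12 for AUC identities.
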