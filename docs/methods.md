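# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Task structure and schedules

One session is a stride-indexed sequence (a stride runs left heel strike to
left heel strike) with three phases: baseline (default 250 strides, no
visual feedback, effective target 0 %SAI), learning (500 strides, feedback
on, targets in %SAI), washout (750 strides, feedback off). Conditions differ
only in learning-target consistency: constant 22; LV ~ N(22, 5²); HV ~
U(5, 39). For LV/HV a new target value and an independent hold length
(uniform on {1,…,5} strides) are drawn at each change point; the final hold
may be truncated by the end of the phase. LV draws are not clipped to any
range (N(22,5) essentially never leaves [5, 39]), and the raw change-point
draws are stored on the schedule. Consecutive equal draws are not redrawn.
The brief orientation block some protocols insert after the first baseline
is not modelled: it familiarizes participants with the display and
contributes no analyzed strides. The ±2% step-length width of the target
lines is carried as schedule metadata for hit classification only.

## Model dynamics

Both model families are stride-indexed state-space recurrences; all four
simulators are deterministic and noiseless. Within a session, state persists
across phase boundaries; each session (days apart in the protocol) restarts
from the initial state.

**S+U.** States are the strategy `s` and the use-dependent bias `w`; output
`x = s + w`. The update order per stride is: read `x_n`, form the error
`e_n = t_n − x_n`, emit the output, then update states for `n+1`. The
strategy update `s_{n+1} = A s_n + C e_n` applies only when stride `n+1` has
feedback; otherwise `s_{n+1} = 0`. Gating on the *produced* stride (rather
than the error stride) is required for washout output to be pure
use-dependent bias from its first stride. Two consequences used as oracles:
washout obeys `x_{n+1} = (E + γF) x_n` exactly, and a constant feedback
target drives the system to the fixed point of a 2×2 linear system. The
`C ≥ 5F` ordinal constraint (strategy at least five times faster) and the
modified model's `γ_HV < γ_LV` ordering are enforced at construction and,
during fitting, by reparameterization (`F = r·C/5`, `γ_LV = u`,
`γ_HV = u·v`, with `r, u, v ∈ (0,1)`), so the optimizer's box is the exact
feasible set.

**AB.** State is the adaptive prior (mean `θ̄`, variance `σ²_prior`); the
output is the MAP blend with the likelihood centred on the current target
(0 %SAI without feedback). The prior is initialised at mean 0 with variance
`σ²_lik` (the model is silent on initialisation; starting at the likelihood
uncertainty makes the first stride an even blend and the choice washes out
within tens of strides). A long run of constant targets drives the prior
variance toward zero, so it is floored at 1e-6 (%SAI)²; without the floor
the learning-phase onset weight is ill-conditioned. `σ²_lik` is treated
throughout as a variance with bounds (0, 100). In the modified AB model the
(β, σ²_lik) pair switches with the per-stride feedback flag while the prior
state carries over; the initial prior variance uses the first stride's
regime (baseline, hence the no-feedback value).

## Fitting and model selection

Each model is fit per participant to the concatenated sessions (all strides,
baseline included) by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, `xtol = 1e-12`)
with Latin-hypercube multi-start within the reparameterized box (default 20
restarts; starting points are kept 2% inside the bounds). The recurrences
are numba-jitted, which keeps a full three-session objective evaluation
around 20 µs and a 20-restart fit under half a second.

Selection criteria use the Gaussian profiled-variance forms
`AIC = n ln(SSE/n) + 2k` and `BIC = n ln(SSE/n) + k ln(n)` with k = 4 (S+U),
2 (AB), 6 (modified S+U), 4 (modified AB). The additive likelihood constant
is omitted; only differences between models fitted to the same strides are
meaningful. At n ≈ 4500 strides and residual variance ≈ 12 (%SAI)² these
produce totals near 11,000, the natural magnitude for this design. Washout
restricted scoring re-uses the fitted parameters and recomputes the
criteria over washout strides only, with k unchanged.

Model recovery simulates single sessions per condition from each candidate
with parameters drawn uniformly within their (reparameterized) bounds, adds
i.i.d. Gaussian motor noise (SD 3.5 %SAI — noiseless recovery is degenerate
because the generating model fits itself exactly), refits both candidates
(6 restarts; diagonal outcomes are insensitive to restart count), and
tabulates win proportions per condition and pooled. AIC and BIC matrices
come from the same fits. Bootstrap CIs for group parameters resample
participants with replacement and report the mean of resample means with
empirical 2.5/97.5 percentiles.

## Kinematics

Occlusion gaps are filled with a not-a-knot cubic spline (exact for cubic
trajectories); filtering is a 4th-order Butterworth low-pass at 10 Hz
applied forward–backward (zero phase), since event timing must not lag.
Heel strike is the heel marker's positive-to-negative sagittal velocity
transition and toe off the fifth-metatarsal's negative-to-positive
transition; extrema with prominence below 5% of the marker's range are
discarded as numerical ripple (a stationary marker otherwise produces
spurious crossings after zero-phase filtering). Step length is the sagittal
heel-to-heel distance at leading heel strike; SAI is computed per stride
(left-to-left). Leading limb placement is ankle-minus-hip at that limb's
heel strike, trailing placement hip-minus-ankle at its toe off; asymmetry is
long side minus short side. Small and large gaps are not distinguished —
one spline method serves both.

## Statistics

The one-way repeated-measures ANOVA (via pingouin) reports the standard
degrees of freedom (k−1, (n−1)(k−1)); some reports instead print
participants−1 as the error df, so the result carries both. No sphericity
correction is applied. Pairwise comparisons are paired t tests with
Bonferroni correction and Cohen's d_z. TOST uses symmetric bounds of ±0.3
SDs of the paired differences; equivalence requires both one-sided p values
below α. The cluster permutation test averages strides into 3-stride bins,
runs paired t tests per bin, sums |t| over the largest same-sign run of
significant bins (p < 0.05), and compares that mass with a null built by
per-participant sign flips of the condition difference (the label-exchange
scheme for a paired design); p = (1 + #null ≥ observed)/(n_perm + 1), and
series must be truncated to a common length first. The washout-rate
regression of stride n+1 on stride n includes an intercept — rates are
noise-sensitive and an intercept guards against a nonzero asymptote. The
power routine inverts the noncentral-t power function of a two-tailed
paired t test; at d_z = 0.91, α = 0.05, power 0.90 it returns n = 15.

## Synthetic data

Cohorts default to 18 participants, one session per condition with the
order counterbalanced over all six permutations, SAI = model simulation +
i.i.d. Gaussian motor noise of SD 3.5 %SAI (chosen to match the
constant-condition learning-phase SD near 3.5 observed at asymptote).
Default generating parameters are the bootstrapped group means of each
model's fits; for the modified S+U model the use-dependent retention is set
to E = 0.99, the value consistent with its 95% CI [0.97, 1.0], which
reproduces the observed ~5–6 %SAI initial bias (the group washout bias
scales as γF·x/(1−E) and is very sensitive to 1−E). A jitter option draws
each participant's parameters uniformly within the reported CIs instead.
All randomness flows from one master seed through named substreams
(schedules, noise, restarts, permutations), so cohorts are bit-reproducible
and any participant can be regenerated independently.

Because group-mean parameters underestimate the nonlinear per-participant
bias, and motor noise of 3.5 %SAI is comparable to the between-condition
early-washout differences (~0.2–0.5 %SAI expected gap change), the expected
group washout pattern is estimated by averaging replicate cohorts (20 by
default) rather than from a single cohort, whose gap statistics flip sign
for an appreciable fraction of seeds.

The marker-session generator builds sagittal marker paths as smoothstep
arcs between per-event extreme positions, so ground-truth events sit
exactly at the velocity sign changes and the built-in step lengths are
realized exactly at the event frames; optional white marker noise can be
added. What these fixtures do **not** emulate: real stride-time
variability, soft-tissue and impact artefacts, marker mislabeling, slow
drifts in baseline asymmetry, or history-dependent (non-i.i.d.) motor
noise. Passing tests therefore validate the algorithms and their numerics,
not robustness to every pathology of recorded data.

## Problem sizes and limitations

The validation suite uses desk-scale sizes: 18-participant cohorts for
parameter recovery, 100 simulations per condition per generator for model
recovery, and 1000 null cohorts at 1000 permutations each for the cluster
calibration. Washout-only parameters (E, F in particular) are weakly
identified from short washouts, and the AB likelihood variance is weakly
identified on noisy single participants even when β recovers well; the
recovery checks therefore target the parameters the design identifies (β,
C). Session state is always reset between sessions; carry-over across
days is not modelled.
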