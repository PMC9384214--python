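# Methods

## Model

Plasma insulin and c-peptide are modelled as linearly cleared species driven
by a glucose-dependent secretion input.  The secretion functional is a
three-parameter sigmoid

    u(g) = K_m / (1 + exp(alpha (C_0 − g)))

with maximal rate K_m (μU/ml/min for insulin, ng/ml/min for c-peptide),
midpoint C_0 and inverse width alpha expressed in the glucose unit of the
record (mg/dl or mg/L; conversion is a factor of 10).  Clearance is either a
single plasma compartment, dx_p/dt = u − x_p/τ_p, or a plasma +
interstitial pair with fixed transport rates q1 = 0.0473 min⁻¹ (plasma →
interstitial) and q2 = 0.0348 min⁻¹ (return), each compartment with its own
degradation time.  Both variants are handled as a stable linear state-space
system dx/dt = A x + B u, y = C x with the plasma state observed.

Insulin and c-peptide are treated as fully independent inference problems
that share only the measured glucose.  Their physiological 1:1 molar
coupling (0.056 ng of c-peptide per μU of insulin) is deliberately *not*
imposed; it is reserved as an external consistency check on the results.

## Numerics

The sparse glucose samples are interpolated with a cubic spline (natural
end conditions by default — the zero-curvature ends avoid overshoot at the
sparsely sampled record boundaries; not-a-knot is available) and never
extrapolated.  Negative spline overshoot is clipped at zero with a warning.

The state equation is propagated on a uniform grid (default Ts = 0.1 min)
with the exact zero-order-hold discretization Φ = e^{A·Ts},
Γ = A⁻¹(Φ − I)B (closed form for the scalar case, dense matrix exponential
otherwise).  The held input over each substep is the average of the
secretion rate at the two bounding grid nodes; this trapezoidal sampling
is second-order accurate and keeps the propagated trajectory within 0.02%
of an adaptive-step ODE integration over a 190-min window (verified in the
test suite for both model variants).  The two-compartment recursion runs
through the (always real, almost always distinct) eigendecomposition of A
as two scalar first-order filters, with a stepwise fallback for the
degenerate case.  Initial conditions are the steady state at the first
measured glucose — subjects are fasted at the baseline draw, so the system
is assumed equilibrated there.  Model outputs at measurement times are
taken from the nearest grid node (≤ 0.05 min offset), avoiding a second
interpolation layer.

## Estimation and uncertainty

For one species the cost is the unweighted sum of squared residuals between
the measured concentrations and the simulated plasma output at the
measurement times (points with a missing assay are skipped; the number of
usable points must exceed the parameter count).  Minimization uses bounded
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
method `trf`, ftol = xtol = 1e-10, variables scaled by their bound widths)
inside the physiological box

    τ ∈ [10, 180] min,  K_m ∈ [1, 350],  C_0 ∈ [200, 1500] mg/L,
    α ∈ [0.015, 0.045] per mg/L

(rescaled for mg/dl records; the interstitial τ_i defaults to the τ_p
range).  Because the problem is nonconvex, the fit restarts from `n_starts`
(default 1000) parameter draws sampled uniformly inside the box from a
seeded generator.  A start is *accepted* if it converged, ended strictly
inside the box (relative tolerance 1e-6 of each bound interval — an optimum
pressed against a bound is not a trustworthy physiological estimate), and
its cost is within a factor (1 + cost_rtol), default 2×, of the best
interior cost.  The last rule removes stray local minima orders of
magnitude above the global basin, which would otherwise contaminate the
ensemble mean; basins of comparable quality are retained because their
spread *is* the uncertainty being quantified.  The accepted ensemble yields
mean ± SD for each parameter (95% interval as mean ± 1.96 SD) and for the
plasma and secretion-rate trajectories, tabulated on the 1-min
interpolation grid and at the record's draw times.  Reported trajectories
are means over accepted solutions' trajectories, not trajectories of the
mean parameters.  Everything is bitwise reproducible for a fixed seed.

An ensemble with *no* accepted start raises an estimation error rather than
returning a fabricated value; downstream consumers treat this as an
infinitely bad fit (see screening).

## Goodness of fit and the molar-ratio check

Three normalized error metrics summarize a subject: root-sum-square misfit
of the insulin and c-peptide trajectories, each normalized by the mean of
the measured series, and the root-sum-square misfit of an ordinary
least-squares line CSR ≈ slope·ISR + intercept (evaluated from the
ensemble-mean secretion rates at the draw times), normalized by the maximum
CSR.  These metrics carry no 1/N inside the root, so they are only
comparable between records with equal sampling; the intercept is fitted
rather than forced through the origin.  A slope above the molar constant is
converted to a hepatic first-pass extraction fraction
α_h = 1 − 0.056/slope, clipped at 0 with a sub-molar flag (c-peptide is not
cleared hepatically, so hepatic extraction inflates the slope above the
molar value).  The 0.056 ng/μU constant is used as a fixed unit conversion
and never re-derived.  The secretion rate at a reference glucose (default
140 mg/dl) is evaluated per accepted solution and reported as mean ± SD,
with a warning when the reference exceeds the subject's measured glucose
range (the sigmoid is then extrapolated beyond the expressed range).  An
ECDF utility supports cohort comparisons of these scalars.

## Synthetic subjects

The generator produces ground-truth subjects for validation studies.  A
gamma-pulse glucose excursion g(t) = g_b + A·(t/t_p)·exp(1 − t/t_p)
(fasting baseline g_b before the dose, peak g_b + A at t_p, relaxation set
by t_p; defaults 900 → 1800 mg/L peaking at 45 min) fixes the glucose at
the draw times.  The subject's *true* dense glucose is the cubic
interpolant through those draw-time values — the same representation the
estimator consumes.  This matters: the estimator can never observe
intra-sample glucose structure, and driving the truth with the raw pulse
(whose slope is discontinuous at the dose) would fold a ~7% interpolation
artifact into every recovery study.  With the consistent construction, a
noiseless generate → fit round trip returns the generating parameters to
machine precision, so recovery studies isolate the effect of noise.

Insulin and c-peptide truths are propagated with the same exact
discretization from the fasting steady state.  C-peptide is coupled at the
exact 1:1 molar ratio (K_m scaled by 0.056, shared C_0 and α) with twice
the insulin degradation time by default (c-peptide clears renally and more
slowly); both can be overridden.  Sampled values receive independent
multiplicative Gaussian noise with relative SD `noise_fraction` (default
0.20), clipped at zero; an additive mode (SD = fraction of the series mean)
is available.  An optional corruption multiplies the already-noisy value(s)
at one draw time (default glucose only, factor 0.6 — emulating a spurious
dip to below-baseline glucose).  Everything derives from one seed.

What the generator does *not* emulate: closed-loop glucose–insulin
feedback, meal-absorption physiology, assay-specific error structure
(heteroscedastic floors, carryover), inter-subject parameter variability,
or hepatic extraction (truth slope is exactly molar).  Passing synthetic
studies therefore demonstrates correctness of the inference machinery
under the stated noise model, not clinical validity.

## Validation studies and what they show

**Noiseless closure.**  Generate → fit recovers all parameters (both model
variants) to far better than 0.5%; the multi-start ensemble is degenerate
(every start reaches the same interior optimum).

**Recovery under noise.**  The standard study uses six subjects with
τ_p ∈ {10, 15, 30, 60, 90, 120} min, K_m = 0.6 μU/ml/min, C_0 = 1000 mg/L,
α = 0.01 per mg/L (α and K_m lie below the physiological lower bounds, so
the study widens those two bounds — `synthetic.VALIDATION_BOUNDS`), ten
draw times, 20% noise, five replicates, 100-start ensembles.  At this noise
level the parameters are *not* precisely identifiable from ten samples: a
Cramér–Rao analysis at the generating parameters bounds τ's relative SD at
38–117% (growing with τ) even if glucose were noise-free, because τ and
K_m trade off along a near-degenerate ridge and the sigmoid saturates over
much of the excursion.  The measured errors (τ: ~20–60% replicate averages;
secretion parameters: tens of percent; roughly half the replicates yield no
accepted interior solution at all because the noisy optimum sits on a
bound) are consistent with that bound.  The acceptance suite asserts the
few-percent recovery that would hold only near ~1% noise and is expected to
fail at 20%; the script `scripts/acceptance.py` reports the honestly
measured values.

**Molar-ratio check.**  On noiseless coupled subjects the independently
fitted CSR~ISR slope is 0.056 within 2% with line misfit < 0.02.

**Outlier screening.**  Removing one interior draw (glucose + insulin +
c-peptide) and refitting with identical seeds flags the draw when all three
error criteria improve.  Two design points: (i) the raw root-sum-square
metrics shrink almost surely when a point is removed, so the verdict
compares degrees-of-freedom-adjusted residual scales √(SS)/√(N − p)
(p = model parameter count, 2 for the line), which are comparable across
record lengths; raw deltas are also reported so users can impose a
magnitude threshold.  (ii) a record whose fit is voided entirely (every
start at a bound — typical when a 40% glucose dip places the record outside
the model class) counts as infinitely bad, so a removal that cures the
failure flags the point.  The screening study uses control-like subjects
(glucose 900 → 1400 mg/L, 5% noise, interior generating parameters
τ = 30 min, C_0 = 1100 mg/L, α = 0.015) with a 0.6-factor corruption of the
60-min glucose.  Measured operating characteristics over 20 seeds:
90% detection, 15% false-flag rate on clean records.  The specificity is
limited by the CSR~ISR criterion, which carries almost no signal here —
both species see the same interpolated glucose, so input corruption largely
cancels in the CSR–ISR relation and that delta is near-random.  Endpoint
draws are never screened (their removal would turn interpolation into
extrapolation).

## Problem sizes

Default ensembles are 1000 starts; the validation studies and test suite
use 50–100 starts (the accepted set is degenerate in practice on clean
data) and 5–20 noise replicates, sizes at which every reported rate is
stable to a few percent.  A 100-start single-species fit takes a few
seconds; the full recovery study ≈ 2 minutes on one CPU.

## Known limitations

- τ/K_m (and C_0/α) ridges limit per-parameter precision on realistic
  noise; trajectory-level quantities (fitted curves, ISR at a reference
  glucose within the measured range) are far better determined than the
  raw parameters.
- The boundary-exclusion rule can void an entire ensemble when the true
  optimum sits near a physiological bound; this is reported as an
  estimation failure rather than silently returning boundary values.
- The uncertainty ensemble quantifies sensitivity to initialization (and,
  through it, multi-modality), not sampling error; it is not a bootstrap
  over data and its SDs understate measurement-noise uncertainty when the
  accepted set is degenerate.
- Hepatic extraction is read off the CSR/ISR slope only; no portal-flow
  dynamics are modelled, and insulin-dependent hepatic clearance is out of
  scope.
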