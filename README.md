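# isrfit

Inference of pancreatic insulin and c-peptide secretion rates from sparse
oral glucose tolerance test (OGTT) measurements.

During an OGTT, blood is drawn at a handful of times over ~3 hours and
assayed for glucose, insulin and c-peptide.  `isrfit` treats the insulin
secretion rate (ISR) and c-peptide secretion rate (CSR) as glucose-dependent
sigmoids,

```
u(g) = K_m / (1 + exp(alpha * (C_0 - g)))
```

feeding first-order plasma clearance,

```
dx_p/dt = u(g(t)) - x_p / tau_p          (single compartment)
```

optionally extended with an interstitial compartment (fixed transport rates
q1 = 0.0473, q2 = 0.0348 min⁻¹).  The sparse glucose samples are resampled
with a cubic spline and drive the model as an exogenous input; the unknown
parameters Θ = (τ_p, K_m, C_0, α) are estimated per species by bounded
nonlinear least squares on the measured insulin (or c-peptide)
concentrations.  Because the problem is nonconvex, estimation restarts from
many random draws inside physiological bounds; solutions that converge to a
bound or to a stray high-cost local minimum are excluded, and the surviving
ensemble provides mean ± SD parameters and trajectories.

Because insulin and c-peptide are co-secreted in a 1:1 molar ratio
(0.056 ng per μU in the working units) but fitted *independently*, the
slope of the fitted CSR~ISR line is a built-in external validation; a slope
above 0.056 is read as first-pass hepatic insulin extraction
`alpha_h = 1 − 0.056/slope`.  A leave-one-timepoint-out screen refits the
record without one draw and flags draws whose removal improves all three
goodness-of-fit criteria simultaneously — a signature of a corrupted
measurement.

The package is aimed at researchers modelling beta-cell function from
clinical OGTT panels (e.g., comparing normal and cystic-fibrosis-related
diabetes phenotypes) and includes a fully seeded synthetic-data generator
for validating the whole pipeline against known ground truth.

## Worked example

Generate a synthetic molar-coupled subject (τ_p = 15 min, K_m = 0.6
μU/ml/min, C_0 = 1000 mg/L, α = 0.01 per mg/L, 5% measurement noise) and
fit both species:

```python
import isrfit as f

spec = f.validation_spec(15.0, noise_fraction=0.05, seed=42)
subject = f.generate_subject(spec)
config = f.FitConfig(n_starts=100, seed=0,
                     bounds=f.synthetic.VALIDATION_BOUNDS,
                     cpeptide_bounds=f.synthetic.CPEPTIDE_VALIDATION_BOUNDS)
ens_i, ens_c = f.fit_subject(subject.record, config)
report = f.evaluate_subject(subject.record, ens_i, ens_c)
```

which prints (via the obvious loop over `ens_i.param_names`):

```
insulin tau_p  = 13.29 +/- 4.8e-07
insulin km     = 0.6647 +/- 2e-08
insulin c0     = 980.3 +/- 4e-06
insulin alpha  = 0.01219 +/- 5.5e-10
accepted starts: 100/100
CSR~ISR slope  = 0.0504 ng/uU (molar constant 0.056)
ISR at 140 mg/dl = 0.661 +/- 0.000 uU/ml/min
normalized RMS: insulin 0.106, c-peptide 0.068, CSR~ISR 0.0375
```

All 100 random starts reach the same interior optimum (the tiny ensemble
SDs), the recovered parameters sit within the scatter implied by 5% noise
(τ̂ = 13.3 vs 15 — see the methods note on identifiability), and the
independently fitted secretion rates fall on a line whose slope is within
10% of the molar constant.  With `noise_fraction=0`, all four parameters
are recovered to machine precision.

The same is available from the shell:

```bash
isrfit simulate --tau 15 --noise 0.05 --seed 42 --out-prefix subj
isrfit fit subj_record.csv --config fit.cfg
isrfit screen subj_record.csv --n-starts 100 --seed 0
```

`fit` writes a JSON parameter summary and per-species mean ± SD trajectory
CSVs; `screen` writes a per-timepoint table with the three error metrics
before and after each removal and the improvement flag.

## Input format

CSV with header `time_min,glucose,insulin,cpeptide` (insulin/c-peptide
cells may be empty) and an optional leading metadata line
`# glucose_unit=mg/L, subject_id=...`.  Glucose units are mg/dl or mg/L;
parameter bounds rescale accordingly.

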