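# Methods

## The thrombin dynamics model

A CAT curve — thrombin (nM) versus time after a tissue-factor trigger — is
modeled as the impulse response of a delayed third-order linear system

    Y(s)/U(s) = Kn / (s³ + K₂s² + K₁s + K₀) · e^(−Kd·s)

with `U` a Dirac impulse whose area is the TF dose in pM (default 5 pM, the
conventional CAT trigger).  The model is phenomenological: it captures the
delay, sigmoidal rise, single peak and exponential-like decay of a thrombin
burst with five patient-specific constants, not the stoichiometry of the
cascade.  It is linear in the input by construction, so curves scale
proportionally with the TF dose — a property real CATs only approximate
(real titrations saturate at high TF), and one of the deliberate
simplifications listed under Limitations.

Units: time in minutes, thrombin in nM, TF in pM.  The pM→nM unit mismatch
is absorbed into the gain `Kn` (nM·min⁻³ per pM), which therefore has no
independent physical calibration.

**Simulation** is analytic.  The impulse response of the cubic denominator
is evaluated by partial fractions for distinct poles,
`g(t) = Σᵢ e^(pᵢt) / Πⱼ≠ᵢ(pᵢ−pⱼ)`, with confluent formulas when poles
coincide (double root: `e^(qt)/d² + t·e^(pt)/d − e^(pt)/d²` with `d = p−q`;
triple root: `t²/2·e^(pt)`), and a state-space integration fallback if the
expansion is not finite.  Poles are treated as confluent when separated by
less than 2e−5 (relative to the largest pole magnitude): an eigenvalue
solver resolves a numerically multiple root only to about ε^(1/m) (~1.2e−5
for a triple root), and below that separation the residue cancellation in
the distinct-root formula costs more accuracy than merging the cluster
does.  The dead time is applied exactly, `y(t) = mag·Kn·g(t−Kd)` for
`t ≥ Kd` and zero before, so causality holds to the bit.  Negative
floating-point undershoot is clipped to zero (thrombin is nonnegative).

Default grid: dt = 1/3 min (the 20 s CAT instrument cadence), 60 min
horizon; both configurable.

**Metrics.**  peak and peak-time take the first grid sample attaining the
maximum; areas (ETP, and the post-peak tail sTail) are trapezoidal.  The
onset delay equals `Kd` when the generating model is known; for measured
curves it is the first time thrombin exceeds 2% of peak.  The 2% threshold
is an operational choice — the delay concept is defined through `Kd` and no
empirical onset rule comes with it; 2% is low enough to sit in the
quasi-flat pre-burst region yet above plausible baseline noise.

**Poles** are the roots of `s³ + K₂s² + K₁s + K₀`, computed by companion
eigenvalues, conjugate-symmetrized, and sorted by real then imaginary part.
For this cubic with positive coefficients, stability (all poles in the left
half-plane) is equivalent to the Routh–Hurwitz condition `K₂K₁ > K₀`.

## Identification

`fit_model` minimizes the sum of squared residuals between the simulated
and measured curve with scipy's bounded trust-region-reflective solver
(ftol = xtol = gtol = 1e−9, 2000-evaluation cap).  Bounds:
`K₀,K₁,K₂,Kn ∈ (1e−6, 1e6)`, `Kd ∈ [0, 20]` min — positivity and a bounded
dead time are implied by the shape of any physical CAT, and the box mainly
keeps the solver out of degenerate corners.  `Kd` is a continuous
parameter: the analytic simulator evaluates `g(t−Kd)` directly at the
shifted times, so there is no integer-lag quantization and no
interpolation error in the dead-time direction.

The default starting point is data-driven rather than fixed: `Kd` from the
2%-of-peak onset, the pole scale from the onset-to-peak rise time via the
reference pole pattern (−a, −2a, −3a) whose impulse response peaks at
ln 3/a, and the gain matched to the observed peak.  A fixed fallback
(poles −1, −2, −3, unit gain) covers the zero-signal case.
`fit_multistart` restarts from log-normal perturbations of that heuristic
(gain re-matched to the peak each time) and keeps the best residual.

Noise-free self-consistency (`fit(simulate(P)) = P`) holds to ~1e−12
relative.  At 1%-of-peak measurement noise the median parameter error is a
few percent: the three denominator coefficients are individually weakly
identified (nearby pole sets produce near-identical curves), while `Kn`
and `Kd` are tight.  This is a property of the model class, not of the
optimizer.

## Factor-to-parameter regression

Each of the five parameters is regressed on the eight factor
concentrations by greedy forward selection: at each step every remaining
factor is tried, the one giving the largest SSE reduction is added, and
all coefficients are refit jointly by ordinary least squares.  Selection
stops when adjusted R² fails to increase (with a 1e−12 guard so that
float-level "improvements" past an exact fit do not add spurious terms),
or when all eight factors are in.  Raw parameter values are regressed (no
transform), and predicted parameters are projected into the fitting bounds
before simulation, since an affine map can emit negative dynamics
coefficients for extreme panels.

Cross-validation partitions samples into k seeded near-equal folds
(sizes differing by at most one).  Per fold, every training curve's
parameters come from its individual fit, the stepwise map is trained on
those, and held-out CATs are predicted from panels alone.  Percent errors
(`|model − experiment|/experiment × 100`) of peak, peak-time and ETP are
taken against the metrics of each held-out sample's own fitted-model
curve, and reported as mean ± SD over samples.

## Normal region and MRE

The normal region is the pointwise minimum, maximum and mean of
healthy-donor CATs on a common grid (optional linear resampling onto the
first curve's grid), the model fitted to the mean curve (the goal model),
and per-property bands (min/max of peak, peak-time, delay, ETP, sTail over
the donors).

MRE scores a curve against the envelope: at each time point where the
curve escapes `[lower, upper]`, the relative excess against the violated
bound — `(y−upper)/upper` above, `(lower−y)/lower` below — averaged over
violating points; zero if the curve never leaves the envelope.  Two
numerical guards: bounds below 1 nM use a 1 nM denominator floor, and
pre-onset points (upper bound < 1 nM) are excluded entirely, because a
relative error against near-zero thrombin is meaningless.  The
bound-relative denominator (rather than the mean or the band width) is a
declared choice; it makes "a uniform 10% exceedance of the upper bound"
score exactly 0.10.

## The GCM controller

One ordered pass over the eight factors, each visited exactly once
(O(n), guaranteed termination; the input panel itself is always a feasible
recommendation).  Goal property values are those of the curve simulated
from the goal model — the fit to the normal mean — not band midpoints.
All property values (current, goal, bands) use the measured-curve
convention of `cat_metrics` without model parameters, so they are mutually
comparable.

Per-factor dosing: the predicted CAT is probed at 9 equally spaced
concentration changes spanning the feasible range (final concentration
inside 60–140%), and the property change is summarized by an
origin-constrained quadratic `ΔP = a₂Δc² + a₁Δc` (the quadratic form is
taken as given; probing is cheap enough that a per-patient model-order
check was not made part of the default path).  The dose is the
minimum-|Δc| real root hitting the target inside the feasible interval,
computed with the cancellation-free quadratic formula (tiny |a₂| collapses
to the linear root); with no in-bound root, the endpoint whose achieved
effect is closest to the target is used and flagged as clamped.

The pass: clip V then VII into band (minimal CAT impact); tune II toward
the goal peak; tune X toward the remaining peak gap (X also counteracts
the peak-time shift II induces, and takes the full residual when II
saturates at a band edge); tune IX toward the goal onset delay; tune VIII
toward the goal peak-time; finally, if the updated curve still leaves the
normal region, tune protein C when its tail area exceeds the goal sTail,
otherwise ATIII, and clip the other anticoagulant into band.

Three controller-level rules where the published description is prose-only:

- **Band gating** — a property already inside its normal band is not
  tuned; the factor is still range-clipped.  This makes a healthy in-range
  panel an exact fixed point.
- **Mandatory range normalization** — every visited factor ends inside
  60–140% whether or not a dose was wanted, since moving concentrations to
  normal is itself a treatment goal.
- **MRE guard** — a solved dose is kept only if it does not worsen the
  predicted CAT's MRE; otherwise the step degrades to a pure range clip.
  With the guard, the final MRE can exceed the initial one only through
  mandatory clips of out-of-band factors, never through tuning.

The controller is fully deterministic.

## Cohort statistics

Heatmaps: per factor and period, the mean of `c(end) − c(start)` over
patients binned by `c(start)` (default 20%-activity bins, last bin
open-ended; edges configurable since the published binning is not).  The
end-minus-start sign convention makes "low starters rise" appear as
positive cells.  Empty cells are NaN, not zero; a patient missing either
endpoint of a period is excluded from that period only.

Welch's t-test uses the standard unequal-variance statistic
`t = (μₓ−μᵧ)/√(Sₓ²/n + Sᵧ²/m)` with Welch–Satterthwaite degrees of freedom
and a two-sided p-value; tiers are ns (p > 0.05), `*` (≤ 0.05), `**`
(≤ 0.01), `***` (≤ 0.001).  Two zero-variance samples with equal means
return t = 0, p = 1.  No multiple-testing correction is applied (raw p
reporting).

## Synthetic data: what it emulates and what it cannot show

No public CAT/trauma dataset exists for this design, so all inputs are
generated.  The generators are seeded and bit-reproducible.

- **Ground-truth factor map.**  Parameters are affine in the panel,
  anchored at the all-100% panel to a realistic healthy center
  (poles −0.25, −0.6, −1.2 /min; 5 pM peak ≈ 250 nM at ≈ 6 min; 2.5 min
  delay), with sparse sensitivities: the gain driven by FII and FX (peak),
  response speed by FX/FVIII/ATIII, decay by PC and ATIII
  (anticoagulants → faster tail decay), delay by FVII and FIX (negative:
  more factor, earlier onset).  Coefficients are sized so parameters stay
  positive and Routh–Hurwitz stable over the whole 0–200% panel range.
  Sparsity makes stepwise-selection recovery checkable against the known
  support.
- **Healthy CAT sets**: log-normal parameter dispersion (σ = 0.08) around
  the center, stability-rejection-sampled, optional additive Gaussian
  curve noise as a fraction of peak.
- **Cohorts**: per-factor first-order relaxation
  `c(t+Δ) = c_eq + (c(t)−c_eq)e^(−λΔ) + noise` over 0/6/12/24 h
  (λ = 0.12–0.15 /h, so ~94% of the gap closes by 24 h), survivor
  equilibria inside 60–140% and non-survivor equilibria outside; CATs
  synthesized through the ground-truth map at every timepoint.  This is
  the simplest process reproducing the observed sign structure (low
  starters rise, high starters fall) and the survivor/non-survivor
  convergence contrast.
- **Stress panels** for the controller: quarters of in-range, uniformly
  low (5–60%), uniformly high (140–220%) and fully mixed panels.
- **Coagulopathic panels**: FII ≈ 40%, FX ≈ 45%, others near normal — a
  low-peak hypocoagulable phenotype.
- **TF titrations** (1/5/20 pM) and **factor-spiking series** mirror bench
  protocols.

Because the synthetic CATs come from the same model family the package
fits, and the synthetic panels map to parameters through an exactly linear
sparse map, passing tests demonstrate *internal correctness* — the
identification, selection, validation and control machinery do what they
claim on data satisfying the model assumptions.  They cannot demonstrate
that real thrombin dynamics are third-order-linear, that real
factor-parameter relations are linear or sparse, or how the stack degrades
under model mismatch, assay artifacts (α₂-macroglobulin tails, calibration
drift), or TF-dose nonlinearity.  Conclusions about clinical performance
require real CAT and factor-panel data.

## Problem sizes and numerical defaults

The shipped checks use: 200 stress panels and 50 coagulopathic patients
for the controller; 25 random stable systems for recovery; 1000 draws for
the pole oracle; 60-sample × 10-seed replicates for selection recovery; a
30-sample cohort for five-fold CV; 100 sample pairs for the Welch
cross-check.  These sizes give stable pass/fail behavior across seeds
while keeping a full run in tens of seconds.  Solver tolerances: 1e−9
(fit), 2000-evaluation cap; stepwise adjusted-R² guard 1e−12; dose-step
relative property tolerance 1e−3; all band clamping to exactly
[60, 140]% activity, configurable in one place (`GCMConfig.band`).

## Known limitations

- The model is strictly linear in TF dose; real CATs saturate.
- Peak-time and onset-delay metrics are quantized to the sampling grid
  (20 s by default), which bounds the achievable precision of the
  corresponding control targets.
- The per-property quadratic dose–effect map extrapolates poorly for
  strongly curved responses far outside the probed range; the MRE guard
  catches, but does not repair, such steps.
- `Kn` has no independent units calibration; fitted magnitudes are
  comparable only within a fixed grid/input convention.
- The MRE's 1 nM denominator floor breaks exact scale invariance for
  curves whose violations occur where the bounds are below ~1 nM.
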