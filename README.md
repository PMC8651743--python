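# coagkit

Transfer-function modeling of thrombin generation, and goal-oriented
coagulation-factor dose recommendation.

## The problem

Trauma-induced coagulopathy is treated today with uncharacterized blood
products and rules of thumb; there is no quantitative guidance on *which*
coagulation factors to give a specific patient, or *how much*.  Yet a
patient's clotting state is measurable two ways: cheaply and quickly as a
panel of eight coagulation-factor concentrations (factors II, V, VII, VIII,
IX, X, antithrombin III and protein C, in % activity, normal band 60–140%),
and slowly but richly as a calibrated automated thrombogram (CAT) — the
thrombin concentration time-history after a tissue-factor (TF) trigger.

`coagkit` implements a personalized control stack that connects the two:

1. **Thrombin dynamics model.**  A CAT curve is the impulse response of a
   delayed third-order linear system,

   ```
   Y(s)/U(s) = Kn / (s³ + K₂s² + K₁s + K₀) · e^(−Kd·s)
   ```

   where `U` is a TF impulse (conventionally 5 pM), `Kd` is the dead time
   before thrombin onset, and the five parameters are patient-specific.
   Simulation is analytic (partial fractions, confluent-root formulas for
   repeated poles); poles of the characteristic cubic give stability and
   response speed.
2. **Identification.**  Bounded trust-region-reflective least squares
   (tolerance 1e−9) fits the five parameters to a measured curve.
3. **Factor → parameter regression.**  Greedy stepwise linear regression
   (largest SSE reduction per step, full refit, adjusted-R² stopping) maps
   the eight-factor panel to the five model parameters, so a CAT can be
   predicted from a rapid factor panel.  Five-fold cross-validation reports
   percent errors of peak, peak-time and ETP (area under the curve).
4. **Normal region.**  Pointwise min/max/mean of healthy-donor CATs defines
   the normal envelope; the model fitted to the mean is the goal CAT.  Any
   curve is scored by MRE — the mean relative excursion beyond the envelope
   over the time points where it escapes.
5. **GCM controller.**  The Goal-oriented Coagulation Management algorithm
   makes one ordered pass over the factors — V, VII (range clipping), II
   (peak), X (peak completion / peak-time compensation), IX (time delay),
   VIII (peak-time), then protein C or ATIII (post-peak tail, "sTail") —
   solving a patient-specific quadratic dose–effect map at each step and
   clamping every recommendation to 60–140% activity.
6. **Cohort statistics & synthetic data.**  Equilibration heatmaps, Welch's
   unequal-variance t-tests with significance tiers, convergence summaries;
   plus seeded generators for every input (healthy CAT sets, trauma
   cohorts with survivor/non-survivor equilibration dynamics, TF
   titrations, factor-spiking series), so the whole stack runs and is
   tested without patient data.

## Worked example

```python
import numpy as np
from coagkit import *
from coagkit.synthetic import make_ground_truth_map, generate_panels

# a realistic patient model: poles at -0.25, -0.6, -1.2 /min
params = ThrombinModelParams(k0=0.18, k1=1.17, k2=2.05, kn=71.7, kd=2.5)
curve = simulate_cat(params, ImpulseInput(5.0))     # 5 pM TF, 20 s grid
m = cat_metrics(curve, params)
# -> peak 249.8 nM at 6.00 min, delay 2.5 min, ETP 1992 nM·min
# -> poles: [-1.2, -0.6, -0.25]

fit = fit_model(curve)      # recovers k0..kd exactly (SSE ~ 5e-25)

# normal region from 20 synthetic healthy donors, then a dose
# recommendation for a coagulopathic panel (depressed FII and FX)
truth = make_ground_truth_map()
region = build_normal_region(
    [predict_cat(truth, p) for p in generate_panels(20, seed=3, sd=10.0)])
patient = FactorPanel(fii=34, fv=102, fvii=87, fviii=105,
                      fix=109, fx=41, atiii=103, pc=102)
rec = gcm_recommend(patient, truth, region)
```

The recommendation raises FII 34 → 128.0 and FX 41 → 60.0 (clamped at the
band edge) and leaves the other six factors untouched; the predicted CAT's
MRE against the normal region drops from 0.418 to 0.000, i.e. the predicted
curve moves fully inside the normal envelope.  The step log shows one entry
per factor:

```
fv     range      dc=  +0.00           range clip
fvii   range      dc=  +0.00           range clip
fii    peak       dc= +93.96           peak via FII
fx     peak       dc= +19.00  clamped  peak via FX in-band
fix    time_delay dc=  +0.00           time delay via FIX in-band
fviii  peak_time  dc=  +0.00           peak time via FVIII in-band
pc     range      dc=  +0.00           range clip
atiii  range      dc=  +0.00           range clip
```

The same workflows are scriptable from the shell:

```sh
coagkit simulate --params params.json --tf-pm 5 --out curve.csv
coagkit fit --curve curve.csv --out params.json
coagkit region build --curves-dir ./normals --out region.json
coagkit recommend --panel panel.csv --map map.json \
    --region region.json --out recommendation.json
coagkit cohort generate --scenario scenario.yaml --out-dir ./cohort
coagkit stats welch --cohort cohort/cohort.csv --factor fii
```

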