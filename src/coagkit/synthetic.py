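"""Seeded synthetic-data generators for the whole stack.

No public CAT/trauma dataset accompanies the modeled study design, so every
input the other modules consume can be generated here: healthy CAT curve
sets, factor panels, longitudinal trauma cohorts whose survivors equilibrate
into the 60–140% activity band (and non-survivors outside it), TF titration
series, and single-factor spiking series.

CAT curves are always synthesized through the same transfer-function model
the rest of the package identifies, via a ground-truth factor-to-parameter
map with known sparse structure, so recovery of that structure (stepwise
selection, cross-validation, closed-loop dose recommendation) is checkable
end to end.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import clip_to_bounds
from .model import CATCurve, ImpulseInput, ThrombinModelParams, is_stable, simulate_cat
from .regression import (
    FACTORS,
    FactorPanel,
    ParameterRegression,
    RegressionMap,
    predict_params,
)
from .cohortstats import TIMEPOINTS_H, PatientTimeline

__all__ = [
    "CENTER_PARAMS", "make_ground_truth_map", "CohortScenario",
    "generate_healthy_cats", "generate_panels", "generate_cohort",
    "generate_spiking_series", "generate_tf_titration",
    "survivor_scenario", "deceased_scenario", "coagulopathic_panels",
    "stress_panels",
]

#: a realistic healthy center: poles (-0.25, -0.6, -1.2) 1/min, ~250 nM peak
#: near 6 min after a 5 pM TF impulse, 2.5 min onset delay
CENTER_PARAMS = ThrombinModelParams(k0=0.18, k1=1.17, k2=2.05,
                                    kn=71.7, kd=2.5)

# relative sensitivities (per % activity) of each parameter to each factor in
# the ground-truth map; sparse by construction so support recovery is testable
_TRUTH_SENSITIVITIES: dict[str, dict[str, float]] = {
    "kn": {"fii": 0.006, "fx": 0.003},            # peak drivers
    "k2": {"fx": 0.002, "fviii": 0.002, "atiii": 0.001},  # response speed
    "k1": {"pc": 0.003, "fviii": 0.001},
    "k0": {"pc": 0.004, "atiii": 0.002},          # tail decay (anticoagulants)
    "kd": {"fvii": -0.003, "fix": -0.004},        # onset delay
}


def make_ground_truth_map(center: ThrombinModelParams = CENTER_PARAMS,
                          ) -> RegressionMap:
    """The ground-truth linear map used to synthesize CATs from panels.

    Each parameter is ``center * (1 + sum_f s_f * (c_f - 100))`` — linear in
    the factor concentrations, anchored at the all-100% panel, with the
    sparse sensitivities above.  Parameters stay positive and the dynamics
    Routh–Hurwitz stable over the whole 0–200% activity range.
    """
    regs = {}
    for pname, cval in center.to_dict().items():
        sens = _TRUTH_SENSITIVITIES.get(pname, {})
        factors = tuple(sens)
        coefs = tuple(cval * s for s in sens.values())
        intercept = cval * (1.0 - 100.0 * sum(sens.values()))
        regs[pname] = ParameterRegression(factors=factors, intercept=intercept,
                                          coefficients=coefs)
    return RegressionMap(regressions=regs, n_samples=0)


def _add_noise(curve: CATCurve, noise_sd: float,
               rng: np.random.Generator) -> CATCurve:
    """Additive Gaussian measurement noise, SD given as a fraction of peak."""
    if noise_sd <= 0:
        return curve
    peak = float(np.max(curve.thrombin))
    y = curve.thrombin + rng.normal(0.0, noise_sd * peak, size=len(curve))
    return CATCurve(curve.times, y)  # clips negative undershoot


def generate_healthy_cats(n: int, seed: int | None = None,
                          params_center: ThrombinModelParams = CENTER_PARAMS,
                          dispersion: float = 0.08,
                          noise_sd: float = 0.0,
                          input: ImpulseInput = ImpulseInput(),
                          duration: float = 60.0, dt: float = 1.0 / 3.0,
                          ) -> tuple[list[CATCurve], list[ThrombinModelParams]]:
    """Healthy-donor CAT curves from log-normal parameter dispersion.

    Parameters are drawn multiplicatively (log-normal, sigma=``dispersion``)
    around the center; draws violating Routh–Hurwitz stability are redrawn.
    Returns the curves and the generating parameters.
    """
    rng = np.random.default_rng(seed)
    curves, params = [], []
    center = params_center.as_array()
    for _ in range(n):
        for _attempt in range(100):
            x = center * rng.lognormal(0.0, dispersion, size=5)
            p = ThrombinModelParams.from_array(clip_to_bounds(x))
            if is_stable(p):
                break
        curve = simulate_cat(p, input=input, duration=duration, dt=dt)
        curves.append(_add_noise(curve, noise_sd, rng))
        params.append(p)
    return curves, params


def generate_panels(n: int, seed: int | None = None,
                    means: dict[str, float] | None = None,
                    sd: float = 12.0) -> list[FactorPanel]:
    """Random factor panels: truncated-Gaussian % activities around ``means``
    (default 100% for every factor)."""
    rng = np.random.default_rng(seed)
    mu = np.array([(means or {}).get(f, 100.0) for f in FACTORS])
    panels = []
    for _ in range(n):
        x = np.maximum(rng.normal(mu, sd), 1.0)
        panels.append(FactorPanel.from_array(x))
    return panels


def coagulopathic_panels(n: int, seed: int | None = None) -> list[FactorPanel]:
    """Trauma-like panels with depressed factor II and X (low predicted peak);
    the other factors sit near normal."""
    return generate_panels(n, seed=seed,
                           means={"fii": 40.0, "fx": 45.0}, sd=8.0)


def stress_panels(n: int, seed: int | None = None) -> list[FactorPanel]:
    """Panels spanning in-range, uniformly low, uniformly high and mixed
    factor levels — the input space a dose recommender must tolerate."""
    rng = np.random.default_rng(seed)
    panels = []
    for i in range(n):
        kind = i % 4
        if kind == 0:      # in-range
            x = rng.uniform(60.0, 140.0, size=8)
        elif kind == 1:    # low
            x = rng.uniform(5.0, 60.0, size=8)
        elif kind == 2:    # high
            x = rng.uniform(140.0, 220.0, size=8)
        else:              # mixed
            x = rng.uniform(5.0, 220.0, size=8)
        panels.append(FactorPanel.from_array(x))
    return panels


@dataclass(frozen=True)
class CohortScenario:
    """Study conditions for one synthetic longitudinal cohort.

    ``equilibria`` are the per-factor targets (% activity) each patient's
    concentrations relax toward over 0/6/12/24 h; survivors default to
    targets inside the 60–140% band, non-survivors must place at least one
    outside.  ``rate_per_h`` is the first-order relaxation rate; noise SDs
    apply to panel values (% activity) and CAT curves (fraction of peak).
    """

    n_patients: int
    outcome: str
    equilibria: dict[str, float]
    initial_means: dict[str, float] = field(default_factory=dict)
    initial_sd: float = 30.0
    rate_per_h: float = 0.12
    panel_noise_sd: float = 4.0
    cat_noise_sd: float = 0.01
    seed: int | None = None
    truth_map: RegressionMap = field(default_factory=make_ground_truth_map)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.panel_noise_sd < 0 or self.cat_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        missing = set(FACTORS) - set(self.equilibria)
        if missing:
            raise ValueError(f"equilibria missing factors: {sorted(missing)}")


def survivor_scenario(n: int = 50, seed: int | None = None,
                      **overrides) -> CohortScenario:
    """Survivor cohort: every factor equilibrates inside 60–140% activity."""
    eq = {"fii": 95.0, "fv": 100.0, "fvii": 90.0, "fviii": 120.0,
          "fix": 110.0, "fx": 95.0, "atiii": 90.0, "pc": 100.0}
    init = {f: 55.0 for f in FACTORS}  # admission levels typically depressed
    kw = dict(n_patients=n, outcome="alive", equilibria=eq,
              initial_means=init, seed=seed)
    kw.update(overrides)
    return CohortScenario(**kw)


def deceased_scenario(n: int = 30, seed: int | None = None,
                      **overrides) -> CohortScenario:
    """Non-survivor cohort: several factors equilibrate outside the band."""
    eq = {"fii": 35.0, "fv": 45.0, "fvii": 50.0, "fviii": 170.0,
          "fix": 100.0, "fx": 40.0, "atiii": 45.0, "pc": 40.0}
    init = {f: 60.0 for f in FACTORS}
    kw = dict(n_patients=n, outcome="deceased", equilibria=eq,
              initial_means=init, rate_per_h=0.15, seed=seed)
    kw.update(overrides)
    return CohortScenario(**kw)


def generate_cohort(scenario: CohortScenario,
                    timepoints: tuple[float, ...] = TIMEPOINTS_H,
                    input: ImpulseInput = ImpulseInput(),
                    duration: float = 60.0, dt: float = 1.0 / 3.0,
                    ) -> tuple[list[PatientTimeline],
                               dict[tuple[str, float], CATCurve]]:
    """Longitudinal cohort with first-order equilibration dynamics.

    Each factor follows ``c(t+Δ) = c_eq + (c(t) - c_eq)·exp(-λΔ) + noise``
    (noise truncated so concentrations stay nonnegative); a CAT curve is
    synthesized at every timepoint through the scenario's ground-truth map.

    Returns the timelines and a ``{(patient_id, time_h): CATCurve}`` dict.
    """
    rng = np.random.default_rng(scenario.seed)
    eq = np.array([scenario.equilibria[f] for f in FACTORS])
    mu0 = np.array([scenario.initial_means.get(f, 100.0) for f in FACTORS])
    timelines: list[PatientTimeline] = []
    curves: dict[tuple[str, float], CATCurve] = {}
    for i in range(scenario.n_patients):
        pid = f"{scenario.outcome}-{i:03d}"
        c = np.maximum(rng.normal(mu0, scenario.initial_sd), 1.0)
        panels: dict[float, FactorPanel] = {}
        prev_t = timepoints[0]
        for t in timepoints:
            decay = np.exp(-scenario.rate_per_h * (t - prev_t))
            c = eq + (c - eq) * decay
            if scenario.panel_noise_sd > 0:
                c = c + rng.normal(0.0, scenario.panel_noise_sd, size=c.size)
            c = np.maximum(c, 0.0)
            panel = FactorPanel.from_array(c)
            panels[t] = panel
            params = predict_params(scenario.truth_map, panel)
            curve = simulate_cat(params, input=input, duration=duration, dt=dt)
            curves[(pid, t)] = _add_noise(curve, scenario.cat_noise_sd, rng)
            prev_t = t
        timelines.append(PatientTimeline(patient_id=pid,
                                         outcome=scenario.outcome,
                                         panels=panels))
    return timelines, curves


def generate_spiking_series(base_panel: FactorPanel, factor: str,
                            spike_levels, map: RegressionMap | None = None,
                            seed: int | None = None,
                            noise_sd: float = 0.0,
                            input: ImpulseInput = ImpulseInput(),
                            duration: float = 60.0, dt: float = 1.0 / 3.0,
                            ) -> list[tuple[FactorPanel, CATCurve]]:
    """Isolated factor-spiking series: one factor raised through increasing
    levels (added % activity) with all others fixed, CATs synthesized through
    the map.  Emulates bench experiments that spike factors II, VIII or X
    into plasma."""
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    levels = [float(v) for v in spike_levels]
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("spike levels must be non-decreasing")
    truth = map or make_ground_truth_map()
    rng = np.random.default_rng(seed)
    out = []
    for lv in levels:
        panel = base_panel.replace(**{factor: getattr(base_panel, factor) + lv})
        params = predict_params(truth, panel)
        curve = simulate_cat(params, input=input, duration=duration, dt=dt)
        out.append((panel, _add_noise(curve, noise_sd, rng)))
    return out


def generate_tf_titration(params: ThrombinModelParams,
                          magnitudes=(1.0, 5.0, 20.0),
                          duration: float = 60.0, dt: float = 1.0 / 3.0,
                          ) -> list[CATCurve]:
    """CAT curves for one parameter set under a TF titration (default
    1/5/20 pM impulses).  The model is linear in the input, so curves scale
    proportionally with the impulse magnitude."""
    return [simulate_cat(params, input=ImpulseInput(m),
                         duration=duration, dt=dt)
            for m in magnitudes]
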