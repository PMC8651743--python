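"""Goal-oriented Coagulation Management (GCM): single-pass dose recommendation.

Given a patient's factor panel, a trained factor-to-parameter regression map
and the normal CAT region, the controller recommends new concentrations for
all eight factors — each clamped to the normal 60–140% activity band — that
move the predicted CAT toward the goal trajectory.  The pass is ordered by
each factor's dominant effect on the CAT:

1. factors V and VII are clipped into the normal band (small CAT impact);
2. factor II is tuned toward the goal peak;
3. factor X finishes the peak correction (it also counteracts the peak-time
   shift II induces, its peak-time effect being opposite);
4. factor IX is tuned toward the goal time delay;
5. factor VIII fine-tunes the peak time;
6. if the updated CAT still leaves the normal region, one anticoagulant is
   tuned toward the goal post-peak tail area (sTail): protein C when the
   tail exceeds the goal's, ATIII otherwise.

Each factor is visited exactly once, so the controller is O(n) in the number
of factors and always terminates with a recommendation (the input panel
itself is always feasible).  Per-factor dose sizes come from a patient-
specific effect map: the predicted change in a CAT property is probed over
the feasible concentration range and summarized by an origin-constrained
quadratic, whose roots give the concentration change that meets the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CATCurve, CATMetrics, ImpulseInput, cat_metrics, simulate_cat
from .region import NormalRegion, in_region, mre
from .regression import (
    NORMAL_BAND,
    FactorPanel,
    RegressionMap,
    predict_params,
)

__all__ = ["EffectPolynomial", "GCMStep", "GCMRecommendation", "GCMConfig",
           "probe_effect_map", "solve_dose", "gcm_recommend"]


@dataclass(frozen=True)
class EffectPolynomial:
    """Origin-constrained quadratic effect of a concentration change.

    ``delta_property = a2 * dc**2 + a1 * dc`` for a change ``dc`` (% activity)
    of one factor, valid over the probed range.
    """

    factor: str
    property: str
    a2: float
    a1: float
    probe_range: tuple[float, float]

    def __call__(self, dc: float) -> float:
        return self.a2 * dc * dc + self.a1 * dc

    @property
    def is_zero(self) -> bool:
        return self.a2 == 0.0 and self.a1 == 0.0


@dataclass(frozen=True)
class GCMStep:
    """Audit record of one modulation step."""

    factor: str
    property: str | None      # None for pure range clipping
    dc: float
    clamped: bool
    target_delta: float = 0.0
    achieved_delta: float = 0.0
    note: str = ""


@dataclass(frozen=True)
class GCMRecommendation:
    input_panel: FactorPanel
    recommended_panel: FactorPanel
    cat_before: CATCurve
    cat_after: CATCurve
    steps: tuple[GCMStep, ...]
    initial_mre: float
    final_mre: float


@dataclass(frozen=True)
class GCMConfig:
    """Controller knobs: concentration band, probe count, dose tolerances."""

    band: tuple[float, float] = NORMAL_BAND
    n_probes: int = 9
    tf: ImpulseInput = field(default_factory=ImpulseInput)
    mre_tolerance: float = 0.0
    #: relative tolerance under which a property gap is considered closed
    property_rtol: float = 1e-3


def _predicted_curve(map: RegressionMap, panel: FactorPanel,
                     region: NormalRegion, input: ImpulseInput,
                     ) -> tuple[CATCurve, CATMetrics]:
    params = predict_params(map, panel)
    curve = simulate_cat(params, input=input,
                         duration=float(region.times[-1]), dt=region.mean.dt)
    # metrics use the measured-curve convention (onset-threshold delay), the
    # same convention behind the region's metric bands
    return curve, cat_metrics(curve)


def probe_effect_map(map: RegressionMap, panel: FactorPanel, factor: str,
                     property: str, n_probes: int = 9,
                     band: tuple[float, float] = NORMAL_BAND,
                     input: ImpulseInput = ImpulseInput(),
                     duration: float = 60.0, dt: float = 1.0 / 3.0,
                     ) -> EffectPolynomial:
    """Fit the patient-specific quadratic effect of one factor on one property.

    Simulates the predicted CAT at ``n_probes`` equally spaced concentration
    changes spanning the feasible range (final concentration inside ``band``)
    and least-squares fits ``a2*dc^2 + a1*dc`` to the observed property
    changes.  A factor absent from every parameter regression yields the zero
    polynomial.
    """
    c0 = getattr(panel, factor)
    lo, hi = band[0] - c0, band[1] - c0
    if hi < lo:
        raise ValueError(f"empty feasible range for {factor} at {c0}")
    if not map.uses_factor(factor):
        return EffectPolynomial(factor, property, 0.0, 0.0, (lo, hi))

    def prop_at(dc: float) -> float:
        p = panel.replace(**{factor: max(c0 + dc, 0.0)})
        params = predict_params(map, p)
        curve = simulate_cat(params, input=input, duration=duration, dt=dt)
        return cat_metrics(curve, params)[property]

    base = prop_at(0.0)
    dcs = np.linspace(lo, hi, n_probes)
    dprops = np.array([prop_at(dc) - base for dc in dcs])
    A = np.column_stack([dcs**2, dcs])
    coef, *_ = np.linalg.lstsq(A, dprops, rcond=None)
    return EffectPolynomial(factor, property, float(coef[0]), float(coef[1]),
                            (float(lo), float(hi)))


def solve_dose(poly: EffectPolynomial, target_delta: float,
               dc_bounds: tuple[float, float]) -> tuple[float, bool]:
    """Concentration change achieving ``target_delta`` of the property.

    Among real roots of ``a2*dc^2 + a1*dc = target_delta`` inside
    ``dc_bounds``, returns the minimum-|dc| root.  With no in-bound root the
    bound endpoint whose achieved effect is closest to the target is returned
    and flagged as clamped; a zero polynomial with a nonzero target returns
    ``dc = 0`` clamped.

    Returns ``(dc, clamped)``.
    """
    lo, hi = dc_bounds
    if hi < lo:
        raise ValueError(f"empty dose bounds {dc_bounds}")
    if poly.is_zero:
        return (0.0, target_delta != 0.0)
    # solve a2*x^2 + a1*x - target = 0 with the cancellation-free form:
    # q = -(a1 + sign(a1)*sqrt(disc))/2, roots q/a2 and -target/q
    if poly.a2 == 0.0 or abs(poly.a2) < 1e-14 * abs(poly.a1):
        roots = np.array([target_delta / poly.a1]) if poly.a1 else np.array([])
    else:
        disc = poly.a1**2 + 4.0 * poly.a2 * target_delta
        if disc < 0:
            roots = np.array([])
        else:
            sq = float(np.sqrt(disc))
            sgn = 1.0 if poly.a1 >= 0 else -1.0
            q = -(poly.a1 + sgn * sq) / 2.0
            roots = (np.array([q / poly.a2, -target_delta / q]) if q != 0
                     else np.array([0.0]))
    in_bounds = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
    if in_bounds:
        dc = min(in_bounds, key=abs)
        return (float(np.clip(dc, lo, hi)), False)
    endpoints = [lo, hi]
    dc = min(endpoints, key=lambda e: abs(poly(e) - target_delta))
    return (float(dc), True)


def gcm_recommend(panel: FactorPanel, map: RegressionMap,
                  region: NormalRegion,
                  config: GCMConfig | None = None) -> GCMRecommendation:
    """Run the single-pass GCM algorithm on one patient panel.

    Always returns a recommendation; every recommended concentration lies in
    the normal band.  A modulation step is only kept when it does not worsen
    the predicted CAT's MRE against the normal region, so the final MRE never
    exceeds the value after the mandatory range-clipping of factors V/VII.
    """
    cfg = config or GCMConfig()
    lo_band, hi_band = cfg.band
    state = panel
    steps: list[GCMStep] = []

    cat0, metrics = _predicted_curve(map, panel, region, cfg.tf)
    initial_mre = mre(cat0, region)
    cur_mre = initial_mre
    goal = region.goal_metrics(cfg.tf)

    # both treatment goals already met: nothing to modulate
    panel_in_band = all(lo_band <= getattr(panel, f) <= hi_band
                        for f in panel.to_dict())
    if panel_in_band and initial_mre <= cfg.mre_tolerance:
        noop = tuple(GCMStep(factor=f, property=None, dc=0.0, clamped=False,
                             note="goals met, no change")
                     for f in ("fv", "fvii", "fii", "fx", "fix", "fviii",
                               "pc", "atiii"))
        return GCMRecommendation(
            input_panel=panel, recommended_panel=panel,
            cat_before=cat0, cat_after=cat0, steps=noop,
            initial_mre=initial_mre, final_mre=initial_mre)

    def _apply(factor: str, dc: float) -> None:
        """Commit a concentration change and refresh the predicted state."""
        nonlocal state, metrics, cur_mre
        if dc == 0.0:
            return
        state = state.replace(**{factor: getattr(state, factor) + dc})
        curve, metrics = _predicted_curve(map, state, region, cfg.tf)
        cur_mre = mre(curve, region)

    def clip_step(factor: str, prop: str | None = None, note: str = "range clip",
                  ) -> None:
        c = getattr(state, factor)
        dc = float(np.clip(c, lo_band, hi_band)) - c
        _apply(factor, dc)
        steps.append(GCMStep(factor=factor, property=prop, dc=dc,
                             clamped=dc != 0.0, note=note))

    def tune_step(factor: str, prop: str, target_value: float,
                  gate_band: tuple[float, float] | None, note: str = "") -> None:
        """Solve and apply one dose toward the goal property value.

        The dose is kept only if the predicted MRE does not worsen; either
        way the factor ends inside the normal band (range normalization is
        mandatory even when no CAT correction is wanted).
        """
        nonlocal state, metrics, cur_mre
        cur = metrics[prop]
        target_delta = target_value - cur
        within_gate = (gate_band is not None
                       and gate_band[0] <= cur <= gate_band[1])
        at_goal = abs(target_delta) <= cfg.property_rtol * max(
            abs(target_value), 1e-9)
        if within_gate or at_goal:
            clip_step(factor, prop=prop,
                      note=note + (" in-band" if within_gate else " at goal"))
            return
        poly = probe_effect_map(map, state, factor, prop,
                                n_probes=cfg.n_probes, band=cfg.band,
                                input=cfg.tf,
                                duration=float(region.times[-1]),
                                dt=region.mean.dt)
        c = getattr(state, factor)
        dc, clamped = solve_dose(poly, target_delta,
                                 (lo_band - c, hi_band - c))
        trial = state.replace(**{factor: c + dc})
        trial_curve, trial_metrics = _predicted_curve(map, trial, region, cfg.tf)
        trial_mre = mre(trial_curve, region)
        if dc != 0.0 and trial_mre <= cur_mre + 1e-12:
            achieved = trial_metrics[prop] - cur
            state, metrics, cur_mre = trial, trial_metrics, trial_mre
            steps.append(GCMStep(factor=factor, property=prop, dc=dc,
                                 clamped=clamped, target_delta=target_delta,
                                 achieved_delta=achieved, note=note))
        else:
            # dose rejected (or null); range normalization still applies
            clip_step(factor, prop=prop,
                      note=note + (" rejected: MRE would worsen"
                                   if dc != 0.0 else " no usable dose"))

    bands = region.metric_bands
    # 1. low-impact factors straight into the normal band
    clip_step("fv")
    clip_step("fvii")
    # 2. factor II drives the peak
    tune_step("fii", "peak", goal.peak, bands["peak"], note="peak via FII")
    # 3. factor X finishes the peak (II may be saturated) and offsets II's
    #    peak-time shift
    tune_step("fx", "peak", goal.peak, bands["peak"], note="peak via FX")
    # 4. factor IX corrects the onset delay
    tune_step("fix", "time_delay", goal.time_delay, bands["time_delay"],
              note="time delay via FIX")
    # 5. factor VIII fine-tunes the peak time
    tune_step("fviii", "peak_time", goal.peak_time, bands["peak_time"],
              note="peak time via FVIII")
    # 6. anticoagulant choice from the post-peak tail vs the goal tail
    cur_curve, metrics = _predicted_curve(map, state, region, cfg.tf)
    if not in_region(cur_curve, region, cfg.mre_tolerance):
        anticoag = "pc" if metrics.s_tail > goal.s_tail else "atiii"
        other = "atiii" if anticoag == "pc" else "pc"
        tune_step(anticoag, "s_tail", goal.s_tail, None, note="tail")
        clip_step(other)
    else:
        clip_step("pc")
        clip_step("atiii")

    cat_after, _ = _predicted_curve(map, state, region, cfg.tf)
    return GCMRecommendation(
        input_panel=panel, recommended_panel=state,
        cat_before=cat0, cat_after=cat_after,
        steps=tuple(steps), initial_mre=initial_mre,
        final_mre=mre(cat_after, region))
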