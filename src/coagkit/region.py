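"""Normal CAT region construction and the mean-relative-error (MRE) score.

Healthy-donor CAT curves define, pointwise in time, a min/max envelope and a
mean trajectory; the thrombin model fitted to the mean is the goal model
whose simulated curve supplies the target CAT properties for dose
recommendation.  Any curve is scored against the envelope with the MRE: the
mean, over time points where it escapes the envelope, of its relative excess
beyond the violated bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_model
from .model import (
    CATCurve,
    CATMetrics,
    GridError,
    ImpulseInput,
    ThrombinModelParams,
    cat_metrics,
)

__all__ = ["NormalRegion", "build_normal_region", "mre", "in_region"]

#: bounds below this (nM) are treated as pre-onset: relative error there is
#: meaningless and those time points are excluded from the MRE
PREONSET_FLOOR = 1.0


@dataclass(frozen=True)
class NormalRegion:
    """Pointwise envelope of healthy CATs plus the fitted goal model.

    ``metric_bands`` holds (min, max) of each CAT property over the normal
    curves; a predicted property inside its band needs no correction.
    """

    lower: CATCurve
    upper: CATCurve
    mean: CATCurve
    goal_params: ThrombinModelParams
    metric_bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not (self.lower.same_grid(self.upper)
                and self.lower.same_grid(self.mean)):
            raise GridError("envelope curves must share one time grid")
        if (np.any(self.lower.thrombin > self.mean.thrombin + 1e-9)
                or np.any(self.mean.thrombin > self.upper.thrombin + 1e-9)):
            raise ValueError("envelope must satisfy lower <= mean <= upper")

    @property
    def times(self) -> np.ndarray:
        return self.mean.times

    def goal_metrics(self, input: ImpulseInput = ImpulseInput()) -> CATMetrics:
        """Properties of the goal CAT (simulated from ``goal_params``)."""
        from .model import simulate_cat

        dt = self.mean.dt
        curve = simulate_cat(self.goal_params, input=input,
                             duration=float(self.times[-1]), dt=dt)
        # measured-curve convention (no params) so goal values are directly
        # comparable with the per-curve metric bands
        return cat_metrics(curve)

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "lower": self.lower.thrombin.tolist(),
            "upper": self.upper.thrombin.tolist(),
            "mean": self.mean.thrombin.tolist(),
            "goal_params": self.goal_params.to_dict(),
            "metric_bands": {k: list(v) for k, v in self.metric_bands.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalRegion":
        t = np.asarray(d["times"], dtype=float)
        return cls(
            lower=CATCurve(t, np.asarray(d["lower"], dtype=float)),
            upper=CATCurve(t, np.asarray(d["upper"], dtype=float)),
            mean=CATCurve(t, np.asarray(d["mean"], dtype=float)),
            goal_params=ThrombinModelParams.from_dict(d["goal_params"]),
            metric_bands={k: (float(v[0]), float(v[1]))
                          for k, v in d["metric_bands"].items()},
        )


def build_normal_region(curves: list[CATCurve],
                        input: ImpulseInput = ImpulseInput(),
                        resample: bool = False) -> NormalRegion:
    """Build the normal region from healthy-donor CAT curves.

    Takes the pointwise minimum, maximum and mean across curves, fits the
    thrombin model to the mean curve (the goal model), and records per-curve
    metric bands.

    Parameters
    ----------
    curves : list of CATCurve
        At least one curve; all on a common grid unless ``resample`` is set,
        in which case curves are linearly resampled onto the first grid.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].times
    aligned = []
    for c in curves:
        if c.same_grid(curves[0]):
            aligned.append(c)
        elif resample:
            aligned.append(c.resample(grid))
        else:
            raise GridError("curves on mismatched grids (set resample=True)")
    Y = np.array([c.thrombin for c in aligned])
    lower = CATCurve(grid, Y.min(axis=0))
    upper = CATCurve(grid, Y.max(axis=0))
    mean = CATCurve(grid, Y.mean(axis=0))
    goal = fit_model(mean, input=input).params
    metrics = [cat_metrics(c) for c in aligned]
    bands = {
        prop: (min(m[prop] for m in metrics), max(m[prop] for m in metrics))
        for prop in ("peak", "peak_time", "time_delay", "etp", "s_tail")
    }
    return NormalRegion(lower=lower, upper=upper, mean=mean,
                        goal_params=goal, metric_bands=bands)


def mre(curve: CATCurve, region: NormalRegion) -> float:
    """Mean relative error of a CAT curve against the normal envelope.

    At each time point where the curve escapes [lower, upper], the relative
    excess against the violated bound is ``(y - upper)/upper`` above and
    ``(lower - y)/lower`` below (bounds under 1 nM use a 1 nM floor in the
    denominator).  Pre-onset points, where the upper bound is below 1 nM,
    are excluded.  Returns the mean over violating points, or 0 when the
    curve never leaves the envelope.
    """
    c = curve if curve.same_grid(region.mean) else curve.resample(region.times)
    y = c.thrombin
    lo = region.lower.thrombin
    up = region.upper.thrombin
    include = up >= PREONSET_FLOOR
    above = include & (y > up)
    below = include & (y < lo)
    errs = np.concatenate([
        (y[above] - up[above]) / np.maximum(up[above], PREONSET_FLOOR),
        (lo[below] - y[below]) / np.maximum(lo[below], PREONSET_FLOOR),
    ])
    return float(errs.mean()) if errs.size else 0.0


def in_region(curve: CATCurve, region: NormalRegion,
              tolerance: float = 0.0) -> bool:
    """True iff the curve's MRE against the region is within ``tolerance``."""
    return mre(curve, region) <= tolerance
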