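"""Cohort equilibration statistics for longitudinal factor panels.

Trauma cohorts are summarized three ways: (1) heatmaps of the mean change in
each factor's concentration over a time period, binned by the concentration
at the period start — low starters rise, high starters fall when patients
equilibrate; (2) Welch's unequal-variance t-test contrasting concentration
changes between outcome groups, with the usual significance tiers; and
(3) per-group mean ± SD trajectories with a flag for whether the final-time
mean sits inside the normal 60–140% activity band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regression import FACTORS, NORMAL_BAND, FactorPanel

__all__ = ["PatientTimeline", "WelchResult", "delta_heatmap", "welch_test",
           "significance_tier", "convergence_summary", "TIMEPOINTS_H"]

#: measurement schedule, hours after admission
TIMEPOINTS_H = (0.0, 6.0, 12.0, 24.0)


@dataclass(frozen=True)
class PatientTimeline:
    """One patient's factor panels over the measurement schedule.

    ``panels`` maps time (h) to the panel measured then; missing timepoints
    are simply absent.  ``outcome`` is a free-form group label, conventionally
    ``"alive"`` or ``"deceased"``.
    """

    patient_id: str
    outcome: str
    panels: dict[float, FactorPanel]

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("timeline needs at least one panel")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(sorted(self.panels))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    tier: str


def significance_tier(p: float) -> str:
    """Map a p-value to the printed tiers: ns (>0.05), * (<=0.05),
    ** (<=0.01), *** (<=0.001)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def welch_test(x, y) -> WelchResult:
    """Welch's unequal-variance t-test for two independent samples.

    t = (mean_x - mean_y) / sqrt(s_x^2/n + s_y^2/m) with Welch–Satterthwaite
    degrees of freedom and a two-sided p-value.  Two zero-variance samples
    with equal means give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / n + vy / m
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
        df = float(n + m - 2)
    else:
        t = float(diff / math.sqrt(se2))
        df = float(se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1)))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=p, tier=significance_tier(p))


def delta_heatmap(timelines: list[PatientTimeline],
                  bin_edges=None,
                  periods: list[tuple[float, float]] | None = None,
                  ) -> dict[str, pd.DataFrame]:
    """Mean concentration change per factor, binned by starting concentration.

    For each factor and each (start, end) period, patients are grouped by
    the bin their starting concentration falls in, and the cell holds the
    mean of ``concentration(end) - concentration(start)`` in that group.
    Cells with no eligible patient are NaN (missing, not zero); patients
    lacking either endpoint of a period are excluded from that period only.

    Returns ``{factor: DataFrame}`` with bin intervals as the index and
    period labels as columns.
    """
    if bin_edges is None:
        # 20%-activity bins, last bin open-ended
        bin_edges = list(np.arange(0.0, 200.0 + 1e-9, 20.0)) + [np.inf]
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    if periods is None:
        periods = [(0.0, 6.0), (6.0, 12.0), (12.0, 24.0)]

    index = pd.IntervalIndex.from_breaks(bin_edges, closed="left")
    cols = [f"{int(a)}-{int(b)}h" for a, b in periods]
    out: dict[str, pd.DataFrame] = {}
    for factor in FACTORS:
        cells = pd.DataFrame(np.nan, index=index, columns=cols)
        for (a, b), col in zip(periods, cols, strict=True):
            starts, deltas = [], []
            for tl in timelines:
                if a in tl.panels and b in tl.panels:
                    c0 = getattr(tl.panels[a], factor)
                    c1 = getattr(tl.panels[b], factor)
                    starts.append(c0)
                    deltas.append(c1 - c0)
            if starts:
                df = pd.DataFrame({"start": starts, "delta": deltas})
                df["bin"] = pd.cut(df["start"], index)
                means = df.groupby("bin", observed=True)["delta"].mean()
                cells.loc[means.index, col] = means.values
        out[factor] = cells
    return out


def convergence_summary(timelines: list[PatientTimeline],
                        band: tuple[float, float] = NORMAL_BAND,
                        ) -> pd.DataFrame:
    """Per group/timepoint/factor mean and SD, with a final-mean in-band flag.

    Returns a tidy DataFrame with columns ``group, time_h, factor, mean, sd,
    n, final_mean_in_band`` (the flag is constant within a group/factor and
    refers to the last timepoint observed for that group).
    """
    if not timelines:
        raise ValueError("need at least one timeline")
    rows = []
    for tl in timelines:
        for t, panel in tl.panels.items():
            for f in FACTORS:
                rows.append((tl.outcome, t, f, getattr(panel, f)))
    df = pd.DataFrame(rows, columns=["group", "time_h", "factor", "value"])
    g = (df.groupby(["group", "time_h", "factor"])["value"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=0), n="count")
           .reset_index())
    final = (g.sort_values("time_h").groupby(["group", "factor"]).tail(1)
             .assign(final_mean_in_band=lambda d:
                     (d["mean"] >= band[0]) & (d["mean"] <= band[1]))
             [["group", "factor", "final_mean_in_band"]])
    return g.merge(final, on=["group", "factor"], how="left")
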