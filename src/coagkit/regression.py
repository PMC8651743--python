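"""Stepwise linear mapping from coagulation-factor panels to model parameters.

Each of the five thrombin-model parameters is regressed on the eight factor
concentrations (II, V, VII, VIII, IX, X, ATIII, protein C, in % activity) by
greedy forward selection: at each step the factor whose addition most reduces
the residual sum of squares is added and all coefficients are refit; selection
stops when adjusted R-squared no longer increases.  The resulting per-parameter
linear models let a CAT trajectory be predicted from a quickly measured factor
panel, and are evaluated with per-property percent errors under k-fold
cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import fitting
from .model import (
    CATCurve,
    ImpulseInput,
    ThrombinModelParams,
    cat_metrics,
    simulate_cat,
)

__all__ = [
    "FACTORS", "PARAM_NAMES", "NORMAL_BAND",
    "FactorPanel", "RegressionMap", "CVReport",
    "fit_stepwise", "predict_params", "predict_cat",
    "percent_error", "cross_validate",
]

#: canonical factor order used everywhere (panels, CSV columns, maps)
FACTORS = ("fii", "fv", "fvii", "fviii", "fix", "fx", "atiii", "pc")

PARAM_NAMES = ("k0", "k1", "k2", "kn", "kd")

#: normal band for factor concentrations, % activity
NORMAL_BAND = (60.0, 140.0)


@dataclass(frozen=True)
class FactorPanel:
    """Concentrations of the eight modeled coagulation factors, % activity."""

    fii: float
    fv: float
    fvii: float
    fviii: float
    fix: float
    fx: float
    atiii: float
    pc: float

    def __post_init__(self) -> None:
        for name in FACTORS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FACTORS])

    @classmethod
    def from_array(cls, x) -> "FactorPanel":
        return cls(**{f: float(v) for f, v in zip(FACTORS, x, strict=True)})

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in FACTORS}

    def replace(self, **changes) -> "FactorPanel":
        d = self.to_dict()
        d.update(changes)
        return FactorPanel(**d)


@dataclass(frozen=True)
class ParameterRegression:
    """One parameter's fitted linear model: ordered factors + coefficients."""

    factors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]  # aligned with ``factors``
    sse_trace: tuple[float, ...] = ()  # training SSE after each addition

    def evaluate(self, panel: FactorPanel) -> float:
        return self.intercept + sum(
            c * getattr(panel, f)
            for f, c in zip(self.factors, self.coefficients, strict=True))


@dataclass(frozen=True)
class RegressionMap:
    """Per-parameter stepwise linear models mapping a panel to model params."""

    regressions: dict[str, ParameterRegression]
    n_samples: int = 0

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.regressions)
        if missing:
            raise ValueError(f"map missing parameters: {sorted(missing)}")

    def uses_factor(self, factor: str) -> bool:
        return any(factor in r.factors and
                   any(c != 0 for f, c in zip(r.factors, r.coefficients)
                       if f == factor)
                   for r in self.regressions.values())

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "regressions": {
                p: {"factors": list(r.factors), "intercept": r.intercept,
                    "coefficients": list(r.coefficients),
                    "sse_trace": list(r.sse_trace)}
                for p, r in self.regressions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionMap":
        regs = {
            p: ParameterRegression(
                factors=tuple(r["factors"]), intercept=float(r["intercept"]),
                coefficients=tuple(float(c) for c in r["coefficients"]),
                sse_trace=tuple(float(s) for s in r.get("sse_trace", ())))
            for p, r in d["regressions"].items()}
        return cls(regressions=regs, n_samples=int(d.get("n_samples", 0)))


@dataclass(frozen=True)
class CVReport:
    """Cross-validation percent errors per CAT property (mean, SD)."""

    property_errors: dict[str, tuple[float, float]]
    fold_assignments: tuple[int, ...]
    k: int
    seed: int | None


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (beta incl. intercept, SSE)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def _adjusted_r2(sse: float, sst: float, n: int, p: int) -> float:
    if sst <= 0 or n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (sse / sst) * (n - 1) / (n - p - 1)


def _stepwise_single(X: np.ndarray, y: np.ndarray) -> ParameterRegression:
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    current_adj = 0.0  # intercept-only model has R^2 = 0
    sse_trace: list[float] = []
    beta = np.array([y.mean()])
    if sst <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        # constant response: intercept-only
        return ParameterRegression(factors=(), intercept=float(y.mean()),
                                   coefficients=(), sse_trace=())
    while remaining and len(selected) + 2 <= n:
        best = None
        for j in remaining:
            cand = selected + [j]
            b, sse = _ols(X[:, cand], y)
            if best is None or sse < best[1]:
                best = (j, sse, b)
        j, sse, b = best
        adj = _adjusted_r2(sse, sst, n, len(selected) + 1)
        # require a real improvement; guards against float-level gains once
        # the fit is already exact
        if adj <= current_adj + 1e-12:
            break
        selected.append(j)
        remaining.remove(j)
        current_adj = adj
        sse_trace.append(sse)
        beta = b
    return ParameterRegression(
        factors=tuple(FACTORS[j] for j in selected),
        intercept=float(beta[0]),
        coefficients=tuple(float(c) for c in beta[1:]),
        sse_trace=tuple(sse_trace))


def fit_stepwise(panels: list[FactorPanel],
                 params: list[ThrombinModelParams]) -> RegressionMap:
    """Greedy forward-selection regression of each model parameter on the
    eight factor concentrations.

    At every step the factor giving the largest SSE reduction is added and
    all coefficients are refit jointly; addition stops when adjusted
    R-squared fails to increase or all eight factors are in.

    Raises
    ------
    ValueError
        Fewer than 10 paired samples, or mismatched list lengths.
    """
    if len(panels) != len(params):
        raise ValueError("panels and params must pair one-to-one")
    if len(panels) < 10:
        raise ValueError(f"need >= 10 paired samples, got {len(panels)}")
    X = np.array([p.as_array() for p in panels])
    P = np.array([p.as_array() for p in params])
    regs = {name: _stepwise_single(X, P[:, i])
            for i, name in enumerate(PARAM_NAMES)}
    return RegressionMap(regressions=regs, n_samples=len(panels))


def predict_params(map: RegressionMap, panel: FactorPanel) -> ThrombinModelParams:
    """Evaluate the per-parameter linear models and project the result into
    the fitting bound box (a linear map can emit non-physical dynamics)."""
    raw = np.array([map.regressions[p].evaluate(panel) for p in PARAM_NAMES])
    return ThrombinModelParams.from_array(fitting.clip_to_bounds(raw))


def predict_cat(map: RegressionMap, panel: FactorPanel,
                input: ImpulseInput = ImpulseInput(),
                duration: float = 60.0, dt: float = 1.0 / 3.0) -> CATCurve:
    """Predict a full CAT trajectory from a factor panel."""
    return simulate_cat(predict_params(map, panel), input=input,
                        duration=duration, dt=dt)


def percent_error(model_value: float, experiment_value: float) -> float:
    """Absolute percent error of a model CAT property against experiment:
    ``|model - experiment| / experiment * 100``."""
    if experiment_value == 0:
        raise ValueError("percent error undefined for zero reference value")
    return abs((model_value - experiment_value) / experiment_value) * 100.0


_CV_PROPERTIES = ("peak", "peak_time", "etp")


def cross_validate(panels: list[FactorPanel],
                   curves: list[CATCurve],
                   k: int = 5,
                   seed: int | None = None,
                   input: ImpulseInput = ImpulseInput(),
                   fitted_params: list[ThrombinModelParams] | None = None,
                   ) -> CVReport:
    """k-fold cross-validation of the panel-to-CAT pipeline.

    Samples are partitioned into ``k`` near-equal random folds (seeded).  For
    each fold the stepwise map is trained on the remaining samples and used
    to predict the held-out CATs; percent errors of peak, peak-time and ETP
    are computed against the metrics of each held-out sample's individually
    fitted model curve, and summarized as mean and SD per property.

    ``fitted_params`` may supply per-sample fitted parameters to reuse;
    otherwise each curve is fit here.
    """
    n = len(panels)
    if len(curves) != n:
        raise ValueError("panels and curves must pair one-to-one")
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if fitted_params is None:
        fitted_params = [fitting.fit_model(c, input=input).params for c in curves]
    ref_metrics = [
        cat_metrics(simulate_cat(p, input=input,
                                 duration=float(c.times[-1]), dt=c.dt), p)
        for p, c in zip(fitted_params, curves, strict=True)]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for i, idx in enumerate(np.array_split(perm, k)):
        folds[idx] = i

    errors: dict[str, list[float]] = {p: [] for p in _CV_PROPERTIES}
    for fold in range(k):
        test = np.nonzero(folds == fold)[0]
        train = np.nonzero(folds != fold)[0]
        m = fit_stepwise([panels[i] for i in train],
                         [fitted_params[i] for i in train])
        for i in test:
            c = curves[i]
            pred = predict_cat(m, panels[i], input=input,
                               duration=float(c.times[-1]), dt=c.dt)
            pm = cat_metrics(pred, predict_params(m, panels[i]))
            for prop in _CV_PROPERTIES:
                errors[prop].append(percent_error(pm[prop], ref_metrics[i][prop]))

    summary = {p: (float(np.mean(v)), float(np.std(v)))
               for p, v in errors.items()}
    return CVReport(property_errors=summary,
                    fold_assignments=tuple(int(f) for f in folds),
                    k=k, seed=seed)
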