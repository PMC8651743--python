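"""Third-order delayed transfer-function model of thrombin generation.

The calibrated automated thrombogram (CAT) records thrombin concentration
(nM) over time after a plasma sample is triggered with a tissue-factor (TF)
impulse.  The thrombin time-history is modeled as the impulse response of

    Y(s)/U(s) = kn / (s^3 + k2*s^2 + k1*s + k0) * exp(-kd*s)

where ``U`` is a Dirac impulse of stated area (pM of TF, conventionally
5 pM), ``kd`` is a pure dead time (minutes) between triggering and thrombin
onset, and ``k0, k1, k2, kn`` shape the rise, peak and decay of the curve.
The five parameters are patient-specific.

Time is in minutes, thrombin in nM, TF in pM; the unit mismatch between
input and output is absorbed into the gain ``kn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ThrombinModelParams",
    "ImpulseInput",
    "CATCurve",
    "CATMetrics",
    "InvalidParameterError",
    "GridError",
    "simulate_cat",
    "compute_poles",
    "cubic_roots",
    "is_stable",
    "cat_metrics",
    "impulse_response",
]

#: fraction of peak used to locate thrombin onset when the dead time is unknown
ONSET_FRACTION = 0.02

#: default sampling interval, 20 s expressed in minutes (CAT instrument cadence)
DEFAULT_DT = 1.0 / 3.0

#: default simulation horizon, minutes
DEFAULT_DURATION = 60.0


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


class GridError(ValueError):
    """Raised when a time grid is empty, non-uniform, or inconsistent."""


@dataclass(frozen=True)
class ThrombinModelParams:
    """The five patient-specific parameters of the thrombin dynamics model.

    Attributes
    ----------
    k0, k1, k2 : float
        Coefficients of the characteristic cubic ``s^3 + k2 s^2 + k1 s + k0``
        (units 1/min^3, 1/min^2, 1/min).  All strictly positive.
    kn : float
        Input gain (nM·min^-3 per pM of TF impulse area).  Strictly positive.
    kd : float
        Dead time between the TF impulse and thrombin onset, minutes.
    """

    k0: float
    k1: float
    k2: float
    kn: float
    kd: float

    def __post_init__(self) -> None:
        vals = (self.k0, self.k1, self.k2, self.kn, self.kd)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if min(self.k0, self.k1, self.k2, self.kn) <= 0:
            raise InvalidParameterError(
                f"k0, k1, k2, kn must be > 0, got {vals[:4]}"
            )
        if self.kd < 0:
            raise InvalidParameterError(f"kd must be >= 0, got {self.kd}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2, self.kn, self.kd])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ThrombinModelParams":
        return cls(*(float(v) for v in x))

    def to_dict(self) -> dict:
        return {"k0": self.k0, "k1": self.k1, "k2": self.k2,
                "kn": self.kn, "kd": self.kd}

    @classmethod
    def from_dict(cls, d: dict) -> "ThrombinModelParams":
        return cls(k0=float(d["k0"]), k1=float(d["k1"]), k2=float(d["k2"]),
                   kn=float(d["kn"]), kd=float(d["kd"]))


@dataclass(frozen=True)
class ImpulseInput:
    """Dirac TF impulse of stated area (pM)."""

    magnitude: float = 5.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.magnitude) and self.magnitude > 0):
            raise InvalidParameterError(
                f"impulse magnitude must be finite and > 0, got {self.magnitude}"
            )


class CATCurve:
    """A sampled thrombin time-history on a uniform grid starting at 0.

    Negative thrombin values within floating-point undershoot are clipped to
    zero (thrombin concentration is physically nonnegative); genuinely
    negative data are rejected.
    """

    __slots__ = ("times", "thrombin")

    def __init__(self, times: np.ndarray, thrombin: np.ndarray,
                 clip_negative: bool = True):
        times = np.asarray(times, dtype=float)
        thrombin = np.asarray(thrombin, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise GridError("time grid must be a non-empty 1-D array")
        if thrombin.shape != times.shape:
            raise GridError("times and thrombin must have equal length")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(thrombin)):
            raise GridError("non-finite values in curve")
        if times.size > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise GridError("time grid must be strictly increasing")
            dt = steps[0]
            if np.any(np.abs(steps - dt) > 1e-9 * max(dt, 1.0)):
                raise GridError("time grid must be uniform")
        if clip_negative:
            thrombin = np.maximum(thrombin, 0.0)
        elif np.any(thrombin < 0):
            raise GridError("negative thrombin values")
        self.times = times
        self.thrombin = thrombin

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise GridError("dt undefined for a single-sample curve")
        return float(self.times[1] - self.times[0])

    def same_grid(self, other: "CATCurve", rtol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and bool(np.allclose(self.times, other.times, rtol=rtol, atol=1e-12)))

    def resample(self, times: np.ndarray) -> "CATCurve":
        """Linear resampling onto a new grid; extrapolates with edge values."""
        y = np.interp(np.asarray(times, dtype=float), self.times, self.thrombin)
        return CATCurve(np.asarray(times, dtype=float), y)


@dataclass(frozen=True)
class CATMetrics:
    """Scalar CAT properties used as control targets.

    peak (nM), peak_time (min), time_delay (min, thrombin-onset delay),
    etp (nM·min, total trapezoidal area = endogenous thrombin potential),
    s_tail (nM·min, post-peak area).
    """

    peak: float
    peak_time: float
    time_delay: float
    etp: float
    s_tail: float

    def __getitem__(self, key: str) -> float:
        return getattr(self, key)

    def to_dict(self) -> dict:
        return {"peak": self.peak, "peak_time": self.peak_time,
                "time_delay": self.time_delay, "etp": self.etp,
                "s_tail": self.s_tail}


# ---------------------------------------------------------------------------
# impulse response of 1 / (s^3 + k2 s^2 + k1 s + k0)
# ---------------------------------------------------------------------------

def _root_clusters(roots: np.ndarray, tol: float) -> list[tuple[complex, int]]:
    """Group the three roots into (value, multiplicity) clusters."""
    order = np.argsort([(r.real, r.imag) for r in roots], axis=0)[:, 0]
    rs = roots[order]
    clusters: list[list[complex]] = [[rs[0]]]
    for r in rs[1:]:
        if abs(r - clusters[-1][-1]) <= tol:
            clusters[-1].append(r)
        else:
            clusters.append([r])
    return [(complex(np.mean(c)), len(c)) for c in clusters]


def impulse_response(k0: float, k1: float, k2: float,
                     t: np.ndarray) -> np.ndarray:
    """Evaluate g(t), the impulse response of ``1/(s^3 + k2 s^2 + k1 s + k0)``,
    at the (nonnegative) times ``t``, via partial fractions.

    Distinct roots use the residue expansion g(t) = sum_i e^{p_i t} / prod_{j != i}
    (p_i - p_j).  Roots coinciding within a relative 1e-8 are merged and handled
    with the confluent (repeated-root) formulas; if the partial-fraction result
    is not finite a state-space integration fallback is used.
    """
    t = np.asarray(t, dtype=float)
    roots = np.roots([1.0, k2, k1, k0])
    scale = max(1.0, float(np.max(np.abs(roots))))
    # a numerically multiple root is resolved by the eigen-solver only to
    # ~eps^(1/multiplicity) (~1.2e-5 for a triple root); below ~2e-5
    # separation the residue cancellation in the distinct-root formula loses
    # more accuracy than merging the cluster does
    clusters = _root_clusters(roots, 2e-5 * scale)

    g = np.zeros(t.shape, dtype=complex)
    try:
        if len(clusters) == 3:
            p, q, r = (c[0] for c in clusters)
            for pi, (pj, pk) in ((p, (q, r)), (q, (p, r)), (r, (p, q))):
                g += np.exp(pi * t) / ((pi - pj) * (pi - pk))
        elif len(clusters) == 2:
            # one double root p, one simple root q
            (p, mp), (q, mq) = clusters
            if mp != 2:
                (p, mp), (q, mq) = (q, mq), (p, mp)
            d = p - q
            g = (np.exp(q * t) / d**2
                 + t * np.exp(p * t) / d
                 - np.exp(p * t) / d**2)
        else:
            # triple root
            p = clusters[0][0]
            g = 0.5 * t**2 * np.exp(p * t)
        out = np.real(g)
        if np.all(np.isfinite(out)):
            return out
    except (ZeroDivisionError, FloatingPointError):
        pass
    # numerical state-space fallback for ill-conditioned near-confluent roots
    sys = signal.lti([1.0], [1.0, k2, k1, k0])
    _, y = signal.impulse(sys, T=np.maximum(t, 0.0))
    return np.asarray(y, dtype=float)


def simulate_cat(params: ThrombinModelParams,
                 input: ImpulseInput = ImpulseInput(),
                 duration: float = DEFAULT_DURATION,
                 dt: float = DEFAULT_DT) -> CATCurve:
    """Simulate the thrombin time-history for a TF impulse.

    Returns ``y(t) = magnitude * kn * g(t - kd)`` for ``t >= kd`` and 0
    before, evaluated on the uniform grid ``0, dt, ..., <= duration``.

    Raises
    ------
    InvalidParameterError
        If parameters are invalid (enforced by ``ThrombinModelParams``).
    GridError
        If ``dt >= duration`` or ``duration <= kd``.
    """
    if dt <= 0 or dt >= duration:
        raise GridError(f"need 0 < dt < duration, got dt={dt}, duration={duration}")
    if duration <= params.kd:
        raise GridError(f"duration {duration} must exceed dead time {params.kd}")
    n = int(math.floor(duration / dt + 1e-9)) + 1
    times = np.arange(n) * dt
    return _simulate_on_grid(params, input.magnitude, times)


def _simulate_on_grid(params: ThrombinModelParams, magnitude: float,
                      times: np.ndarray) -> CATCurve:
    tau = times - params.kd
    active = tau >= 0
    y = np.zeros_like(times)
    if np.any(active):
        y[active] = magnitude * params.kn * impulse_response(
            params.k0, params.k1, params.k2, tau[active])
    return CATCurve(times, y)


def cubic_roots(k2: float, k1: float, k0: float) -> np.ndarray:
    """Roots of ``s^3 + k2 s^2 + k1 s + k0`` for arbitrary real coefficients,
    sorted by real part then imaginary part.  Accepts degenerate coefficient
    sets (e.g. all zero -> triple root at 0) that the parameter type itself
    rules out."""
    roots = np.roots([1.0, k2, k1, k0])
    # symmetrize conjugate pairs against round-off
    imag = roots[np.abs(roots.imag) > 0]
    if imag.size == 2:
        re = float(np.mean(imag.real))
        im = float(np.mean(np.abs(imag.imag)))
        real_root = roots[np.abs(roots.imag) == 0]
        if real_root.size == 1:
            roots = np.array([complex(re, -im), complex(re, im),
                              complex(real_root[0].real, 0.0)])
    order = np.lexsort((roots.imag, roots.real))
    return roots[order]


def compute_poles(params: ThrombinModelParams) -> np.ndarray:
    """Poles of the fitted model: roots of the characteristic cubic
    ``s^3 + k2 s^2 + k1 s + k0``.

    Returned sorted by real part then imaginary part; complex roots come in
    conjugate pairs.  Poles with negative real parts indicate a stable
    (self-limiting) thrombin response.
    """
    return cubic_roots(params.k2, params.k1, params.k0)


def is_stable(params: ThrombinModelParams) -> bool:
    """True iff all three poles lie strictly in the left half-plane.

    Equivalent to the Routh–Hurwitz condition k0 > 0, k2 > 0, k2*k1 > k0.
    """
    return params.k0 > 0 and params.k2 > 0 and params.k2 * params.k1 > params.k0


def cat_metrics(curve: CATCurve,
                params: ThrombinModelParams | None = None) -> CATMetrics:
    """Scalar properties of a CAT curve.

    peak and peak_time take the first grid point attaining the maximum; areas
    are trapezoidal.  The onset delay is read from ``params.kd`` when the
    generating model is known, otherwise from the first time thrombin exceeds
    2% of peak.
    """
    y = curve.thrombin
    t = curve.times
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    peak_time = float(t[ipk])
    etp = float(np.trapezoid(y, t))
    s_tail = float(np.trapezoid(y[ipk:], t[ipk:])) if ipk < len(y) - 1 else 0.0
    if peak <= 0.0:
        return CATMetrics(0.0, 0.0, 0.0, 0.0, 0.0)
    if params is not None:
        delay = float(params.kd)
    else:
        above = np.nonzero(y >= ONSET_FRACTION * peak)[0]
        delay = float(t[above[0]]) if above.size else 0.0
    delay = min(delay, peak_time)
    return CATMetrics(peak, peak_time, delay, etp, s_tail)
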