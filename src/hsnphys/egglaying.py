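"""Two-state interval model of C. elegans egg-laying behavior.

Egg laying alternates between an active state, in which eggs are laid in
quick succession, and a long quiescent (inactive) state. The marginal
distribution of intervals between consecutive egg-laying events under this
two-state point process is a two-component exponential mixture with CDF

    F(x) = 1 - [A e^{-a x} + B e^{-p b x}]
    A = p (a - b) / (a - p b),   B = a (1 - p) / (a - p b)

where ``a`` (1/min) is the fast, intra-cluster event rate, ``p b`` (1/min)
the slow rate governing inactive-state dwell, and ``p`` the dimensionless
probability weighting the two. A + B = 1 identically, so F(0) = 0.

The fast and slow time constants 1/a and 1/(p b) are the cluster and
quiescence timescales; the slow one is typically tens of minutes.

Fitting follows the original analysis: nonlinear least squares of F
against the empirical cumulative probability of the observed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError, ParameterError
from .fitting import FitResult, asymptotic_ci95

__all__ = [
    "IntervalModelParams",
    "IntervalSample",
    "EggTimeline",
    "interval_cdf",
    "interval_pdf",
    "fit_intervals",
    "time_constants",
    "mean_interval",
]


@dataclass(frozen=True)
class IntervalModelParams:
    """Parameters (p, a, b) of the two-state interval model.

    p : dimensionless, 0 < p < 1
    a : fast rate, 1/min, > 0
    b : base slow rate, 1/min, > 0 (the slow mixture rate is p*b)

    a == p*b is excluded (the mixture-weight denominator vanishes).
    """

    p: float
    a: float
    b: float

    def validate(self) -> "IntervalModelParams":
        if not (0.0 < self.p < 1.0):
            raise ParameterError(f"p must lie in (0, 1), got {self.p}")
        if self.a <= 0 or self.b <= 0:
            raise ParameterError(f"rates must be positive, got a={self.a}, b={self.b}")
        if self.a == self.p * self.b:
            raise ParameterError("a == p*b: mixture weights undefined")
        return self

    @property
    def weight_fast(self) -> float:
        """Mixture weight A = p(a-b)/(a-p*b) on the fast (rate a) component."""
        return self.p * (self.a - self.b) / (self.a - self.p * self.b)


@dataclass(frozen=True)
class IntervalSample:
    """Inter-event intervals in minutes, all positive."""

    intervals: np.ndarray

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.size and iv.min() <= 0:
            raise InputError("all intervals must be > 0")

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class EggTimeline:
    """Event times of one animal, minutes from recording start."""

    event_times: np.ndarray
    duration: float
    animal_id: str = "animal_0"

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if self.duration <= 0:
            raise InputError("duration must be > 0")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise InputError("event_times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise InputError("event_times must lie within [0, duration]")

    def intervals(self) -> IntervalSample:
        """Intervals between consecutive events. The open interval after the
        last event is censored by the end of observation and is dropped."""
        return IntervalSample(np.diff(self.event_times))


def _weights(params: IntervalModelParams) -> tuple[float, float]:
    a_w = params.weight_fast
    return a_w, 1.0 - a_w


def interval_cdf(x, params: IntervalModelParams):
    """F(x) = 1 - [A e^{-a x} + B e^{-p b x}] for x >= 0 (minutes)."""
    params.validate()
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise InputError("interval_cdf is defined for x >= 0")
    aw, bw = _weights(params)
    out = 1.0 - (aw * np.exp(-params.a * xv) + bw * np.exp(-params.p * params.b * xv))
    return out if out.ndim else float(out)


def interval_pdf(x, params: IntervalModelParams):
    """f(x) = A a e^{-a x} + B p b e^{-p b x}; integrates to 1."""
    params.validate()
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise InputError("interval_pdf is defined for x >= 0")
    aw, bw = _weights(params)
    slow = params.p * params.b
    out = aw * params.a * np.exp(-params.a * xv) + bw * slow * np.exp(-slow * xv)
    return out if out.ndim else float(out)


def time_constants(params: IntervalModelParams) -> tuple[float, float]:
    """(tau_fast, tau_slow) = (1/a, 1/(p*b)) in minutes.

    tau_fast is the intra-cluster timescale; tau_slow the quiescence
    timescale. Raises if the labeling is inverted (a <= p*b).
    """
    params.validate()
    tau_fast = 1.0 / params.a
    tau_slow = 1.0 / (params.p * params.b)
    if not tau_fast < tau_slow:
        raise ParameterError("component labels require a > p*b (tau_fast < tau_slow)")
    return tau_fast, tau_slow


def mean_interval(params: IntervalModelParams) -> float:
    """E[X] = A/a + B/(p*b), minutes."""
    params.validate()
    aw, bw = _weights(params)
    return aw / params.a + bw / (params.p * params.b)


# --- fitting ---------------------------------------------------------------

_BOUNDS_LO = np.array([1e-4, 1e-6, 1e-6])
_BOUNDS_HI = np.array([1.0 - 1e-4, 1e3, 1e3])


def _safe_cdf(xv: np.ndarray, p: float, a: float, b: float) -> np.ndarray:
    # guard the a == p*b singularity along the optimizer's path
    denom = a - p * b
    if abs(denom) < 1e-12:
        a = a + 1e-9
        denom = a - p * b
    aw = p * (a - b) / denom
    return 1.0 - (aw * np.exp(-a * xv) + (1.0 - aw) * np.exp(-p * b * xv))


def _default_init(x: np.ndarray) -> np.ndarray:
    # two-piece exponential split at the sample median: fast rate from the
    # short half, slow rate from the long half
    med = np.median(x)
    short = x[x <= med]
    long_ = x[x > med]
    a0 = 1.0 / max(float(np.mean(short)), 1e-6)
    slow0 = 1.0 / max(float(np.mean(long_)), 1e-6) if long_.size else a0 / 10.0
    p0 = 0.5
    b0 = slow0 / p0
    theta = np.array([p0, a0, b0])
    return np.clip(theta, _BOUNDS_LO * 1.01, _BOUNDS_HI * 0.99)


def _canonicalize(p: float, a: float, b: float) -> tuple[float, float, float]:
    """Relabel components so the rate-a exponential is the fast one.

    The mixture (weight A on rate a, weight 1-A on rate p*b) is invariant
    under swapping the two rates with the complementary weight; this remap
    re-expresses the same distribution with a > p*b.
    """
    slow = p * b
    if a >= slow:
        return p, a, b
    aw = p * (a - b) / (a - slow)
    a_new, slow_new, w_new = slow, a, 1.0 - aw
    p_new = (w_new * (a_new - slow_new) + slow_new) / a_new
    p_new = float(np.clip(p_new, _BOUNDS_LO[0], _BOUNDS_HI[0]))
    b_new = slow_new / p_new
    return p_new, a_new, b_new


def fit_intervals(sample: IntervalSample, init: IntervalModelParams | None = None) -> FitResult:
    """Least-squares fit of the interval CDF to the empirical cumulative
    probability of the sample.

    The empirical cumulative probability uses Hazen plotting positions
    (i - 0.5)/n at the sorted intervals. Parameters are box-constrained to
    the valid region; when no ``init`` is given, a two-piece exponential
    split at the sample median seeds the optimizer. 95% CIs are asymptotic.

    Non-convergence is reported via ``converged=False``, not raised.
    """
    x = np.sort(sample.intervals)
    n = x.size
    if n < 10:
        raise InputError(f"need at least 10 intervals to fit, got {n}")
    ecdf = (np.arange(1, n + 1) - 0.5) / n

    theta0 = (
        np.clip(np.array([init.p, init.a, init.b]), _BOUNDS_LO, _BOUNDS_HI)
        if init is not None
        else _default_init(x)
    )

    def residuals(theta):
        return _safe_cdf(x, *theta) - ecdf

    res = least_squares(residuals, theta0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf")

    p_hat, a_hat, b_hat = res.x
    if a_hat < p_hat * b_hat:
        # refit from the equivalent canonical labeling so that the Jacobian
        # (hence the CIs) refers to the reported parameterization
        theta_c = np.clip(_canonicalize(p_hat, a_hat, b_hat), _BOUNDS_LO, _BOUNDS_HI)
        res = least_squares(residuals, theta_c, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf")
        p_hat, a_hat, b_hat = res.x

    rss = float(2.0 * res.cost)
    hw = asymptotic_ci95(res.x, res.jac, rss, n)
    names = ("p", "a", "b")
    ci95 = {nm: (float(v - h), float(v + h)) for nm, v, h in zip(names, res.x, hw)}
    params = IntervalModelParams(float(p_hat), float(a_hat), float(b_hat))
    return FitResult(params=params, ci95=ci95, rss=rss, converged=bool(res.success), n=n)
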