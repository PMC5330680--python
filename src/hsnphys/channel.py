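"""Steady-state biophysics of T-type (low-voltage-activated) calcium channels.

Analysis pipeline for two-electrode voltage-clamp data from Xenopus oocytes
expressing Cav3.1-family channels in a barium bath:

* peak-current extraction from step sweeps with capacitive blanking,
* chord conductance via the Goldman-Hodgkin-Katz (GHK) flux equation as the
  driving term (not the linear V - Vrev chord),
* Boltzmann fits of the normalized steady-state activation and inactivation
  curves (V50 and slope factor k with asymptotic 95% CIs),
* the window current w(V) = m_inf(V) * h_inf(V) arising from the overlap of
  the two curves, with peak-location and width metrics,
* the leak-current quality-control rule used to accept oocytes.

Voltages are millivolts, currents microamps, concentrations millimolar,
temperature kelvin. Inward current is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares, minimize_scalar, brentq

from .errors import InputError, ParameterError
from .fitting import FitResult, asymptotic_ci95

__all__ = [
    "BoltzmannParams",
    "GHKSettings",
    "StepProtocol",
    "SweepSet",
    "ConductanceCurve",
    "WindowMetrics",
    "ChannelModel",
    "boltzmann",
    "ghk_drive",
    "reversal_potential",
    "extract_peaks",
    "chord_conductance_curve",
    "availability_curve",
    "fit_boltzmann",
    "window_curve",
    "window_metrics",
    "qc_leak",
    "DEFAULT_ACTIVATION_PROTOCOL",
    "DEFAULT_INACTIVATION_PROTOCOL",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

Sense = Literal["activation", "inactivation"]


@dataclass(frozen=True)
class BoltzmannParams:
    """Half-voltage (mV), slope factor k (mV, > 0) and gating sense."""

    v_half: float
    k: float
    sense: Sense = "activation"

    def validate(self) -> "BoltzmannParams":
        if self.k <= 0:
            raise ParameterError(f"slope factor k must be > 0, got {self.k}")
        if self.sense not in ("activation", "inactivation"):
            raise ParameterError(f"unknown sense {self.sense!r}")
        return self


@dataclass(frozen=True)
class GHKSettings:
    """Constant-field flux settings.

    Defaults describe the recording bath: divalent barium charge carrier
    (z = 2), 10 mM external Ba2+, room temperature. Intracellular Ba2+ is
    not measurable in the oocyte and is set to a nominal 0.1 mM; because
    conductance curves are normalized to their maximum, only the shape of
    the drive versus voltage matters, not its absolute scale.
    """

    z: int = 2
    temperature: float = 295.0
    c_in: float = 0.1
    c_out: float = 10.0
    permeability_scale: float = 1.0

    def validate(self) -> "GHKSettings":
        if self.z == 0:
            raise ParameterError("valence z must be nonzero")
        if self.temperature <= 0 or self.c_in <= 0 or self.c_out <= 0:
            raise ParameterError("temperature and concentrations must be > 0")
        return self

    @property
    def thermal_voltage_mv(self) -> float:
        """RT/F in millivolts."""
        return 1000.0 * GAS_CONSTANT * self.temperature / FARADAY


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol. Activation: steps from holding. Inactivation:
    a long prepulse per listed voltage, then a fixed test step."""

    kind: Sense
    holding: float
    steps: tuple
    step_duration: float  # ms
    sample_interval: float = 0.1  # ms
    prepulse_duration: float | None = None  # ms, inactivation only
    test_voltage: float | None = None  # mV, inactivation only

    def validate(self) -> "StepProtocol":
        if not self.steps:
            raise InputError("protocol needs at least one step voltage")
        if self.step_duration <= 0 or self.sample_interval <= 0:
            raise ParameterError("durations must be > 0")
        if self.kind == "inactivation":
            if self.prepulse_duration is None or self.test_voltage is None:
                raise ParameterError("inactivation protocol needs prepulse_duration and test_voltage")
            if self.prepulse_duration <= 0:
                raise ParameterError("prepulse_duration must be > 0")
        return self

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.step_duration, self.sample_interval)


DEFAULT_ACTIVATION_PROTOCOL = StepProtocol(
    kind="activation",
    holding=-90.0,
    steps=tuple(np.arange(-80.0, 10.0 + 1e-9, 10.0)),
    step_duration=150.0,
)

DEFAULT_INACTIVATION_PROTOCOL = StepProtocol(
    kind="inactivation",
    holding=-90.0,
    steps=tuple(np.arange(-100.0, -30.0 + 1e-9, 5.0)),
    step_duration=150.0,
    prepulse_duration=1000.0,
    test_voltage=-30.0,
)


@dataclass(frozen=True)
class SweepSet:
    """Current sweeps on a shared time grid, one series per protocol step."""

    protocol: StepProtocol
    time: np.ndarray  # ms
    currents: np.ndarray  # µA, shape (n_steps, n_samples)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.atleast_2d(np.asarray(self.currents, dtype=float))
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "currents", c)
        if c.shape != (len(self.protocol.steps), t.size):
            raise InputError(
                f"currents shape {c.shape} does not match "
                f"({len(self.protocol.steps)} steps, {t.size} samples)"
            )


@dataclass(frozen=True)
class ConductanceCurve:
    """Normalized chord conductance versus voltage."""

    voltages: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "g", g)
        if v.size != g.size:
            raise InputError("voltages and g must have equal length")
        if v.size == 0:
            raise InputError("empty conductance curve")
        if np.any(g < 0):
            raise InputError("conductance values must be >= 0")


@dataclass(frozen=True)
class WindowMetrics:
    """Location and extent of the window current."""

    v_peak: float
    w_peak: float
    v_low: float
    v_high: float
    width: float
    threshold_frac: float


@dataclass(frozen=True)
class ChannelModel:
    """Minimal kinetic container for simulating step sweeps: steady-state
    Boltzmann gating with first-order relaxation time constants."""

    scale: float
    act: BoltzmannParams
    inact: BoltzmannParams
    tau_m: float = 5.0  # ms
    tau_h: float = 30.0  # ms
    ghk: GHKSettings = field(default_factory=GHKSettings)

    def validate(self) -> "ChannelModel":
        if self.tau_m <= 0 or self.tau_h <= 0:
            raise ParameterError("time constants must be > 0")
        self.act.validate()
        self.inact.validate()
        self.ghk.validate()
        return self


def boltzmann(v, params: BoltzmannParams):
    """Steady-state gating fraction at voltage v (mV).

    activation:   1 / (1 + exp((v_half - v)/k)), increasing in v
    inactivation: 1 / (1 + exp((v - v_half)/k)), decreasing in v
    """
    params.validate()
    vv = np.asarray(v, dtype=float)
    if params.sense == "activation":
        arg = (params.v_half - vv) / params.k
    else:
        arg = (vv - params.v_half) / params.k
    out = 1.0 / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def ghk_drive(v, ghk: GHKSettings):
    """GHK current per unit permeability at voltage v (mV).

    I = P z² F² V / (RT) · (c_in - c_out e^{-u}) / (1 - e^{-u}),
    u = zFV/RT. Near V = 0 the 0/0 is resolved by the Taylor splice
    u/(1 - e^{-u}) = 1 + u/2 + u²/12 + O(u⁴) for |u| < 1e-4, giving the
    exact limit z F P (c_in - c_out) at V = 0. Units are arbitrary but
    consistent (proportional to µA for a fixed permeability scale).
    """
    ghk.validate()
    vv = np.asarray(v, dtype=float)
    u = ghk.z * vv / ghk.thermal_voltage_mv
    numer = ghk.c_in - ghk.c_out * np.exp(-u)
    small = np.abs(u) < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_exact = u / (-np.expm1(-u))
    ratio_taylor = 1.0 + u / 2.0 + u * u / 12.0
    ratio = np.where(small, ratio_taylor, ratio_exact)
    out = ghk.permeability_scale * ghk.z * FARADAY * numer * ratio
    return out if out.ndim else float(out)


def reversal_potential(ghk: GHKSettings) -> float:
    """Nernst reversal of the GHK drive: (RT/zF) ln(c_out/c_in), in mV."""
    ghk.validate()
    return ghk.thermal_voltage_mv / ghk.z * float(np.log(ghk.c_out / ghk.c_in))


def extract_peaks(sweeps: SweepSet, blank_ms: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-sweep peak current: the signed value of largest magnitude after
    discarding the first ``blank_ms`` of the step (capacitive blanking).

    Inward currents are negative. An all-flat sweep yields peak 0 with a
    logged warning.
    """
    if blank_ms >= sweeps.protocol.step_duration:
        raise InputError("blank_ms must be shorter than the step")
    keep = sweeps.time >= blank_ms
    voltages = np.asarray(sweeps.protocol.steps, dtype=float)
    peaks = np.empty(voltages.size)
    for i, trace in enumerate(sweeps.currents):
        seg = trace[keep]
        idx = int(np.argmax(np.abs(seg)))
        peaks[i] = seg[idx]
        if np.all(seg == seg[0]) and seg[0] == 0.0:
            logger.warning("sweep %d (%.1f mV) is flat; peak set to 0", i, voltages[i])
    return voltages, peaks


def chord_conductance_curve(voltages, peaks, ghk: GHKSettings) -> ConductanceCurve:
    """g(V) = peak(V) / ghk_drive(V), normalized so max(g) = 1."""
    v = np.asarray(voltages, dtype=float)
    pk = np.asarray(peaks, dtype=float)
    drive = np.asarray(ghk_drive(v, ghk))
    # characteristic drive magnitude for these settings; a step essentially at
    # the reversal potential produces |drive| many orders below this
    scale = abs(ghk.permeability_scale) * abs(ghk.z) * FARADAY * (ghk.c_in + ghk.c_out)
    bad = np.abs(drive) < 1e-9 * scale
    if np.any(bad):
        offending = v[bad]
        raise InputError(
            f"test step at the reversal potential (drive = 0) at {offending.tolist()} mV"
        )
    g = pk / drive
    g = np.clip(g, 0.0, None)
    gmax = g.max()
    if gmax <= 0:
        raise InputError("all conductances are zero; cannot normalize")
    return ConductanceCurve(voltages=v, g=g / gmax)


def availability_curve(prepulse_voltages, peaks) -> ConductanceCurve:
    """Steady-state availability from an inactivation protocol.

    Every test pulse is delivered at the same voltage, so the GHK drive is a
    common factor and availability is simply peak magnitude normalized to
    its maximum, plotted against the prepulse voltage.
    """
    v = np.asarray(prepulse_voltages, dtype=float)
    mag = np.abs(np.asarray(peaks, dtype=float))
    if mag.max() <= 0:
        raise InputError("all peaks are zero; cannot normalize availability")
    return ConductanceCurve(voltages=v, g=mag / mag.max())


_K_BOUNDS = (0.1, 100.0)
_V_BOUNDS = (-200.0, 100.0)


def fit_boltzmann(
    curve: ConductanceCurve,
    sense: Sense,
    init: BoltzmannParams | None = None,
) -> FitResult:
    """Unweighted least-squares Boltzmann fit of a normalized curve.

    Returns v_half and k with asymptotic 95% CIs. The fit is flagged
    non-converged when the optimizer fails or a parameter is pinned at its
    bound (the signature of fitting the wrong sense or saturated data).
    """
    v = curve.voltages
    g = curve.g
    n = v.size
    if n < 4:
        raise InputError(f"need at least 4 points to fit a Boltzmann, got {n}")
    if np.any(g > 1.0 + 0.5):
        raise InputError("curve values far above 1; normalize before fitting")

    if init is not None:
        theta0 = np.array([init.v_half, init.k])
    else:
        v50_guess = float(v[np.argmin(np.abs(g - 0.5))])
        theta0 = np.array([v50_guess, 5.0])
    lo = np.array([_V_BOUNDS[0], _K_BOUNDS[0]])
    hi = np.array([_V_BOUNDS[1], _K_BOUNDS[1]])
    theta0 = np.clip(theta0, lo, hi)

    sign = 1.0 if sense == "activation" else -1.0

    def residuals(theta):
        v50, k = theta
        return 1.0 / (1.0 + np.exp(sign * (v50 - v) / k)) - g

    res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
    v50_hat, k_hat = res.x
    rss = float(2.0 * res.cost)
    hw = asymptotic_ci95(res.x, res.jac, rss, n)
    ci95 = {
        "v_half": (float(v50_hat - hw[0]), float(v50_hat + hw[0])),
        "k": (float(k_hat - hw[1]), float(k_hat + hw[1])),
    }
    at_bound = bool(
        np.any(np.isclose(res.x, lo, rtol=0, atol=1e-6))
        or np.any(np.isclose(res.x, hi, rtol=0, atol=1e-6))
    )
    params = BoltzmannParams(v_half=float(v50_hat), k=float(k_hat), sense=sense)
    return FitResult(
        params=params,
        ci95=ci95,
        rss=rss,
        converged=bool(res.success) and not at_bound,
        n=n,
    )


def _check_window_senses(act: BoltzmannParams, inact: BoltzmannParams) -> None:
    if act.sense != "activation" or inact.sense != "inactivation":
        raise ParameterError("window requires act.sense='activation' and inact.sense='inactivation'")
    act.validate()
    inact.validate()


def window_curve(act: BoltzmannParams, inact: BoltzmannParams, v_grid) -> tuple[np.ndarray, np.ndarray]:
    """w(V) = m_inf(V) * h_inf(V): the steady-state window-current fraction."""
    _check_window_senses(act, inact)
    v = np.asarray(v_grid, dtype=float)
    return v, np.asarray(boltzmann(v, act)) * np.asarray(boltzmann(v, inact))


def window_metrics(
    act: BoltzmannParams,
    inact: BoltzmannParams,
    threshold_frac: float = 0.1,
) -> WindowMetrics:
    """Peak location/height and the voltage range where w >= threshold_frac * w_peak.

    w is log-concave (each log-Boltzmann term is concave in V), hence
    unimodal: the peak is located by golden-section refinement of a coarse
    grid and the range edges by bisection outward from the peak.
    """
    _check_window_senses(act, inact)
    if not (0.0 < threshold_frac < 1.0):
        raise ParameterError("threshold_frac must lie in (0, 1)")

    def w(v):
        return float(boltzmann(v, act) * boltzmann(v, inact))

    span = 25.0 * max(act.k, inact.k)
    lo = min(act.v_half, inact.v_half) - span
    hi = max(act.v_half, inact.v_half) + span
    grid = np.linspace(lo, hi, 2001)
    wg = np.asarray(boltzmann(grid, act)) * np.asarray(boltzmann(grid, inact))
    i0 = int(np.argmax(wg))
    bl = grid[max(i0 - 1, 0)]
    bh = grid[min(i0 + 1, grid.size - 1)]
    opt = minimize_scalar(lambda v: -w(v), bounds=(bl, bh), method="bounded",
                          options={"xatol": 1e-7})
    v_peak = float(opt.x)
    w_peak = w(v_peak)

    target = threshold_frac * w_peak

    def edge(direction: float) -> float:
        a = v_peak
        step = max(act.k, inact.k)
        b = a + direction * step
        while w(b) > target:
            step *= 2.0
            b = a + direction * step
            if abs(b - v_peak) > 1e5:  # pragma: no cover - unreachable for valid params
                raise ParameterError("window edge bracket expansion failed")
        f = lambda v: w(v) - target
        x0, x1 = (b, a) if direction < 0 else (a, b)
        return float(brentq(f, x0, x1, xtol=1e-9))

    v_low = edge(-1.0)
    v_high = edge(+1.0)
    return WindowMetrics(
        v_peak=v_peak,
        w_peak=w_peak,
        v_low=v_low,
        v_high=v_high,
        width=v_high - v_low,
        threshold_frac=threshold_frac,
    )


def qc_leak(holding_current: float, threshold: float = -0.1) -> bool:
    """Oocyte acceptance rule: leak magnitude at holding must be strictly
    below the threshold magnitude (default |I| < 0.1 µA at -90 mV);
    exactly at the threshold fails."""
    return abs(holding_current) < abs(threshold)
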