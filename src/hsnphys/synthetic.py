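"""Seeded synthetic-data generators for every input the analyses consume.

Each generator emulates the statistical structure the corresponding model
assumes, so every downstream fit can be exercised against data of known
ground truth:

* egg-laying intervals: i.i.d. draws from the two-component exponential
  mixture (weight A on rate ``a``, weight 1-A on rate ``p*b``);
* event timelines: cumulative interval sums truncated at the assay length;
* steady-state conductance curves: Boltzmann gating plus Gaussian noise,
  clipped at zero, one curve per simulated cell;
* voltage-clamp sweeps: scale · m(t) · h(t) · GHK drive with first-order
  gating relaxation, plus Gaussian current noise;
* fluorescence traces: baseline + linear photobleach drift + exponential-
  decay transients + Gaussian noise, paired with a noisy flat background;
* embryo stage counts: multinomial draws over the seven categories.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .channel import (
    BoltzmannParams,
    ChannelModel,
    ConductanceCurve,
    StepProtocol,
    SweepSet,
    boltzmann,
    ghk_drive,
)
from .egglaying import EggTimeline, IntervalModelParams, IntervalSample
from .errors import InputError, ParameterError
from .stats import STAGE_CATEGORIES, StageDistribution
from .traces import FluorescenceTrace

__all__ = [
    "sample_intervals",
    "simulate_timeline",
    "simulate_peak_conductance",
    "simulate_inactivation_curve",
    "simulate_sweeps",
    "simulate_fluorescence",
    "sample_stages",
]


def _mixture_weight(params: IntervalModelParams) -> float:
    params.validate()
    w = params.weight_fast
    if not (0.0 <= w <= 1.0):
        raise ParameterError(
            f"mixture weight A = {w:.4g} outside [0, 1]; sampling requires a "
            "proper two-exponential mixture (typically a > b)"
        )
    return w


def sample_intervals(params: IntervalModelParams, n: int, seed: int) -> IntervalSample:
    """n i.i.d. intervals (minutes) from the two-exponential mixture."""
    if n < 1:
        raise InputError("n must be >= 1")
    w = _mixture_weight(params)
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < w
    draws = np.where(
        fast,
        rng.exponential(1.0 / params.a, size=n),
        rng.exponential(1.0 / (params.p * params.b), size=n),
    )
    # exponential draws are > 0 almost surely; enforce the invariant anyway
    draws = np.maximum(draws, np.finfo(float).tiny)
    return IntervalSample(draws)


def simulate_timeline(
    params: IntervalModelParams,
    duration: float,
    seed: int,
    animal_id: str = "sim_0",
) -> EggTimeline:
    """Renewal process: cumulative interval sums truncated at ``duration``."""
    if duration <= 0:
        raise InputError("duration must be > 0")
    _mixture_weight(params)
    rng = np.random.default_rng(seed)
    mean = 1.0 / params.a + 1.0 / (params.p * params.b)
    times = []
    t = 0.0
    w = _mixture_weight(params)
    # draw in chunks sized by the expected count to limit rng calls
    chunk = max(16, int(2 * duration / mean) + 8)
    while t <= duration:
        fast = rng.random(chunk) < w
        draws = np.where(
            fast,
            rng.exponential(1.0 / params.a, size=chunk),
            rng.exponential(1.0 / (params.p * params.b), size=chunk),
        )
        for d in draws:
            t += d
            if t > duration:
                break
            times.append(t)
    return EggTimeline(np.array(times), duration=duration, animal_id=animal_id)


def _noisy_curves(
    base: np.ndarray,
    voltages: np.ndarray,
    noise_sd: float,
    n_cells: int,
    seed: int,
) -> list[ConductanceCurve]:
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_cells):
        g = base + rng.normal(0.0, noise_sd, size=base.size) if noise_sd > 0 else base.copy()
        curves.append(ConductanceCurve(voltages=voltages, g=np.clip(g, 0.0, None)))
    return curves


def simulate_peak_conductance(
    act: BoltzmannParams,
    voltages,
    noise_sd: float,
    n_cells: int,
    seed: int,
) -> list[ConductanceCurve]:
    """Per-cell normalized activation curves: Boltzmann + Gaussian noise, clipped at 0."""
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise InputError("voltages must be non-empty")
    if act.sense != "activation":
        raise ParameterError("simulate_peak_conductance expects sense='activation'")
    base = np.asarray(boltzmann(v, act))
    return _noisy_curves(base, v, noise_sd, n_cells, seed)


def simulate_inactivation_curve(
    inact: BoltzmannParams,
    prepulses,
    noise_sd: float,
    n_cells: int,
    seed: int,
) -> list[ConductanceCurve]:
    """Per-cell steady-state availability curves (decreasing Boltzmann sense)."""
    v = np.asarray(prepulses, dtype=float)
    if v.size == 0:
        raise InputError("prepulses must be non-empty")
    if inact.sense != "inactivation":
        raise ParameterError("simulate_inactivation_curve expects sense='inactivation'")
    base = np.asarray(boltzmann(v, inact))
    return _noisy_curves(base, v, noise_sd, n_cells, seed)


def _relax(x0: float, x_inf: float, t: np.ndarray, tau: float) -> np.ndarray:
    return x_inf + (x0 - x_inf) * np.exp(-t / tau)


def simulate_sweeps(
    model: ChannelModel,
    protocol: StepProtocol,
    noise_sd: float,
    seed: int,
) -> SweepSet:
    """Voltage-clamp sweeps: I(t) = scale · m(t) · h(t) · ghk_drive(V) + noise.

    Activation protocol: both gates relax first-order from their holding
    steady state toward the step steady state. Inactivation protocol: the
    recorded sweep is the test pulse; h starts from its value at the end of
    the prepulse (relaxed from holding toward the prepulse steady state) and
    m starts from its prepulse steady state.
    """
    model.validate()
    protocol.validate()
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = protocol.time_grid()

    m_hold = float(boltzmann(protocol.holding, model.act))
    h_hold = float(boltzmann(protocol.holding, model.inact))

    rows = []
    for v_step in protocol.steps:
        if protocol.kind == "activation":
            v_test = float(v_step)
            m0, h0 = m_hold, h_hold
        else:
            v_test = float(protocol.test_voltage)
            h_pre = float(boltzmann(v_step, model.inact))
            h0 = h_pre + (h_hold - h_pre) * float(
                np.exp(-protocol.prepulse_duration / model.tau_h)
            )
            m0 = float(boltzmann(v_step, model.act))
        m = _relax(m0, float(boltzmann(v_test, model.act)), t, model.tau_m)
        h = _relax(h0, float(boltzmann(v_test, model.inact)), t, model.tau_h)
        current = model.scale * m * h * float(ghk_drive(v_test, model.ghk))
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=t.size)
        rows.append(current)
    return SweepSet(protocol=protocol, time=t, currents=np.array(rows))


def simulate_fluorescence(
    transient_times,
    amplitude: float,
    decay_tau: float,
    bleach_slope: float,
    f0: float,
    bg: float,
    noise_sd: float,
    duration: float = 900.0,
    rate: float = 0.5,
    seed: int = 0,
) -> FluorescenceTrace:
    """Synthetic GCaMP recording: defaults emulate 0.5 Hz for 15 min.

    The ROI sees the cell signal plus the same background light that the
    background ROI measures, so background subtraction recovers the signal:

    roi(t) = bg + f0 + bleach_slope·t
             + Σ amplitude·exp(-(t-t_i)/decay_tau)·1[t>=t_i] + noise
    background(t) = bg + noise (independent draws).
    """
    if rate <= 0:
        raise InputError("rate must be > 0")
    if decay_tau <= 0:
        raise ParameterError("decay_tau must be > 0")
    events = np.asarray(transient_times, dtype=float)
    if events.size and (events.min() < 0 or events.max() > duration):
        raise InputError("transient times must lie within [0, duration]")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * rate))) / rate
    roi = bg + f0 + bleach_slope * t
    for ti in events:
        mask = t >= ti
        roi = roi + np.where(mask, amplitude * np.exp(-(t - ti) / decay_tau), 0.0)
    background = np.full_like(t, bg)
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd, size=t.size)
        background = background + rng.normal(0.0, noise_sd, size=t.size)
    return FluorescenceTrace(sample_rate=rate, roi=roi, background=background)


def sample_stages(probs, n: int, seed: int) -> StageDistribution:
    """Multinomial draw of n embryos over the seven stage categories."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (len(STAGE_CATEGORIES),):
        raise ParameterError(f"expected {len(STAGE_CATEGORIES)} probabilities")
    if np.any(p < 0):
        raise ParameterError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ParameterError(f"probabilities must sum to 1, got {p.sum():.6g}")
    if n < 0:
        raise InputError("n must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p / p.sum()) if n > 0 else np.zeros(p.size, dtype=int)
    return StageDistribution(counts)
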