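# hsnphys

Quantitative analyses of the *C. elegans* egg-laying circuit and of the
T-type calcium channels that gate its response to inhibitory neuropeptides,
packaged as a tested Python library with seeded synthetic-data generators,
so every analysis can be exercised end to end without bench recordings.

The package targets researchers working on small-circuit neurophysiology
and quantitative behavior: it covers behavioral point-process modeling,
voltage-clamp steady-state analysis, and calcium-imaging statistics.

## What it computes

**Two-state egg-laying interval model** (`hsnphys.egglaying`). Egg laying
alternates between active phases (clusters of events) and long quiescent
phases. The inter-event interval CDF is a two-component exponential mixture

```
F(x) = 1 − [A e^(−a·x) + B e^(−p·b·x)],
A = p(a−b)/(a−p·b),  B = a(1−p)/(a−p·b),  A + B = 1
```

with fast rate `a` (1/min) and slow rate `p·b`. The model is fitted by
nonlinear least squares to the empirical cumulative probability, and the
time constants `1/a` (intra-cluster) and `1/(p·b)` (quiescence, typically
tens of minutes) are derived from the fit.

**T-type channel steady-state gating** (`hsnphys.channel`). From
voltage-clamp step sweeps: peak currents (capacitive blanking), chord
conductance `g(V) = I_peak / GHK(V)` using the Goldman–Hodgkin–Katz flux
equation as the driving term, Boltzmann fits

```
m∞(V) = 1 / (1 + exp((V50 − V)/k))      (activation)
h∞(V) = 1 / (1 + exp((V − V50)/k))      (inactivation)
```

with 95% CIs, the window current `w(V) = m∞(V)·h∞(V)` with peak-voltage and
width metrics, and the oocyte leak-current QC rule (|I| < 0.1 µA at −90 mV).

**GCaMP ΔF/F pipeline** (`hsnphys.traces`). Background subtraction, linear
regression of the whole video as the photobleach baseline,
ΔF/F = (F − F0)/F0, and the cumulative ΔF/F statistic
`Σ |ΔF/F(t+1) − ΔF/F(t)|` — the discrete total variation of the trace,
used as a transient-shape-agnostic measure of integrated activity.

**Rank-sum statistics** (`hsnphys.stats`). Ordinal embryo-stage scoring
over seven developmental categories and a Wilcoxon Mann–Whitney test with
exact enumeration (midranks for ties) for small groups and a tie-corrected
normal approximation otherwise.

**Synthetic data** (`hsnphys.synthetic`). Seeded generators for every
input: mixture-exponential intervals and timelines, noisy Boltzmann
conductance curves, kinetic GHK sweeps, fluorescence traces with transients
plus photobleach drift, and multinomial stage counts.

## Worked example

```python
import numpy as np
from hsnphys import (IntervalModelParams, fit_intervals, time_constants,
                     BoltzmannParams, fit_boltzmann, window_metrics)
from hsnphys.synthetic import sample_intervals, simulate_peak_conductance

# --- interval model: simulate 1000 intervals and fit them back
truth = IntervalModelParams(p=0.5, a=1.0, b=0.1)   # mean interval 11.0 min
fit = fit_intervals(sample_intervals(truth, n=1000, seed=7))
print(fit.params)           # IntervalModelParams(p=0.514, a=1.021, b=0.093)
print(time_constants(fit.params))  # (0.98 min fast, 20.8 min quiescence)

# --- gating: 10 noisy wild-type activation curves, mean recovered V50
act = BoltzmannParams(v_half=-37.14, k=5.0, sense="activation")
curves = simulate_peak_conductance(act, np.arange(-80, 11, 10), 0.02, 10, seed=42)
v50 = np.mean([fit_boltzmann(c, "activation").params.v_half for c in curves])
print(round(v50, 2))        # -37.02

# --- window current: wild type vs mutant midpoints, shared k = 5 mV
wt = window_metrics(act, BoltzmannParams(-58.18, 5.0, "inactivation"))
mut = window_metrics(BoltzmannParams(-44.69, 5.0, "activation"),
                     BoltzmannParams(-63.11, 5.0, "inactivation"))
print(round(wt.v_peak, 2), round(mut.v_peak, 2))   # -47.66 -53.9
```

The interval fit recovers the generating parameters within sampling error;
the mean fitted half-activation voltage reproduces the generating value to
a fraction of a millivolt; and the mutant window current peaks ~6 mV more
hyperpolarized than wild type while its width is nearly unchanged — the
channel-level signature that lets mutant neurons escape hyperpolarizing
peptidergic inhibition.

A command-line interface exposes the same pipelines
(`hsnphys simulate-intervals | fit-intervals | simulate-sweeps |
fit-activation | fit-inactivation | window | dff | compare-stages`); every
output CSV is accompanied by a provenance JSON recording the arguments and
seed.

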