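# Methods

This note documents the models implemented in `hsnphys`, the defaults and
numerical choices, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Egg-laying interval model

The behavior is modeled as a two-state point process: an active state in
which events occur at rate `a` and an inactive state entered/exited so
that the marginal interval distribution is the two-component exponential
mixture

F(x) = 1 − [A·e^(−a·x) + B·e^(−p·b·x)], A = p(a−b)/(a−p·b), B = 1 − A.

Parameters: `p` (dimensionless, in (0,1)), `a` and `b` (1/min, positive),
with `a ≠ p·b`. The derived time constants are `1/a` (fast, intra-cluster)
and `1/(p·b)` (slow, quiescence). Typical fitted quiescence timescales are
20–30 min, which is the order-of-magnitude check the tests apply.

**Fitting.** The CDF is fitted by unweighted nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) to the empirical
cumulative probability at the sorted intervals. The plotting-position
convention is Hazen, (i − 0.5)/n; the convention used in the original
MATLAB analysis is not recorded, and Hazen is a standard unbiased-ish
middle ground. Box constraints: p ∈ (1e−4, 1−1e−4), a, b ∈ (1e−6, 1e3)
min⁻¹. Default initialization splits the sample at its median and fits a
one-exponential rate to each half. 95% CIs are asymptotic
(t-critical × sqrt of the diagonal of RSS/(n−3)·(JᵀJ)⁻¹); a singular
Jacobian (degenerate one-component data) yields infinite CIs via the
pseudo-inverse rather than an error. Non-convergence is reported in the
`converged` flag, never raised.

**Identifiability.** The mixture is invariant under swapping the two rates
with the complementary weight. Fits are canonicalized to `a > p·b` (the
rate-`a` component is the fast one); if the optimizer lands in the swapped
labeling, the parameters are remapped to the equivalent canonical point and
the fit is re-polished there so the reported CIs refer to the reported
parameterization.

**Validity region.** The invariants above admit parameter sets where A is
outside [0,1] (a signed-weight phase-type density — still a valid CDF for
part of that region, e.g. b slightly above a). The closed forms evaluate
there; the *sampler* requires 0 ≤ A ≤ 1 (a proper probabilistic mixture,
in practice a > b) and raises a parameter error otherwise.

**Censoring.** Intervals are computed between observed events only; the
open interval after the last event (censored by the end of observation) is
dropped, and animals that leave the arena simply contribute fewer
intervals.

## T-type channel steady-state analysis

**GHK drive.** Chord conductance divides the peak current by the
Goldman–Hodgkin–Katz flux expression rather than a linear (V − Vrev) term:

I(V) ∝ P·z²F²V/(RT) · (c_in − c_out·e^(−u)) / (1 − e^(−u)), u = zFV/RT.

Defaults describe the recording bath: z = 2 (Ba²⁺ charge carrier),
c_out = 10 mM, T = 295 K. Intracellular Ba²⁺ is not measurable in the
oocyte; the default c_in = 0.1 mM is nominal, and because conductance
curves are normalized per cell before any averaging, only the shape of the
drive versus voltage matters, not its scale. For |u| < 1e−4 the 0/0 is
resolved with the three-term Taylor splice u/(1−e^(−u)) ≈ 1 + u/2 + u²/12,
which is smooth across V = 0 and exact to O(u⁴) (the splice is tested
against the closed form on both sides of the switch).

**Peaks and curves.** Peak current per sweep is the signed extremum of
largest magnitude after discarding the first 2 ms of the step (capacitive
blanking; configurable), inward negative. Activation analysis divides the
peaks by the drive at each step voltage and normalizes to the maximum.
Inactivation analysis uses `availability_curve`: every test pulse is at
the same voltage, so the drive is a common factor and availability is peak
magnitude normalized to its maximum against prepulse voltage.

**Boltzmann fits.** Unweighted least squares (the default of the usual
sigmoidal-fit tools), bounds V50 ∈ (−200, 100) mV, k ∈ (0.1, 100) mV,
asymptotic 95% CIs. A parameter pinned at a bound flags the fit as
non-converged — the signature of fitting the wrong sense or saturated
data. Slope factors for simulation default to k_act = 5 mV and
k_inact = 4 mV, typical Cav3.1 magnitudes; the analysis itself never
assumes them.

**Window current.** w(V) = m∞(V)·h∞(V). Because each log-Boltzmann term is
concave in V, w is log-concave and unimodal: the peak is found by bounded
scalar minimization (golden-section-style refinement, xatol 1e−7) of a
2001-point coarse grid spanning both midpoints ± 25k, and the edges of the
window range by `brentq` bisection outward from the peak with doubling
bracket expansion. The "width" of the window has no standard definition;
this package uses the outermost voltages where w ≥ threshold_frac · w_peak
with threshold_frac defaulting to 0.1, and exposes the threshold rather
than fixing it.

**Oocyte QC.** `qc_leak` passes a cell iff |holding current| is strictly
below the threshold magnitude (default 0.1 µA at −90 mV); exactly at the
threshold fails. The boundary rule is a design decision (the acceptance
criterion is stated as "less than").

**Sweep simulation.** Currents are scale·m(t)·h(t)·drive(V) with m and h
relaxing first-order (τ_m = 5 ms, τ_h = 30 ms by default —
order-of-magnitude T-type kinetics, configurable). Activation protocol:
both gates start from their holding-potential steady state (holding
−90 mV, 150-ms steps −80…+10 mV in 10-mV increments). Inactivation
protocol: the recorded sweep is the test pulse (−30 mV); h starts from its
value at the end of a 1-s prepulse (relaxed from holding toward the
prepulse steady state), m from its prepulse steady state. The protocols are
standard low-voltage-activated designs consistent with a −90 mV holding
reference; the exact bench protocols were never published beyond figure
insets.

## Calcium-trace pipeline

Per frame: F_corr = ROI − background. The photobleach baseline F0(t) is
the ordinary least-squares line over the *entire* video — deliberately not
a percentile or windowed baseline, matching the original analysis; dense
transients therefore bias the slope slightly upward, which the tests
quantify against a closed-form OLS oracle. ΔF/F = (F_corr − F0)/F0.
Division by the time-varying baseline is chosen because the reported
quantity is dimensionless; a `baseline_mode="subtract"` variant returns
F_corr − F0 in AU for traces whose baseline crosses zero (division raises
a pipeline error naming the first offending sample).

Cumulative ΔF/F is the discrete total variation Σ|x(t+1) − x(t)| of the
ΔF/F series. The wording of the original description is ambiguous about
whether differences are summed over raw ROI fluorescence or ΔF/F; the
figure axes are labeled in ΔF/F units, so ΔF/F is the default and
`statistic="raw"` exposes the literal raw-sum variant.

**Affine invariance.** Adding an affine trend to the ROI shifts the OLS
baseline by exactly that trend, so detrended *residuals* are invariant:
a noise-free affine trace yields a cumulative statistic ≤ 1e−9, and the
subtract-mode statistic is exactly invariant to affine trends even with
transients present. The divide-mode statistic is not exactly invariant
when transients are present (the same residuals are divided by a shifted
baseline); this is inherent to ΔF/F, not an implementation artifact.

Defaults: 0.5 Hz sampling, 900 s (450 samples). No smoothing and no
transient detection anywhere in the pipeline.

## Rank-sum test

Embryo stages are coded 1..7 in developmental order (1–8 cell, 9–25 cell,
>26 cell pre-morphogenesis, comma, two-fold, three-fold, hatched/L1) and
compared per embryo. The two-sided Wilcoxon Mann–Whitney p-value is exact
whenever both groups have ≤ 10 observations: the permutation distribution
of the rank sum (midranks for ties) is built by dynamic programming over
doubled ranks, which is arithmetically identical to enumerating all
C(n, n1) labelings but polynomial in n. Above that, the tie-corrected
normal approximation with continuity correction 0.5 is used; the
cross-over size is where the two methods agree to well under 0.01. No
multiple-comparison correction is applied by default (matching the
original analysis across genotype panels); callers can correct externally.

## Synthetic-data generators

The generators emulate the *statistical structure the models assume*, with
Gaussian noise throughout (the simplest model compatible with
least-squares fitting):

- intervals are i.i.d. mixture draws — serial correlation between
  consecutive intervals, which a mechanistic hidden-state walk would
  induce, is deliberately not modeled because only the marginal interval
  distribution is ever fitted;
- conductance noise is additive on the normalized curve and clipped at 0;
  real cell-to-cell variability also scatters V50 and k, which the
  generators do not emulate;
- fluorescence traces are baseline + linear bleach + instantaneous-rise
  exponential-decay transients; real GCaMP transients have finite rise
  times and motion artifacts that are not modeled. The ROI channel
  includes the background light plus the cell signal, so background
  subtraction recovers the signal exactly at zero noise;
- stage counts are multinomial per plate.

Passing tests therefore demonstrate correctness of the estimators under
the assumed generative models — parameter recovery, oracle equivalence,
invariances — not robustness to the artifacts of real recordings.

## Problem sizes

Cohort sizes mirror the study: 10/5 cells for wild-type/mutant activation,
7/6 for inactivation; 1000 intervals for the interval-model recovery;
450-sample fluorescence traces; 20 animals per cohort in the
matched-total-variation comparison. Property tests run a few dozen
randomized cases each with derandomized (seeded) search.

## Known limitations

- No hidden-Markov or maximum-likelihood alternative to the CDF
  least-squares interval fit (the enumeration-free NLS approach is the
  deliverable; an ML fit would be a natural extension).
- No mechanistic membrane-potential model of the neuron and no coupling
  between the behavioral, electrophysiological, and imaging layers; the
  three analyses are independent, as in the source analyses.
- The window "range" metric depends on the exposed threshold fraction;
  there is no community-standard definition.
- Figure-only quantities (per-genotype time constants, slope-factor
  tables, imaging group means) have no published numeric values and are
  covered by property-based recovery rather than value reproduction.
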