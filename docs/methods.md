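# Methods

## The problem

Oxygen-uptake (V̇O2) kinetics — how fast pulmonary V̇O2 follows a change
in work rate — is a standard index of aerobic fitness. The classical
estimate fits a delayed mono-exponential to the on-transient of a step in
work rate and reports the time constant τ, but a single transient is so
contaminated by breath-to-breath noise that many repetitions must be
averaged before τ is usable. This package implements an alternative
frequency-domain index, the **mean normalized gain (MNG)**, computed from
the V̇O2 response to a pseudorandom binary sequence (PRBS) of work rates,
together with the classical time-domain analysis and the statistics used
to compare the two.

## PRBS protocol

A 4-stage binary shift register with modulo-2 adder feedback
((stage1 + stage4) mod 2 inserted at stage 1 after a right shift)
produces a maximal-length sequence of period 2⁴ − 1 = 15. Each bit is
held for 30 s at one of two work-rate levels (defaults 25 W and 100 W,
1 → high), so one period spans 450 s. An m-sequence excites all
low-order harmonics of the fundamental f1 = 1/450 Hz ≈ 0.0022 Hz with
non-zero amplitude, which is what makes the per-harmonic gains below
well defined.

The register seed and the bit→watt mapping only rotate or complement the
sequence in time. Amplitude spectra are invariant under cyclic shifts,
so neither choice affects any gain-derived quantity; both are exposed as
parameters. The default seed is (1,1,1,1). A second constant,
`STEP_ALIGNED_SEED = (0,1,0,0)`, selects the rotation in which the
sequence's 90-s low run is immediately followed by its 120-s high run
with the transition at the 180th second — the embedded step used for
time-domain fitting. `validate_window` checks this property and reports
the available low→high runs when it fails, rather than silently fitting
a window that straddles input switches.

## First-order simulator

The synthetic V̇O2 response is the first-order linear model

    τ dy/dt = a0 + G (u(t − td) − u_low) − y,   G = a1 / (high − low),

so the steady state is a0 at the low level and a0 + a1 at the high
level. Defaults follow the in-silico study design: td = 0 (the muscular
response is modelled without circulatory transit delay), amplitudes and
time constants per the ten published parameter sets
(a0 ∈ [125, 400] ml·min⁻¹, a1 ∈ [600, 900] ml·min⁻¹, τ ∈ [15, 52] s),
and an extreme-τ grid {0.001 … 1500 s} for mapping the MNG–τ relation.

Integration uses the exact zero-order-hold solution — a piecewise
exponential between input switches — rather than Euler stepping, so
there is no step-size error; the discrete response differs from the
continuous system only through sampling (at 1 s the difference in
harmonic-gain ratios is ~10⁻⁴ relative). A delay that is not a multiple
of the sampling interval splits each interval into two exactly
propagated segments. The simulation runs `n_warmup_periods` (default 2)
discarded periods before the returned one; if the returned period still
differs from its predecessor by more than 10⁻⁶ relative (slow systems,
τ ≳ 200 s), warm-up doubles automatically until it converges.

## Breath-by-breath measurement model

Real carts report V̇O2 per breath at irregular times. The generator
draws breath intervals from a lognormal distribution (default mean 3 s,
CV 0.2) and adds i.i.d. Gaussian noise (default SD 120 ml·min⁻¹,
independent of signal level) to the interpolated signal value at each
breath — the standard white-noise description of breath-to-breath
fluctuation. All parameters and the seed are explicit. The model does
not emulate outlier breaths, level-dependent noise, slow drifts, or the
cardio-dynamic (phase I) component, so tests passing on this generator
demonstrate correctness of the computations, not robustness to every
artefact of real gas-exchange data.

## Preprocessing

Breaths are linearly interpolated onto the 1-s grid (no extrapolation;
each breath value is anchored at its end-timestamp). Optional filters:
a centered moving average of 3, 5 or 7 s (window truncated at the
edges, preserving length) and a zero-phase 4th-order Butterworth
low-pass at 0.075 Hz applied forward–backward — zero phase because both
analysis branches depend on timing. Repeated PRBS responses are combined
by pointwise ensemble averaging; replicates must already share the grid
(t0, dt, length), and the package deliberately does not guess an
alignment algorithm for misaligned repetitions.

## Frequency-domain analysis and MNG

One period is decomposed without taper or padding (it is periodic by
construction) into

    A_h = (1/N) Σ x(t) cos(2π h f1 t),  B_h = (1/N) Σ x(t) sin(2π h f1 t),
    Amp_h = √(A_h² + B_h²),

with the factor 2 carried by the reconstruction formula. The
per-harmonic system gain is gAmp_h = V̇O2Amp_h / ẆAmp_h, and

    MNG = 100 · mean_{h=2..4} (gAmp_h / gAmp_1)   [%].

Analysis stops at h = 4 (0.0089 Hz) because the V̇O2 response is treated
as linear only below ≈0.01 Hz; the harmonic range is configurable
(2–3, 2–4, 2–5, 2–10) for the extreme-τ study. Normalizing by gAmp_1
cancels the static gain and baseline, so MNG isolates the temporal
dynamics: for a first-order system

    MNG(τ) = 100 · mean_h √((1 + (2π f1 τ)²) / (1 + (2π h f1 τ)²)),

which is strictly decreasing in τ with limits 100 % (τ → 0) and
100·mean(1/h) ≈ 36.1 % for h = 2..4 (τ → ∞). This closed form is kept in
the package as `analytic_mng` and serves as the independent oracle for
the simulate→decompose→gain pipeline. The "average gAmp" summary of the
ten-set study is the mean of |gAmp_h| over h = 2..4; this reading
reproduces all ten published values at printed precision.

## Time-domain analysis

The mono-exponential V̇O2(t) = a0 + a(1 − e^−(t−TD)/τ) (V̇O2 = a0 for
t < TD) is fitted to the final 10 s of the 90-s low stretch plus the
120 s of the following high stretch, with the first 20 s after onset
excluded as the cardio-dynamic phase. Baseline samples participate with
model value a0 (the model is otherwise undefined before TD). The fit is
trust-region nonlinear least squares with starts a0 = mean(baseline),
a = mean(last 30 s) − a0, τ = 30 s, TD = 15 s and bounds
τ ∈ [0.1, 200] s, TD ∈ [0, 60] s, which bracket the physiological range
(10 < τ < 100 s); τ landing on a bound is flagged. Per-parameter CI95
and p-values come from the asymptotic covariance (Jacobian-based) with a
t reference distribution; MRT = τ + TD by construction.

## Statistics

- Pearson r with two-sided p (scipy).
- Bland–Altman: bias = mean(x − y), limits ±1.96·SD of differences.
  "Percent of total variation" divides by the range of the pooled
  values by default; the denominator is configurable to the pooled mean
  because the verbal definition is ambiguous.
- Group CI95 = 1.96·SD as % of the group mean, used to compare the
  between-replicate variability of τ and MNG on equal footing.
- Sample-size curves use the noncentral-t power formulation
  (statsmodels) for two-sample or paired t-tests at power 0.8, α 0.05,
  rounded up with a floor of n = 2.
- The MNG–log10(τ) relation is described by a 4-parameter logistic
  fitted by least squares; a straight-line fit restricted to
  τ ∈ [10, 100] s is reported alongside, since the logistic mid-section
  is nearly linear there.

## Problem sizes used by the tests and studies

The canned studies run one 450-sample period per parameter set (ten
sets; ten extreme τ values × four harmonic ranges). Noisy
parameter-recovery checks use 200 replicate seeds for single-repetition
fits, 25 ensembles of 8 for the averaging comparison, and 30 matched
replicates for the τ-vs-MNG variability ordering; these sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances.

## Known limitations

- With sparse breaths (3-s mean interval) and noise SD 120 ml·min⁻¹,
  the single-repetition τ estimator from the 130-s embedded window is
  strongly right-skewed: its median tracks the true τ but its mean is
  biased high by several seconds, because interpolation correlates the
  noise and the window carries only ~37 independent breaths. Recovery
  assertions therefore use per-breath noise at the 1-s analysis
  resolution; the skew itself mirrors the well-known instability of
  single-transient τ estimates and is visible in the variability
  ordering study (τ CI95 ≫ MNG CI95).
- The simulator is strictly first-order and linear: no slow component,
  no cardio-dynamic phase, no asymmetry between on- and off-transients.
  MNG values from real above-moderate-intensity exercise would violate
  the symmetry assumption of the Fourier description.
- Phase (and coherence) analysis is deliberately out of scope; only
  amplitude information enters MNG.
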