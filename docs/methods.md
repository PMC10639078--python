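# Methods

This note documents the models, estimators and numerical choices behind
`dockfret`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Two-state docking model

The pseudoknot is modeled as a continuous-time two-state Markov process:
undocked (mid-FRET, mean μ_undock) ⇌ docked (high-FRET, μ_dock) with
first-order rate constants k_dock (undocked→docked) and k_undock.
Sojourn times in each state are exponential; the stationary docked
occupancy is k_dock/(k_dock+k_undock), and the equilibrium constant
K_eq = k_dock/k_undock corresponds to ΔG°_dock = −RT ln K_eq with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 293.15 K (20 °C) throughout.

Osmolyte dependence follows the linear free-energy (m-value) model:
ΔG°_dock(c) = ΔG°_dock(0) + m·c. The kinetic split of that perturbation
is parameterized by the transition-state value Φ:
k_dock(c) = k_dock(0)·exp(−Φ m c/RT), with k_undock following from
detailed balance. Φ = 1 therefore leaves k_undock unchanged; Φ = 0
leaves k_dock unchanged.

## Synthetic data generator

`simulate.py` renders the Markov path to camera frames of 60 ms
(configurable) by occupancy-weighted averaging of the state FRET means
within each frame — the blurring a real integrating camera produces at a
transition. Channel intensities are
I_A = E·I_total + ε, I_D = (1−E)·I_total + ε with i.i.d. Gaussian ε per
channel (gamma factor fixed at 1). Photobleaching is a single
exponential time for total-signal loss (mean 30 s by default); after the
bleach frame both channels carry zero-mean noise only, producing the
single-step signature QC requires. A configurable fraction of molecules
is static (never transitions; docked by default, matching the
static high-FRET population seen under stabilizing conditions).

Defaults are the mesophilic riboswitch's no-osmolyte study conditions:
k_dock = 1.35 s⁻¹, k_undock = 0.5 s⁻¹, μ = 0.57/0.98. The intensity
scale and noise are not reported for the real instrument; the defaults
I_total = 500 a.u. and σ_channel = 70 a.u. put the total-intensity SNR
at ≈5 and clear the QC thresholds with realistic margins.

Not emulated: donor-only/acceptor-only photophysics (blinking, partial
bleaching), spectral crosstalk, gamma ≠ 1, intensity heterogeneity
between molecules, drift, and non-Markovian kinetics. Passing recovery
tests on this generator demonstrates estimator correctness under the
stated model, not robustness to those artifacts — QC is designed to
discard most of them in real data.

Reproducibility: each molecule is driven by a child stream spawned from
one root seed; identical seeds give bit-identical datasets.

## Trace QC

E = I_A/(I_D+I_A) per frame; frames with non-positive total intensity
are invalid. The photobleach change-point is the minimum-SSE two-segment
piecewise-constant split of the total intensity, restricted to splits
whose post-step mean is below 25% of the pre-step mean (so an
intermediate plateau of a multi-step staircase cannot mask the drop to
background); the trace is single-step unless either flank contains a
second step of at least half the main drop. SNR is defined as the mean
pre-bleach total intensity over the SD of the residual after a 5-frame
median filter — the selection threshold (4:1) is standard, the formula
itself is a package choice and is configurable. Acceptance requires all
four criteria (single-step bleach, ≥100 pre-bleach frames, SNR > 4,
mean total > 300 a.u.); every decision is a pure function of the trace
and is recorded per molecule.

## Idealization

Each accepted trace is fit independently with a two-state Gaussian HMM
by segmental k-means: deterministic 2-means initialization (centers at
the data extremes, so a minority state occupying only a few percent of
frames survives initialization), then alternating Viterbi segmentation
and hard re-estimation of means, SDs (floored at 0.01 FRET) and
transition probabilities (one pseudocount per cell) until the path is
fixed or `max_iter` is reached.

A one-state alternative is always scored against the converged two-state
model by BIC on the complete-data log-likelihood *including transition
terms*: splitting pure noise forces near-every-frame toggling whose
transition cost (~ln 2 per frame) exceeds the emission gain, so static
molecules robustly prefer one state. Additionally, a fitted state mean
outside the physical FRET window [−0.2, 1.2] marks the split as a
noise-tail artifact (the ratio E is heavy-tailed when the denominator
fluctuates low) and the trace is classified static.

Dynamic traces then undergo a short-dwell refinement: the Viterbi path
is the MAP path and is conservative about single-frame excursions, and
hard-assignment SDs are inflated by camera-blurred transition frames.
The refinement replaces the emission model with per-state medians and
SDs propagated from the measured channel noise,
σ_E(μ) = sqrt((1−μ)² + μ²)/(√2·SNR), and re-decodes by posterior
(forward–backward) marginals, re-estimating only the transition matrix
between rounds (two by default; freezing emissions prevents the
re-decode from feeding back on its own output). A guard skips refinement
when either state holds <10 frames or the separation is under 3 noise
SDs. At the study conditions this raises frame accuracy to ~98% and
roughly halves the short-dwell deficit. `refine=False` restores plain
segmental k-means.

Dwells are maximal constant-state runs; the first and last dwell of each
trace are flagged censored (truncated by observation start and by
bleaching). Durations are integer frame counts times the frame interval;
sub-frame events cannot be represented, and no missed-event correction
is applied — rates approaching 1/60 ms are underestimated and the
kinetics stage flags them.

TDP: every transition contributes a point at (departing dwell mean FRET,
arriving dwell mean FRET), smoothed with a 0.02-FRET Gaussian kernel on
a 100×100 grid over [0,1]². TODP: every molecule contributes total
weight 1, split over the distinct transition types it exhibits at least
once (placed at its fitted state means); static molecules sit on the
diagonal at their mean FRET, so the diagonal weight fraction estimates
the static fraction of the population.

## Dwell-time kinetics

Rates come from least-squares fits of the cumulative dwell count with
A(1−e^{−k(τ−τ₀)}) and its two-component sum. Choices that matter:

* **Censored dwells are excluded.** Unbiased for exponential data when
  dwells are short relative to the observation window; when the mean
  dwell approaches the bleach-limited window (tens of seconds), the
  exclusion length-biases the retained sample and both rates are
  *overestimated* (at a 3 s mean dwell in a ~20 s window, by ~30–50%).
  Maximum-likelihood fitting with censoring would remove this but is out
  of scope; derived quantities such as endpoint Φ from pipeline-estimated
  rates inherit the bias at fast-denaturation endpoints.
* **Dead time τ₀ of one frame.** Decoded dwell lists are unreliable at
  the resolution limit (a deficit of true single-frame events, an excess
  of artifact ones). Dwells ≤ 1 frame are excluded and the fit origin is
  shifted to τ₀; for exponential sojourns the conditional distribution
  is again exponential with the same rate, so the estimator stays
  unbiased without any missed-event correction. A double-fit component
  faster than 1/τ₀ is rejected as sub-resolution.
* **Model selection.** The double fit is retained only if all four
  parameters' 95% CIs (±1.96 SE from the linearized covariance) exclude
  negative values, n ≥ 40 dwells, the rates are distinct and resolvable,
  *and* a two-component exponential mixture beats the single exponential
  by BIC on the i.i.d. durations themselves. The last condition is
  needed because cumulative-count residuals are strongly correlated,
  which makes CI-based rejection alone too permissive (~30% false
  doubles at n = 200); with it, false selection is <5%. Double-fit
  conditions are summarized by the weighted average
  (A₁k₁+A₂k₂)/(A₁+A₂) (amplitudes normalized).
* **Bootstrap.** Whole traces (not dwells) are resampled with
  replacement, M from M, 1000 replicates by default; the SD of the
  replicate weighted-average rates is the reported error. Replicate fit
  failures are skipped and counted (warning above 10%). A dataset of
  identical traces yields SD exactly 0.

Under the flagship recovery condition (200 traces, k_dock = 1.35 s⁻¹,
k_undock = 0.5 s⁻¹, SNR ≈ 5) both rates are recovered within ~10%
across seeds; ±2 bootstrap SDs cover the truth in ≥80% of simulated
datasets.

## Population thermodynamics

Histograms pool the first 100 valid pre-bleach frames of every accepted
molecule (bin width 0.02 on [−0.2, 1.2]; out-of-range noise values are
retained, not clamped). The two-Gaussian fit is initialized at the two
most prominent histogram modes (falling back to distribution quantiles)
and refined by bounded least squares with analytic Jacobians; the best
of all initializations by SSE wins. K_eq is the analytic area ratio of
the components. Working from histogram areas (not kinetics) is what lets
static and dynamic molecules enter one consistent equilibrium measure.

Known bias: frames blurred across a transition transfer apparent weight
between components, inflating K_eq by ~15–25% at these kinetics. The
inflation is nearly uniform in osmolyte concentration, so ΔG offsets
largely cancel in the m-value slope; recovery tests confirm slopes
within ~0.02 kcal mol⁻¹ M⁻¹ of truth at 150 molecules/point. Resolving
the bias would require modeling the blur bridge explicitly (a third
component), which is out of scope.

The m-value is fit by unweighted OLS by default (slope SE = reported
error). A weighted option uses inverse bootstrap variances per point;
with only five points the OLS residual SE has three degrees of freedom
and is itself highly variable, so the weighted SE is the better
uncertainty statement and is what the acceptance study uses.

Φ is computed by the endpoint method by default (the ratio of Δln k_dock
to Δln K_eq between the lowest and highest concentrations), with a
slope-ratio variant that agrees exactly when ln k is linear in
concentration. No range clamp is applied; the method is recorded with
the result.

## Melting curves

A_260 is background-corrected by pointwise subtraction of the A_340/A_320
channel. Derivatives are estimated by local cubic regression in windows
of 15 points on the native (non-uniform) temperature grid — the standard
ramp is 1 °C steps from 10–22 °C, 0.5 °C to 75 °C, 1 °C to 95 °C — which
gives dA/dT and d²A/dT² directly from the fitted coefficients.
Transitions are local maxima of dA/dT with relative prominence ≥ 0.3
(invariant to affine rescaling of the absorbance axis), with Tm refined
to the adjacent zero-crossing of d²A/dT². The first and last 3 °C are
excluded: edge windows are one-sided and dominate derivative noise, and
a derivative still rising at the interior boundary means the true
maximum lies outside the usable range (suppressed with a note). Window
15/prominence 0.3 were chosen so that 1%-of-amplitude noise yields a
clean single-Tm detection in ≥90% of replicates while noiseless
two-transition curves (40/66 °C) are recovered to 0.01 °C. Up to three
transitions are reported, ascending.

## Pipeline

`run_titration` composes QC → idealization → kinetics + thermodynamics
per condition, then the m-value fit and Φ across conditions; every
reported number carries its molecule/trace/dwell counts, failed
conditions are recorded without aborting the run, and a rerun on the
same inputs and seeds is bit-identical. Stage outputs are plain TSV/JSON
so each stage can be rerun independently; the resolved configuration is
serialized beside every run.

## Known limitations

* No missed-event or censoring-bias corrections (flagged, not fixed).
* Apparent FRET without gamma/crosstalk correction.
* Two states only; heterogeneity beyond a static subpopulation (e.g.
  the multiple FRET levels seen at high denaturant) is not modeled.
* Histogram K_eq carries the camera-blur inflation described above.
* The synthetic generator's idealized noise model means real-data
  performance depends on QC removing photophysical artifacts first.
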