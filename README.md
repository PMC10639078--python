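# dockfret

Analysis toolkit for single-molecule FRET (smFRET) studies of riboswitch
pseudoknot **docking** — the reversible formation of the P2 helix that
closes the H-type pseudoknot of small preQ₁ riboswitch aptamers — and for
the UV-melting experiments that accompany them. It targets the standard
experimental design in which surface-immobilized, dye-labeled RNA
molecules are imaged at 60 ms time resolution while the solution is
titrated with osmolytes (the denaturant urea, the stabilizer TMAO), and
every stage is exercisable end-to-end on synthetic data with known ground
truth.

## What it computes

Per-molecule donor/acceptor intensity traces are converted to apparent
FRET, `E = I_A / (I_D + I_A)`, and filtered by four selection criteria
(single-step photobleach, ≥100 pre-bleach frames, SNR > 4:1, total
intensity > 300 a.u.). Accepted traces are idealized with a two-state
Gaussian hidden-Markov model (segmental k-means plus a posterior
refinement stage), giving state paths, dwell times, and transition
density / transition occupancy density plots (TDP/TODP). From there:

* **Kinetics** — cumulative dwell-time distributions fit with
  `y = A(1−e^{−kτ})` (or a double-exponential, selected by a
  confidence-interval rule plus a mixture BIC test), giving the docking
  and undocking rate constants `k_dock` and `k_undock`; errors by
  bootstrap over molecules (1000 replicates).
* **Thermodynamics** — FRET histograms from the first 100 frames of each
  molecule, fit with two Gaussians; the docking equilibrium constant is
  the component-area ratio `K_eq = AUC_high / AUC_mid` and
  `ΔG°_dock = −RT ln K_eq` at T = 20 °C.
* **m-values** — the slope of ΔG°_dock versus osmolyte concentration
  (linear free-energy model), with OLS or bootstrap-weighted fits.
* **Φ analysis** — `Φ = Δln k_dock / Δln K_eq` between titration
  endpoints (or as a slope ratio), locating the urea-sensitive contacts
  relative to the docking transition state: Φ = 1 means fully formed in
  the transition state, Φ = 0 means not yet formed.
* **Melting curves** — Tm extraction from absorbance-vs-temperature
  curves by the second-derivative method on the instrument's non-uniform
  ramp, supporting the stepwise P2/P1 melting of thermophilic aptamers.

The `dockfret.simulate` module generates the matching synthetic data:
continuous-time two-state Markov traces with camera-integration blurring,
Gaussian channel noise, exponential photobleaching, static
subpopulations, osmolyte-dependent rates under the m-value/Φ model, and
sigmoidal melting curves.

## Worked example

```python
import dockfret as df

# simulate one condition: 200 molecules at the mesophile's zero-urea rates
cfg = df.SimulationConfig(k_dock=1.35, k_undock=0.5, rng_seed=0)
dataset, truth = df.simulate_condition_dataset(cfg, 200)

accepted, qc = df.select_traces(dataset)
itraces = [df.idealize_two_state(ft) for ft in accepted]
k_dock, k_undock = df.estimate_rates_for_condition(itraces, bootstrap=False)
print(f"accepted {len(accepted)}/200;"
      f" k_dock = {k_dock.value:.2f} /s, k_undock = {k_undock.value:.2f} /s")

hist = df.build_fret_histogram(accepted)
fit = df.fit_two_gaussians(hist)
point = df.compute_delta_g(fit)
print(f"mu_undock = {fit.mu_undock:.2f}, mu_dock = {fit.mu_dock:.2f},"
      f" dG_dock = {point.delta_g:+.2f} kcal/mol")
```

prints (seed 0):

```
accepted 160/200; k_dock = 1.32 /s, k_undock = 0.46 /s
mu_undock = 0.55, mu_dock = 0.96, dG_dock = -0.74 kcal/mol
```

i.e. the generator's rates (1.35 and 0.5 s⁻¹) and state means (0.57,
0.98) are recovered within a few percent; the histogram free energy is
somewhat more negative than the kinetic value −RT ln(1.35/0.5) = −0.58
kcal/mol because camera-blurred transition frames shift population weight
toward the docked component — a resolution bias of the histogram method
that is nearly uniform across a titration and therefore largely cancels
in m-value slopes (see `docs/methods.md`).

A command-line interface wraps the same stages
(`dockfret simulate | qc | titrate | simulate-melt | melt`,
`dockfret print-config` for the full resolved configuration).

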