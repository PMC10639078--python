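"""Synthetic smFRET and UV-melting data with known ground truth.

The generator emulates what the downstream analysis stages consume:

* two-state (undocked/docked) continuous-time Markov trajectories per
  molecule, rendered to camera frames by occupancy-weighted averaging of
  the state FRET means over each 60 ms integration window;
* additive i.i.d. Gaussian noise per detection channel (gamma factor 1);
* single-exponential photobleaching of the total signal, after which both
  channels carry zero-mean noise only (the single-step bleach signature
  that quality control detects);
* a configurable subpopulation of static molecules that never transition;
* osmolyte titrations in which the docking free energy is linear in
  concentration (the m-value model) and the osmolyte's effect is split
  between k_dock and k_undock by a transition-state Phi value;
* van't-Hoff-style sigmoidal melting curves with one to three transitions
  on the instrument's non-uniform temperature ramp.

Every simulated molecule is accompanied by a ground-truth sidecar (true
state path, true dwells, bleach frame, static flag) that analysis stages
never read; it exists so that recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import RT_KCAL_PER_MOL
from .melting import MeltingCurve
from .traces import Condition, ConditionDataset, IntensityTrace

__all__ = [
    "SimulationConfig",
    "TitrationGroundTruth",
    "GroundTruthSidecar",
    "simulate_two_state_trace",
    "simulate_condition_dataset",
    "simulate_titration",
    "titration_rates",
    "simulate_melting_curve",
    "standard_melting_grid",
]

UNDOCKED, DOCKED = 0, 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the per-molecule trace simulator.

    Defaults correspond to the mesophilic riboswitch at 100 nM ligand and
    no Mg2+ / no osmolyte: k_dock = 1.35 s^-1, k_undock = 0.5 s^-1, state
    FRET means 0.57 (undocked) and 0.98 (docked), 60 ms frames. The
    intensity scale (500 a.u.) and channel noise (70 a.u., i.e. a total-
    intensity SNR of ~5) are generator choices, since only QC thresholds
    constrain them.
    """

    k_dock: float = 1.35
    k_undock: float = 0.5
    mu_undock: float = 0.57
    mu_dock: float = 0.98
    sigma_channel: float = 70.0
    i_total: float = 500.0
    frame_interval: float = 0.06
    n_frames_max: int = 1000
    bleach_mean_time: float = 30.0
    static_fraction: float = 0.0
    static_state: int = DOCKED
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_dock <= 0 or self.k_undock <= 0:
            raise ValueError("rate constants must be positive")
        if not (0.0 <= self.mu_undock < self.mu_dock <= 1.0):
            raise ValueError("state means must satisfy 0 <= mu_undock < mu_dock <= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames_max < 1:
            raise ValueError("n_frames_max must be >= 1")
        if self.bleach_mean_time <= 0:
            raise ValueError("bleach_mean_time must be positive")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ValueError("static_fraction must lie in [0, 1]")
        if self.static_state not in (UNDOCKED, DOCKED):
            raise ValueError("static_state must be 0 (undocked) or 1 (docked)")
        if self.sigma_channel < 0 or self.i_total <= 0:
            raise ValueError("sigma_channel >= 0 and i_total > 0 required")

    @property
    def docked_occupancy(self) -> float:
        """Stationary docked-state probability k_dock/(k_dock + k_undock)."""
        return self.k_dock / (self.k_dock + self.k_undock)


@dataclass(frozen=True)
class TitrationGroundTruth:
    """Linear free-energy ground truth for an osmolyte titration.

    ΔG°dock(c) = dg0 + m_eq * c; the kinetic split is
    k_dock(c) = k_dock0 * exp(-phi * m_eq * c / RT) and k_undock follows
    from detailed balance, k_undock(c) = k_dock(c) * exp(ΔG°dock(c)/RT).
    With ``dg0 = None`` (default) the zero-osmolyte free energy is derived
    from the base rate constants, dg0 = -RT ln(k_dock0/k_undock0), keeping
    the thermodynamics and kinetics self-consistent.
    """

    m_eq: float = 0.32
    phi: float = 0.63
    k_dock0: float = 1.35
    k_undock0: float = 0.5
    dg0: float | None = None
    concentrations: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if self.k_dock0 <= 0 or self.k_undock0 <= 0:
            raise ValueError("base rate constants must be positive")
        if not 0.0 <= self.phi <= 1.0:
            warnings.warn(f"Phi = {self.phi} outside [0, 1]; allowed but unusual", stacklevel=2)

    @property
    def dg0_effective(self) -> float:
        if self.dg0 is not None:
            return self.dg0
        return -RT_KCAL_PER_MOL * float(np.log(self.k_dock0 / self.k_undock0))


@dataclass
class GroundTruthSidecar:
    """Per-molecule ground truth; written beside datasets, never read by analysis."""

    molecule_id: str
    state_path: np.ndarray          # per-frame majority state, frames [0, bleach_frame)
    dwell_states: np.ndarray        # alternating states of the true dwell sequence
    dwell_durations: np.ndarray     # seconds; sums to the observed (pre-bleach) time
    bleach_frame: int               # first fully bleached frame (== n_frames if unbleached)
    bleach_time: float              # seconds (may exceed the trace length)
    static: bool
    seed: int = 0

    @property
    def n_transitions(self) -> int:
        return max(len(self.dwell_states) - 1, 0)


def titration_rates(gt: TitrationGroundTruth, concentration: float) -> tuple[float, float, float]:
    """True (k_dock, k_undock, dG) at one osmolyte concentration."""
    dg = gt.dg0_effective + gt.m_eq * concentration
    k_dock = gt.k_dock0 * float(np.exp(-gt.phi * gt.m_eq * concentration / RT_KCAL_PER_MOL))
    k_undock = k_dock * float(np.exp(dg / RT_KCAL_PER_MOL))
    return k_dock, k_undock, dg


def _sample_state_path(config: SimulationConfig, t_end: float, rng: np.random.Generator,
                       static: bool) -> tuple[np.ndarray, np.ndarray]:
    """Sample the continuous-time two-state path on [0, t_end].

    Returns (states, durations) of the alternating dwell sequence, with
    the final dwell truncated at t_end.
    """
    if static:
        return (np.array([config.static_state]), np.array([t_end]))
    p_docked = config.docked_occupancy
    state = DOCKED if rng.random() < p_docked else UNDOCKED
    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    while t < t_end:
        rate = config.k_undock if state == DOCKED else config.k_dock
        dwell = rng.exponential(1.0 / rate)
        dwell = min(dwell, t_end - t)
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = 1 - state
    return np.array(states), np.array(durations)


def _frame_occupancy(states: np.ndarray, durations: np.ndarray, n_frames: int,
                     dt: float) -> np.ndarray:
    """Docked-state occupancy fraction of each camera frame.

    Cumulative docked time is piecewise linear in t with slope 1 inside
    docked dwells, so frame occupancies follow from interpolation at the
    frame edges (this is the camera-integration blurring of transitions).
    """
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    docked_cum = np.concatenate([[0.0], np.cumsum(np.where(states == DOCKED, durations, 0.0))])
    frame_edges = np.arange(n_frames + 1) * dt
    d = np.interp(frame_edges, edges, docked_cum)
    return np.diff(d) / dt


def simulate_two_state_trace(
    config: SimulationConfig,
    rng: np.random.Generator,
    molecule_id: str = "mol",
    condition: Condition | None = None,
) -> tuple[IntensityTrace, GroundTruthSidecar]:
    """Simulate one molecule's donor/acceptor trace plus ground truth.

    The molecule is static with probability ``config.static_fraction``.
    Photobleaching truncates the informative part of the trace: from the
    bleach frame on, both channels contain zero-mean channel noise only.
    """
    dt = config.frame_interval
    n = config.n_frames_max
    static = bool(rng.random() < config.static_fraction)

    bleach_time = float(rng.exponential(config.bleach_mean_time))
    bleach_frame = min(int(np.floor(bleach_time / dt)), n)
    t_obs = bleach_frame * dt  # fully-lit time actually rendered

    if bleach_frame > 0:
        states, durations = _sample_state_path(config, t_obs, rng, static)
        occ = _frame_occupancy(states, durations, bleach_frame, dt)
    else:
        states, durations = np.array([], dtype=int), np.array([])
        occ = np.zeros(0)

    efficiency = config.mu_undock + occ * (config.mu_dock - config.mu_undock)
    i_acc = np.zeros(n)
    i_don = np.zeros(n)
    i_acc[:bleach_frame] = efficiency * config.i_total
    i_don[:bleach_frame] = (1.0 - efficiency) * config.i_total
    if config.sigma_channel > 0:
        i_acc += rng.normal(0.0, config.sigma_channel, n)
        i_don += rng.normal(0.0, config.sigma_channel, n)

    path = (occ >= 0.5).astype(np.int8)
    trace = IntensityTrace(i_don, i_acc, dt, molecule_id=molecule_id,
                           condition=condition or Condition())
    sidecar = GroundTruthSidecar(
        molecule_id=molecule_id,
        state_path=path,
        dwell_states=states.astype(np.int8),
        dwell_durations=durations,
        bleach_frame=bleach_frame,
        bleach_time=bleach_time,
        static=static,
    )
    return trace, sidecar


def simulate_condition_dataset(
    config: SimulationConfig,
    n_molecules: int,
    condition: Condition | None = None,
) -> tuple[ConditionDataset, list[GroundTruthSidecar]]:
    """Simulate one condition's worth of molecules.

    Reproducible: molecules are driven by child streams spawned from
    ``config.rng_seed``, so the same seed yields a bit-identical dataset
    and per-molecule seeds are recorded in the sidecars.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    condition = condition or Condition()
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(n_molecules)
    traces: list[IntensityTrace] = []
    sidecars: list[GroundTruthSidecar] = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        mol_id = f"mol{i:04d}"
        tr, sc = simulate_two_state_trace(config, rng, molecule_id=mol_id, condition=condition)
        sc.seed = int(child.entropy) if isinstance(child.entropy, int) else config.rng_seed
        traces.append(tr)
        sidecars.append(sc)
    return ConditionDataset(traces, condition=condition, frame_interval=config.frame_interval), sidecars


def simulate_titration(
    gt: TitrationGroundTruth,
    base: SimulationConfig,
    n_per_conc: int,
    osmolyte: str = "urea",
) -> list[tuple[ConditionDataset, list[GroundTruthSidecar]]]:
    """Simulate a full osmolyte titration under the linear free-energy model.

    Each concentration gets its own dataset with rate constants from
    :func:`titration_rates` and a distinct child seed derived from the base
    seed, so the whole titration is reproducible from one integer.
    """
    out = []
    for j, c in enumerate(gt.concentrations):
        k_dock, k_undock, _ = titration_rates(gt, c)
        cfg = replace(base, k_dock=k_dock, k_undock=k_undock,
                      rng_seed=(base.rng_seed * 1_000_003 + j) % (2**31 - 1))
        cond = Condition(urea_M=c if osmolyte == "urea" else 0.0,
                         tmao_M=c if osmolyte == "tmao" else 0.0,
                         label=f"{osmolyte}_{c:g}M")
        out.append(simulate_condition_dataset(cfg, n_per_conc, condition=cond))
    return out


def standard_melting_grid() -> np.ndarray:
    """The spectrophotometer ramp: 1 degC steps 10-22, 0.5 degC 22-75, 1 degC 75-95."""
    return np.unique(np.concatenate([
        np.arange(10.0, 22.0, 1.0),
        np.arange(22.0, 75.0, 0.5),
        np.arange(75.0, 95.0 + 1e-9, 1.0),
    ]))


def simulate_melting_curve(
    tm_list: list[float],
    widths: list[float],
    amplitudes: list[float],
    noise_sd: float = 0.0,
    temp_grid: np.ndarray | None = None,
    baseline: float = 0.5,
    baseline_slope: float = 0.0,
    background_level: float = 0.0,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> MeltingCurve:
    """Simulate an absorbance-vs-temperature denaturation curve.

    A(T) = baseline + baseline_slope*(T - T0) + sum_i amp_i * sigmoid((T - Tm_i)/width_i)
    plus Gaussian noise. Each logistic's inflection sits exactly at its Tm.
    Overlapping transitions (closer than the sum of their widths) are
    allowed but flagged with a warning because the extractor may merge them.
    """
    tm = np.asarray(tm_list, dtype=float)
    w = np.asarray(widths, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if not (len(tm) == len(w) == len(a)):
        raise ValueError("tm_list, widths, amplitudes must have equal length")
    if len(tm) > 1 and np.any(np.diff(tm) <= 0):
        raise ValueError("tm_list must be sorted ascending")
    if np.any(w <= 0):
        raise ValueError("widths must be positive")
    for i in range(len(tm) - 1):
        if tm[i + 1] - tm[i] < w[i] + w[i + 1]:
            warnings.warn(
                f"transitions at {tm[i]:g} and {tm[i+1]:g} degC overlap strongly", stacklevel=2)

    temps = standard_melting_grid() if temp_grid is None else np.asarray(temp_grid, dtype=float)
    absorb = baseline + baseline_slope * (temps - temps[0])
    for tmi, wi, ai in zip(tm, w, a):
        absorb = absorb + ai / (1.0 + np.exp(-(temps - tmi) / wi))
    background = np.full_like(temps, background_level)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        absorb = absorb + rng.normal(0.0, noise_sd, len(temps))
        background = background + rng.normal(0.0, noise_sd, len(temps))
    return MeltingCurve(temperature=temps, absorbance=absorb,
                        background=background if background_level or noise_sd else None,
                        label=label)
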