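"""Two-state hidden-Markov idealization of FRET traces.

Each accepted trace is idealized independently with a two-state Gaussian
hidden-Markov model fit by segmental k-means: alternate (a) Viterbi
segmentation under the current state means/SDs and transition matrix with
(b) re-estimation of those parameters from the segmentation, until the
path stops changing. States are reported ordered by mean FRET (undocked =
0, mid-FRET; docked = 1, high-FRET).

A one-state (static) alternative is always scored against the converged
two-state model by BIC on the complete-data log-likelihood (emissions plus
transition terms). Splitting pure noise into two levels forces the Viterbi
path to toggle almost every frame, which the transition term penalizes by
~ln 2 per frame — more than the emission gain — so static molecules are
classified as static without a separation heuristic. Genuinely dynamic
traces, whose dwells span many frames, pay almost no transition cost and
keep the two-state model.

Dynamic traces then pass through a short-dwell refinement stage. The
Viterbi path of segmental k-means is the MAP path and is conservative
about brief excursions: single-frame events whose emission evidence is
marginal are absorbed into the surrounding dwell, and the hard-assignment
parameter estimates inflate the state SDs with camera-blurred transition
frames, compounding the loss. The refinement re-derives the emission model
from quantities that are robust to both effects — per-state medians for
the means, and SDs propagated from the measured channel noise of the
trace, sigma_E(mu) = sqrt((1-mu)^2 + mu^2) / (sqrt(2) * SNR) — and then
re-decodes by posterior (forward-backward) marginals, updating only the
transition matrix between rounds. A guard skips refinement when either
state is sparsely populated or the state separation is within three
noise SDs, where the noise model itself is unreliable.

Dwells are maximal constant-state runs of the idealized path; the first
and last dwell of every trace are censored (cut off by the start of
observation and by photobleaching) and are flagged as such for the
kinetics stage. Transition maps summarize a dataset: the TDP weights every
transition event, the TODP weights every molecule once, spread over the
distinct transition types it exhibits, with static molecules on the
diagonal — so the TODP diagonal weight estimates the static fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qc import FretTrace

__all__ = [
    "IdealizationConfig",
    "IdealizedTrace",
    "Dwell",
    "TransitionMap",
    "idealize_two_state",
    "extract_dwells",
    "build_tdp",
    "build_todp",
]

UNDOCKED, DOCKED = 0, 1
STATE_NAMES = {UNDOCKED: "undocked", DOCKED: "docked"}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class IdealizationConfig:
    max_iter: int = 100
    #: lower bound on the per-state emission SD (FRET units)
    sd_floor: float = 0.01
    #: initial self-transition probability before re-estimation
    p_stay_init: float = 0.95
    #: minimum frames required to attempt a two-state fit
    min_frames: int = 20
    #: posterior short-dwell refinement after segmental k-means
    refine: bool = True
    refine_rounds: int = 2
    #: refinement guard: frames required in each state
    refine_min_frames: int = 10
    #: refinement guard: state separation in units of the larger noise SD
    refine_separation_sds: float = 3.0
    #: physical FRET window; a fitted state mean outside it is a noise-tail
    #: artifact (ratio noise is heavy-tailed), not a conformational state
    fret_min: float = -0.2
    fret_max: float = 1.2


@dataclass
class IdealizedTrace:
    """Idealized two-state path of one molecule."""

    molecule_id: str
    state_path: np.ndarray        # 0/1 per analyzed frame
    efficiency: np.ndarray        # observed FRET on the same frames
    state_means: np.ndarray       # [mu_undocked, mu_docked], ordered
    state_sds: np.ndarray
    frame_interval: float
    n_transitions: int
    converged: bool = True

    @property
    def is_dynamic(self) -> bool:
        return self.n_transitions >= 1

    @property
    def mean_fret(self) -> float:
        return float(np.mean(self.efficiency)) if len(self.efficiency) else float("nan")


@dataclass(frozen=True)
class Dwell:
    """One uninterrupted sojourn in a state."""

    state: int
    n_frames: int
    duration: float               # seconds
    left_censored: bool
    right_censored: bool
    mean_fret: float
    molecule_id: str = ""

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class TransitionMap:
    """TDP or TODP density over (initial FRET, final FRET) in [0,1]^2."""

    kind: str                     # "TDP" | "TODP"
    grid: np.ndarray              # (n_grid, n_grid) density, y rows x columns
    edges: np.ndarray             # shared bin edges for both axes
    entries: list[tuple[float, float, float]] = field(default_factory=list)  # (x, y, weight)
    n_molecules: int = 0

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.entries))

    @property
    def diagonal_fraction(self) -> float:
        """Weight fraction of on-diagonal (no-transition) entries."""
        total = self.total_weight
        if total == 0:
            return float("nan")
        diag = sum(w for x, y, w in self.entries if x == y)
        return float(diag / total)


def _viterbi_two_state(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                       trans: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most likely 0/1 state path under Gaussian emissions."""
    n = len(x)
    log_em = -0.5 * (((x[:, None] - means[None, :]) / sds[None, :]) ** 2) \
        - np.log(sds)[None, :] - 0.5 * _LOG_2PI
    log_t = np.log(trans)
    delta = np.log(pi) + log_em[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_t          # cand[i, j] = from i to j
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + log_em[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _posterior_path(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                    trans: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Per-frame MAP state from forward-backward posterior marginals."""
    n = len(x)
    em = np.exp(-0.5 * (((x[:, None] - means[None, :]) / sds[None, :]) ** 2)) / sds[None, :]
    em = np.maximum(em, 1e-300)
    alpha = np.zeros((n, 2))
    c = np.zeros(n)
    alpha[0] = pi * em[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ trans) * em[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.ones((n, 2))
    for t in range(n - 2, -1, -1):
        beta[t] = (trans @ (em[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    return (gamma[:, 1] > gamma[:, 0]).astype(np.int8)


def _reestimate(x: np.ndarray, path: np.ndarray, sd_floor: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Means, SDs and transition matrix from a hard segmentation.

    Transition counts carry one pseudocount per cell so probabilities stay
    strictly positive; an empty state inherits the global mean/SD.
    """
    means = np.empty(2)
    sds = np.empty(2)
    for s in (0, 1):
        sel = path == s
        if np.count_nonzero(sel) >= 2:
            means[s] = np.mean(x[sel])
            sds[s] = max(np.std(x[sel]), sd_floor)
        elif np.count_nonzero(sel) == 1:
            means[s] = x[sel][0]
            sds[s] = sd_floor
        else:
            means[s] = np.mean(x)
            sds[s] = max(np.std(x), sd_floor)
    counts = np.ones((2, 2))
    np.add.at(counts, (path[:-1], path[1:]), 1.0)
    trans = counts / counts.sum(axis=1, keepdims=True)
    return means, sds, trans


def _complete_loglik(x: np.ndarray, path: np.ndarray, means: np.ndarray,
                     sds: np.ndarray, trans: np.ndarray) -> float:
    em = -0.5 * (((x - means[path]) / sds[path]) ** 2) - np.log(sds[path]) - 0.5 * _LOG_2PI
    tr = np.log(trans[path[:-1], path[1:]])
    return float(em.sum() + tr.sum())


def _two_means(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means on scalars, initialized at the 1st/99th percentiles.

    Near-extreme initialization keeps a minority state alive even when it
    holds only a few percent of the frames (mid-quantile inits collapse
    both centers into the majority mode), while staying robust to isolated
    ratio-noise outliers that raw min/max inits would latch onto.
    """
    centers = np.percentile(x, [1.0, 99.0]).astype(float)
    if centers[0] == centers[1]:
        return centers
    for _ in range(max_iter):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == s].mean() if np.any(assign == s) else centers[s] for s in (0, 1)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _static_result(ftrace: FretTrace, x: np.ndarray, converged: bool = True) -> IdealizedTrace:
    mu = float(np.mean(x))
    sd = float(np.std(x))
    return IdealizedTrace(
        molecule_id=ftrace.molecule_id,
        state_path=np.zeros(len(x), dtype=np.int8),
        efficiency=x,
        state_means=np.array([mu, mu]),
        state_sds=np.array([sd, sd]),
        frame_interval=ftrace.frame_interval,
        n_transitions=0,
        converged=converged,
    )


def _refine_short_dwells(x: np.ndarray, path: np.ndarray, trans: np.ndarray,
                         snr: float, config: IdealizationConfig
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Posterior re-decode with a blur-robust emission model.

    State means are per-state medians of the segmental-k-means path; state
    SDs are propagated from the measured channel noise via the trace SNR
    (falling back to median-absolute-deviation SDs when no SNR is
    available). Emissions stay frozen across rounds; only the transition
    matrix is re-estimated from each decoded path, which keeps the
    re-decode from running away on its own output.
    """
    n0 = int(np.count_nonzero(path == 0))
    n1 = int(np.count_nonzero(path == 1))
    sep_means, sep_sds = _robust_emissions(x, path, snr, config.sd_floor)
    if (n0 < config.refine_min_frames or n1 < config.refine_min_frames
            or sep_means[1] - sep_means[0]
            < config.refine_separation_sds * sep_sds.max()):
        means, sds, trans = _reestimate(x, path, config.sd_floor)
        return path, means, sds, trans

    means, sds = sep_means, sep_sds
    for _ in range(max(config.refine_rounds, 1)):
        pi = np.array([trans[1, 0], trans[0, 1]])
        pi = pi / pi.sum()
        new_path = _posterior_path(x, means, sds, trans, pi)
        if len(np.unique(new_path)) < 2:
            break  # refinement collapsed a state; keep the previous path
        changed = not np.array_equal(new_path, path)
        path = new_path
        counts = np.ones((2, 2))
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
        trans = counts / counts.sum(axis=1, keepdims=True)
        if not changed:
            break
    return path, means, sds, trans


def _robust_emissions(x: np.ndarray, path: np.ndarray, snr: float,
                      sd_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Median state means; SDs from channel-noise propagation (or MAD).

    For apparent FRET E = I_A/(I_D + I_A) with equal i.i.d. channel noise
    sigma_ch and total intensity I, error propagation gives
    sigma_E(E) = (sigma_ch / I) * sqrt((1-E)^2 + E^2); the trace SNR
    measured by QC is I / (sqrt(2) * sigma_ch), so
    sigma_E = sqrt((1-E)^2 + E^2) / (sqrt(2) * SNR).
    """
    means = np.empty(2)
    sds = np.empty(2)
    for s in (0, 1):
        v = x[path == s]
        if len(v) == 0:
            means[s] = float(np.median(x))
        else:
            means[s] = float(np.median(v))
        if snr > 0:
            sds[s] = np.sqrt((1.0 - means[s]) ** 2 + means[s] ** 2) / (np.sqrt(2.0) * snr)
        elif len(v) >= 5:
            sds[s] = 1.4826 * float(np.median(np.abs(v - means[s])))
        else:
            sds[s] = float(np.std(x))
        sds[s] = max(sds[s], sd_floor)
    return means, sds


def idealize_two_state(ftrace: FretTrace,
                       config: IdealizationConfig | None = None) -> IdealizedTrace:
    """Fit one trace with the two-state segmental k-means model.

    Runs on the valid pre-bleach frames. Returns a static (single-state)
    idealization when the trace has too few frames, collapses to a single
    cluster, or when BIC prefers the one-state model.
    """
    config = config or IdealizationConfig()
    x = ftrace.prebleach
    n = len(x)
    if n < config.min_frames:
        return _static_result(ftrace, x)

    centers = _two_means(x)
    if centers[1] - centers[0] < config.sd_floor:
        return _static_result(ftrace, x)
    path = (np.abs(x[:, None] - centers[None, :]).argmin(axis=1)).astype(np.int8)
    means, sds, _ = _reestimate(x, path, config.sd_floor)
    p = config.p_stay_init
    trans = np.array([[p, 1 - p], [1 - p, p]])

    converged = False
    for _ in range(config.max_iter):
        pi = np.array([trans[1, 0], trans[0, 1]])
        pi = pi / pi.sum()  # stationary distribution of the 2-state chain
        new_path = _viterbi_two_state(x, means, sds, trans, pi)
        means, sds, trans = _reestimate(x, new_path, config.sd_floor)
        if np.array_equal(new_path, path):
            path = new_path
            converged = True
            break
        path = new_path

    # order states by mean FRET: undocked (0) below docked (1)
    if means[0] > means[1]:
        means = means[::-1].copy()
        sds = sds[::-1].copy()
        trans = trans[::-1, ::-1].copy()
        path = (1 - path).astype(np.int8)

    # one-state alternative: BIC on the complete-data log-likelihood
    ll2 = _complete_loglik(x, path, means, sds, trans)
    mu0, sd0 = float(np.mean(x)), max(float(np.std(x)), config.sd_floor)
    ll1 = float(np.sum(-0.5 * ((x - mu0) / sd0) ** 2 - np.log(sd0) - 0.5 * _LOG_2PI))
    bic2 = 6.0 * np.log(n) - 2.0 * ll2
    bic1 = 2.0 * np.log(n) - 2.0 * ll1
    if bic1 <= bic2 or len(np.unique(path)) < 2:
        return _static_result(ftrace, x, converged=converged)
    if means[0] <= config.fret_min + 1e-9 or means[1] >= config.fret_max - 1e-9:
        # a cluster piled at the winsorization boundary is the heavy tail
        # of the ratio noise, not a conformational state
        return _static_result(ftrace, x, converged=converged)

    if config.refine:
        path, means, sds, trans = _refine_short_dwells(
            x, path, trans, ftrace.qc.snr, config)
        if means[0] > means[1]:
            means = means[::-1].copy()
            sds = sds[::-1].copy()
            path = (1 - path).astype(np.int8)

    return IdealizedTrace(
        molecule_id=ftrace.molecule_id,
        state_path=path,
        efficiency=x,
        state_means=means,
        state_sds=sds,
        frame_interval=ftrace.frame_interval,
        n_transitions=int(np.count_nonzero(np.diff(path))),
        converged=converged,
    )


def extract_dwells(itrace: IdealizedTrace) -> list[Dwell]:
    """Maximal constant-state runs of the idealized path.

    The first dwell is left-censored (the molecule was already in that
    state when observation started) and the last is right-censored
    (truncated by photobleaching). Durations sum exactly to the analyzed
    trace duration.
    """
    path = itrace.state_path
    if len(path) == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    dwells = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        dwells.append(Dwell(
            state=int(path[a]),
            n_frames=int(b - a),
            duration=float((b - a) * itrace.frame_interval),
            left_censored=(i == 0),
            right_censored=(i == len(starts) - 1),
            mean_fret=float(np.mean(itrace.efficiency[a:b])),
            molecule_id=itrace.molecule_id,
        ))
    return dwells


def _kde_grid(entries: list[tuple[float, float, float]], n_grid: int,
              bandwidth: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(0.0, 1.0, n_grid + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.zeros((n_grid, n_grid))
    for x, y, w in entries:
        gx = np.exp(-0.5 * ((centers - x) / bandwidth) ** 2)
        gy = np.exp(-0.5 * ((centers - y) / bandwidth) ** 2)
        grid += w * np.outer(gy, gx) / (2.0 * np.pi * bandwidth**2)
    return grid, edges


def build_tdp(itraces: list[IdealizedTrace], n_grid: int = 100,
              bandwidth: float = 0.02) -> TransitionMap:
    """Transition density plot: one point per transition event.

    Each transition contributes at (mean observed FRET of the departing
    dwell, mean observed FRET of the arriving dwell), smoothed with a
    Gaussian kernel on an ``n_grid`` x ``n_grid`` grid over [0,1]^2.
    """
    if not itraces:
        raise ValueError("need at least one idealized trace")
    entries: list[tuple[float, float, float]] = []
    for it in itraces:
        dwells = extract_dwells(it)
        for a, b in zip(dwells[:-1], dwells[1:]):
            entries.append((a.mean_fret, b.mean_fret, 1.0))
    grid, edges = _kde_grid(entries, n_grid, bandwidth)
    return TransitionMap(kind="TDP", grid=grid, edges=edges, entries=entries,
                         n_molecules=len(itraces))


def build_todp(itraces: list[IdealizedTrace], n_grid: int = 100,
               bandwidth: float = 0.02) -> TransitionMap:
    """Transition occupancy density plot: one unit of weight per molecule.

    A dynamic molecule's unit weight is split evenly over the distinct
    transition types (ordered state pairs) it exhibits at least once,
    placed at its fitted state means; a static molecule's full weight sits
    on the diagonal at its mean FRET. Total weight equals the number of
    molecules, and the diagonal weight fraction estimates the static
    fraction of the population.
    """
    if not itraces:
        raise ValueError("need at least one idealized trace")
    entries: list[tuple[float, float, float]] = []
    for it in itraces:
        if not it.is_dynamic:
            m = it.mean_fret
            entries.append((m, m, 1.0))
            continue
        pairs = set()
        path = it.state_path
        for a, b in zip(path[:-1], path[1:]):
            if a != b:
                pairs.add((int(a), int(b)))
        w = 1.0 / len(pairs)
        for a, b in sorted(pairs):
            entries.append((float(it.state_means[a]), float(it.state_means[b]), w))
    grid, edges = _kde_grid(entries, n_grid, bandwidth)
    return TransitionMap(kind="TODP", grid=grid, edges=edges, entries=entries,
                         n_molecules=len(itraces))
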