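"""UV melting-curve analysis: Tm extraction by the second-derivative method.

Thermal denaturation of the riboswitch is followed by hyperchromicity at
260 nm; each structural transition produces a sigmoidal rise in absorbance
whose inflection temperature is the melting temperature Tm. Tm is located
where dA/dT is maximal, equivalently where d2A/dT2 crosses zero, which is
robust to baseline offsets and slow drifts. The thermophilic aptamer melts
its P2 and P1 stems in two separate transitions; the mesophilic one shows
a single cooperative transition, so the extractor supports one to three
transitions per curve.

Derivatives are estimated by local polynomial regression on the native
(possibly non-uniform) temperature grid: the ramp recorded 1 degC steps
below 22 degC, 0.5 degC steps to 75 degC, then 1 degC steps again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "MeltingCurve",
    "MeltingResult",
    "MeltingConfig",
    "background_correct",
    "find_melting_temperatures",
]


@dataclass
class MeltingCurve:
    """Absorbance vs temperature, with an optional background channel.

    ``absorbance`` is A260; ``background`` (A340 or A320) tracks lamp and
    cuvette drift at a wavelength where the RNA does not absorb.
    """

    temperature: np.ndarray
    absorbance: np.ndarray
    background: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if len(self.background) != len(self.temperature):
                raise ValueError("background length mismatch")
        if len(self.temperature) != len(self.absorbance):
            raise ValueError("temperature and absorbance must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if np.any(self.temperature < 5.0) or np.any(self.temperature > 100.0):
            raise ValueError("temperatures must lie within [5, 100] degC")


@dataclass
class MeltingResult:
    """Detected melting transitions of one curve, ascending in Tm."""

    tm_list: list[float]
    prominences: list[float]
    smoothing: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.tm_list)


@dataclass(frozen=True)
class MeltingConfig:
    """Smoothing and peak-detection settings for Tm extraction.

    window/degree control the local polynomial (Savitzky-Golay-style, but
    evaluated on the actual temperatures); prominence_frac is the minimum
    dA/dT peak prominence relative to the largest derivative excursion, so
    detection is invariant to affine rescaling of the absorbance axis.
    Transitions within edge_margin of the data range are suppressed since
    derivative estimates there are one-sided and unreliable.
    """

    window: int = 15
    degree: int = 3
    prominence_frac: float = 0.3
    edge_margin: float = 3.0
    max_transitions: int = 3


def background_correct(curve: MeltingCurve) -> MeltingCurve:
    """Subtract the background-wavelength channel pointwise.

    Curves without a background channel pass through unchanged with a note
    in the label (the correction removes common-mode drift only; it never
    affects Tm of a drift-free curve).
    """
    if curve.background is None:
        return MeltingCurve(curve.temperature, curve.absorbance, None,
                            label=(curve.label + " [no background channel]").strip())
    return MeltingCurve(curve.temperature, curve.absorbance - curve.background,
                        None, label=curve.label)


def _local_poly_derivatives(t: np.ndarray, y: np.ndarray, window: int,
                            degree: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed value, first and second derivative at every point.

    Fits a degree-``degree`` polynomial to the ``window`` points nearest
    each sample (in index space, clipped at the edges) in the variable
    (T - T_i), so the fitted coefficients give the derivatives directly.
    """
    n = len(t)
    half = window // 2
    smooth = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        hi = lo + window
        x = t[lo:hi] - t[i]
        # polyfit returns highest degree first
        coef = np.polyfit(x, y[lo:hi], degree)
        smooth[i] = coef[-1]
        d1[i] = coef[-2]
        d2[i] = 2.0 * coef[-3] if degree >= 2 else 0.0
    return smooth, d1, d2


def find_melting_temperatures(curve: MeltingCurve,
                              config: MeltingConfig | None = None) -> MeltingResult:
    """Locate melting transitions of one (background-corrected) curve.

    A transition is reported where the smoothed dA/dT has a local maximum
    of sufficient relative prominence; its Tm is refined to the adjacent
    zero-crossing of d2A/dT2, linearly interpolated between grid points.
    """
    config = config or MeltingConfig()
    t, y = curve.temperature, curve.absorbance
    if len(t) < 25:
        raise ValueError("need at least 25 points for derivative analysis")
    if t[-1] - t[0] < 30.0:
        raise ValueError("temperature range must span at least 30 degC")
    window = min(config.window, len(t))
    smooth, d1, d2 = _local_poly_derivatives(t, y, window, config.degree)

    notes: list[str] = []
    if np.ptp(smooth) <= 1e-12 * max(np.max(np.abs(smooth)), 1.0):
        return MeltingResult([], [], smoothing={"window": window, "degree": config.degree},
                             notes=["flat curve: no absorbance change"])
    # derivative estimates in the one-sided edge windows are unreliable;
    # keep them out of both the scale and the peak search
    interior = (t >= t[0] + config.edge_margin) & (t <= t[-1] - config.edge_margin)
    scale = float(np.max(np.abs(d1[interior]))) if np.any(interior) else 0.0
    if scale <= 0 or not np.isfinite(scale):
        return MeltingResult([], [], smoothing={"window": window, "degree": config.degree},
                             notes=["flat curve: no derivative signal"])

    d1_search = np.where(interior, d1, -np.inf)
    peaks, props = find_peaks(d1_search, prominence=config.prominence_frac * scale)
    interior_idx = np.flatnonzero(interior)
    tms: list[float] = []
    proms: list[float] = []
    for p, prom in zip(peaks, props["prominences"]):
        if p == interior_idx[0] or p == interior_idx[-1]:
            # derivative still rising at the interior boundary: the true
            # maximum lies inside the suppressed edge region
            notes.append(f"transition near {t[p]:.1f} degC suppressed (edge margin)")
            continue
        tm = t[p]
        # refine: d2 crosses zero from + to - at the inflection
        j = p
        while j + 1 < len(t) and d2[j] > 0 and d2[j + 1] > 0:
            j += 1
        if j + 1 < len(t) and d2[j] > 0 >= d2[j + 1]:
            tm = t[j] + (t[j + 1] - t[j]) * d2[j] / (d2[j] - d2[j + 1])
        if tm < t[0] + config.edge_margin or tm > t[-1] - config.edge_margin:
            notes.append(f"transition near {tm:.1f} degC suppressed (edge margin)")
            continue
        tms.append(float(tm))
        proms.append(float(prom / scale))

    if len(tms) > config.max_transitions:
        order = np.argsort(proms)[::-1][: config.max_transitions]
        notes.append(f"kept {config.max_transitions} most prominent of {len(tms)} transitions")
        tms = [tms[i] for i in sorted(order)]
        proms = [proms[i] for i in sorted(order)]
    if not tms:
        notes.append("no transition exceeded the prominence threshold")

    order = np.argsort(tms)
    return MeltingResult(
        tm_list=[tms[i] for i in order],
        prominences=[proms[i] for i in order],
        smoothing={"window": window, "degree": config.degree,
                   "prominence_frac": config.prominence_frac},
        notes=notes,
    )
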