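"""Population thermodynamics: histograms, free energies, m-values, Phi.

The docking equilibrium is read from FRET population histograms built
from the first 100 frames of every accepted trace. The histogram is fit
with the sum of two Gaussians — mid-FRET (undocked) and high-FRET
(docked) — and the equilibrium constant is the ratio of the analytic
areas under the components,

    K_eq = AUC_high / AUC_mid,    dG_dock = -RT ln K_eq   (T = 20 degC).

Working from histogram areas rather than kinetics deliberately captures
both dynamic and static molecules in the same statistic: under
stabilizing osmolytes a substantial subpopulation docks permanently and
would be invisible to dwell-time analysis.

The m-value is the slope of an ordinary least-squares line through
dG_dock versus osmolyte concentration (positive for denaturants such as
urea, negative for protective osmolytes such as TMAO); its error is the
standard error of the fitted slope. Bootstrap errors on dG resample whole
molecules, mirroring the kinetics bootstrap.

The transition-state parameter Phi compares the osmolyte's effect on the
docking rate with its effect on the docking equilibrium:

    Phi = d ln k_dock / d ln K_eq

evaluated either between the lowest and highest concentrations (endpoint
method, the default) or as a ratio of regression slopes of ln k_dock and
ln K_eq versus concentration. Phi = 1 means the urea-sensitive contacts
are fully formed in the transition state (equivalently, k_undock is
osmolyte-independent); Phi = 0 means they only form after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .constants import R_KCAL_PER_MOL_K, T_STANDARD_K
from .qc import FretTrace

__all__ = [
    "HistogramConfig",
    "FretHistogram",
    "TwoGaussianFit",
    "TitrationPoint",
    "MValueFit",
    "PhiResult",
    "build_fret_histogram",
    "fit_two_gaussians",
    "delta_g_from_keq",
    "compute_delta_g",
    "bootstrap_delta_g",
    "fit_m_value",
    "compute_phi",
]


@dataclass(frozen=True)
class HistogramConfig:
    """FRET histogram settings: [-0.2, 1.2] range keeps noise-driven
    out-of-range values instead of clamping them; 0.02 bins."""

    first_n_frames: int = 100
    bin_width: float = 0.02
    range_min: float = -0.2
    range_max: float = 1.2


@dataclass
class FretHistogram:
    edges: np.ndarray
    counts: np.ndarray
    n_molecules: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class TwoGaussianFit:
    """Two-component Gaussian fit of a FRET histogram, ordered by mean.

    AUCs are the analytic component areas amplitude * sigma * sqrt(2 pi);
    fractions are the AUCs normalized to sum to 1.
    """

    mu_undock: float
    sigma_undock: float
    amp_undock: float
    mu_dock: float
    sigma_dock: float
    amp_dock: float
    near_degenerate: bool = False

    @property
    def auc_mid(self) -> float:
        return float(self.amp_undock * self.sigma_undock * np.sqrt(2.0 * np.pi))

    @property
    def auc_high(self) -> float:
        return float(self.amp_dock * self.sigma_dock * np.sqrt(2.0 * np.pi))

    @property
    def fractions(self) -> tuple[float, float]:
        """(undocked, docked) population fractions."""
        total = self.auc_mid + self.auc_high
        return (self.auc_mid / total, self.auc_high / total)


@dataclass
class TitrationPoint:
    concentration: float
    keq: float
    delta_g: float
    bootstrap_sd: float = float("nan")
    n_molecules: int = 0


@dataclass
class MValueFit:
    m_value: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int


@dataclass
class PhiResult:
    phi: float
    method: str                      # "endpoint" | "slope"
    inputs: dict = field(default_factory=dict)


def build_fret_histogram(ftraces: Sequence[FretTrace],
                         config: HistogramConfig | None = None) -> FretHistogram:
    """Pool the first 100 valid pre-bleach frames of each molecule."""
    config = config or HistogramConfig()
    if not ftraces:
        raise ValueError("need at least one accepted trace")
    pooled = [ft.prebleach[: config.first_n_frames] for ft in ftraces]
    values = np.concatenate(pooled) if pooled else np.empty(0)
    n_bins = int(round((config.range_max - config.range_min) / config.bin_width))
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(config.range_min, config.range_max))
    return FretHistogram(edges=edges, counts=counts.astype(float),
                         n_molecules=len(ftraces))


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def _two_gauss_jac(x, a1, m1, s1, a2, m2, s2):
    g1 = np.exp(-0.5 * ((x - m1) / s1) ** 2)
    g2 = np.exp(-0.5 * ((x - m2) / s2) ** 2)
    return np.stack([
        g1,
        a1 * g1 * (x - m1) / s1**2,
        a1 * g1 * (x - m1) ** 2 / s1**3,
        g2,
        a2 * g2 * (x - m2) / s2**2,
        a2 * g2 * (x - m2) ** 2 / s2**3,
    ], axis=1)


def fit_two_gaussians(hist: FretHistogram,
                      config: HistogramConfig | None = None) -> TwoGaussianFit:
    """Least-squares two-Gaussian fit on the bin centers.

    Components are initialized at the two most prominent local maxima of
    the (lightly smoothed) histogram; when the distribution is strongly
    skewed toward one state this keeps the second component anchored at
    the minor mode instead of collapsing both inits into the major one.
    Quantile-based inits (25/75 then 10/90) serve as fallbacks. A fit in
    which one component holds >=99% of the area is flagged near-degenerate
    (effectively unimodal data).
    """
    from scipy.signal import find_peaks

    config = config or HistogramConfig()
    x, y = hist.centers, hist.counts
    if np.count_nonzero(y) < 2:
        raise ValueError("need at least 2 occupied bins")
    total = y.sum()
    mean = float(np.sum(x * y) / total)
    sd = float(np.sqrt(np.sum(y * (x - mean) ** 2) / total))
    peak = float(y.max())
    cum = np.cumsum(y) / total

    def quantile(q: float) -> float:
        return float(np.interp(q, cum, x))

    inits: list[tuple[float, float]] = []
    y_smooth = np.convolve(y, np.ones(5) / 5.0, mode="same")
    pk, props = find_peaks(y_smooth, prominence=0.05 * float(y_smooth.max()))
    if len(pk) >= 2:
        top = np.argsort(props["prominences"])[::-1][:2]
        lo_x, hi_x = np.sort(x[pk[top]])
        inits.append((float(lo_x), float(hi_x)))
    elif len(pk) == 1:
        # one visible mode: seed the second component on either flank so a
        # minor population hiding in a shoulder can still be found
        main = float(x[pk[0]])
        inits.append((quantile(0.10), main))
        inits.append((main, quantile(0.90)))
    inits.append((quantile(0.25), quantile(0.75)))
    inits.append((quantile(0.10), quantile(0.90)))

    bounds = ([0.0, config.range_min, 0.005, 0.0, config.range_min, 0.005],
              [np.inf, config.range_max, 0.5, np.inf, config.range_max, 0.5])
    best: np.ndarray | None = None
    best_sse = np.inf
    last_err: Exception | None = None
    for lo_x, hi_x in inits:
        p0 = [peak, lo_x, max(min(sd / 2, 0.1), 0.02),
              peak, hi_x, max(min(sd / 2, 0.1), 0.02)]
        try:
            cand, _ = curve_fit(_two_gauss, x, y, p0=p0, bounds=bounds,
                                jac=_two_gauss_jac, maxfev=5000,
                                x_scale=[max(peak, 1.0), 1.0, 0.1,
                                         max(peak, 1.0), 1.0, 0.1])
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        sse = float(np.sum((y - _two_gauss(x, *cand)) ** 2))
        if sse < best_sse:
            best, best_sse = cand, sse
    if best is None:
        raise RuntimeError(f"two-Gaussian fit failed to converge: {last_err}")
    popt = best

    comps = sorted([(popt[1], popt[2], popt[0]), (popt[4], popt[5], popt[3])])
    (m1, s1, a1), (m2, s2, a2) = comps
    fit = TwoGaussianFit(mu_undock=m1, sigma_undock=s1, amp_undock=a1,
                         mu_dock=m2, sigma_dock=s2, amp_dock=a2)
    # degenerate: one component vanishing, or the two overlapping so
    # strongly (separation under two component SDs) that the data are
    # effectively unimodal
    fit.near_degenerate = (min(fit.fractions) < 0.01
                           or (m2 - m1) < 2.0 * max(s1, s2))
    return fit


def delta_g_from_keq(keq: float, temperature: float = T_STANDARD_K) -> float:
    """dG = -RT ln K_eq in kcal/mol."""
    if keq <= 0:
        raise ValueError("K_eq must be positive")
    return float(-R_KCAL_PER_MOL_K * temperature * np.log(keq))


def compute_delta_g(fit: TwoGaussianFit, temperature: float = T_STANDARD_K,
                    concentration: float = float("nan"),
                    n_molecules: int = 0) -> TitrationPoint:
    """Docking free energy from the component areas: K_eq = AUC_high/AUC_mid."""
    auc_mid, auc_high = fit.auc_mid, fit.auc_high
    if auc_mid <= 0 or auc_high <= 0:
        raise ValueError("both component areas must be positive")
    keq = auc_high / auc_mid
    return TitrationPoint(concentration=concentration, keq=keq,
                          delta_g=delta_g_from_keq(keq, temperature),
                          n_molecules=n_molecules)


def bootstrap_delta_g(ftraces: Sequence[FretTrace], B: int = 1000, seed: int = 0,
                      config: HistogramConfig | None = None,
                      temperature: float = T_STANDARD_K) -> float:
    """Bootstrap SD of dG: resample molecules, rebuild, refit, recompute.

    Replicates whose two-Gaussian fit fails are skipped (counted toward a
    warning threshold of 10%).
    """
    import warnings as _warnings

    config = config or HistogramConfig()
    m = len(ftraces)
    if m < 2:
        raise ValueError("bootstrap needs at least 2 traces")
    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, m, size=m)
        sample = [ftraces[i] for i in idx]
        try:
            hist = build_fret_histogram(sample, config)
            point = compute_delta_g(fit_two_gaussians(hist, config), temperature)
            values.append(point.delta_g)
        except (RuntimeError, ValueError):
            failed += 1
    if failed > 0.1 * B:
        _warnings.warn(f"{failed}/{B} bootstrap replicates failed to fit", stacklevel=2)
    if not values:
        return float("nan")
    vals = np.asarray(values)
    if np.ptp(vals) == 0.0:
        return 0.0  # np.std of identical values carries mean-roundoff noise
    return float(np.std(vals))


def fit_m_value(points: Sequence[TitrationPoint],
                weighted: bool = False) -> MValueFit:
    """Line through dG versus concentration; the slope is the m-value.

    Default is a plain (unweighted) OLS fit whose slope standard error is
    the reported m-value uncertainty. With ``weighted=True`` the points
    are weighted by their inverse bootstrap variances and the slope SE is
    propagated from those known per-point errors — preferable when the
    line has few points, where the OLS residual-based SE is itself highly
    uncertain.
    """
    if len(points) < 3:
        raise ValueError("m-value fit needs at least 3 concentrations")
    c = np.array([p.concentration for p in points])
    g = np.array([p.delta_g for p in points])
    if not weighted:
        res = linregress(c, g)
        return MValueFit(m_value=float(res.slope), intercept=float(res.intercept),
                         slope_se=float(res.stderr), r_squared=float(res.rvalue**2),
                         n_points=len(points))
    sd = np.array([p.bootstrap_sd for p in points])
    if not np.all(np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError("weighted fit needs positive bootstrap SDs on every point")
    w = 1.0 / sd**2
    cw = np.sum(w * c) / np.sum(w)
    gw = np.sum(w * g) / np.sum(w)
    sxx = np.sum(w * (c - cw) ** 2)
    slope = float(np.sum(w * (c - cw) * (g - gw)) / sxx)
    intercept = float(gw - slope * cw)
    slope_se = float(np.sqrt(1.0 / sxx))
    resid = g - (intercept + slope * c)
    sst = np.sum(w * (g - gw) ** 2)
    r2 = float(1.0 - np.sum(w * resid**2) / sst) if sst > 0 else float("nan")
    return MValueFit(m_value=slope, intercept=intercept, slope_se=slope_se,
                     r_squared=r2, n_points=len(points))


def compute_phi(rates_by_concentration: Mapping[float, tuple[float, float]],
                method: str = "endpoint") -> PhiResult:
    """Transition-state Phi from (k_dock, k_undock) across concentrations.

    endpoint: Phi = [ln k_dock(lo) - ln k_dock(hi)] /
                    [ln K_eq(lo) - ln K_eq(hi)] between the lowest and
    highest concentrations. slope: ratio of OLS slopes of ln k_dock and
    ln K_eq versus concentration. The two agree exactly whenever ln k is
    exactly linear in concentration. No range clamp is applied.
    """
    conc = sorted(rates_by_concentration)
    if len(conc) < 2:
        raise ValueError("Phi needs rates at >= 2 concentrations")
    kd = np.array([rates_by_concentration[c][0] for c in conc], dtype=float)
    ku = np.array([rates_by_concentration[c][1] for c in conc], dtype=float)
    if np.any(kd <= 0) or np.any(ku <= 0):
        raise ValueError("rate constants must be positive")
    ln_kd = np.log(kd)
    ln_keq = np.log(kd / ku)

    if method == "endpoint":
        d_keq = ln_keq[0] - ln_keq[-1]
        if d_keq == 0:
            raise ValueError("equilibrium unchanged between endpoints: Phi undefined")
        phi = (ln_kd[0] - ln_kd[-1]) / d_keq
        inputs = {"c_low": conc[0], "c_high": conc[-1],
                  "k_dock": (kd[0], kd[-1]), "k_undock": (ku[0], ku[-1])}
    elif method == "slope":
        s_kd = linregress(conc, ln_kd).slope
        s_keq = linregress(conc, ln_keq).slope
        if s_keq == 0:
            raise ValueError("equilibrium slope is zero: Phi undefined")
        phi = s_kd / s_keq
        inputs = {"slope_ln_k_dock": float(s_kd), "slope_ln_keq": float(s_keq)}
    else:
        raise ValueError(f"unknown Phi method: {method!r}")
    return PhiResult(phi=float(phi), method=method, inputs=inputs)
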