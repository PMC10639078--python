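"""FRET calculation and algorithmic trace selection.

Apparent FRET efficiency is computed per frame as E = I_A / (I_D + I_A)
from background-corrected intensities (no gamma correction). A trace is
accepted for analysis only if all four selection criteria hold:

1. single-step photobleaching of the total (donor + acceptor) signal,
2. at least ``min_prebleach_frames`` (default 100) frames before bleaching,
3. signal-to-noise ratio above ``min_snr`` (default 4:1),
4. mean pre-bleach total intensity above ``min_total_intensity`` (default
   300 a.u.).

The experimental workflow applied these criteria by eye; here they are
algorithmic and each decision is a pure function of the trace, recorded
per molecule in a QC table. The SNR definition (mean total intensity over
the SD of the residual after a 5-frame median filter) is a package choice,
exposed in the config, since no formula accompanies the 4:1 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .traces import Condition, ConditionDataset, IntensityTrace

__all__ = [
    "QCConfig",
    "QCReport",
    "FretTrace",
    "compute_fret",
    "detect_bleach_step",
    "estimate_snr",
    "select_traces",
]

#: SNR reported for traces whose residual SD is numerically zero.
SNR_CAP = 1e6


@dataclass(frozen=True)
class QCConfig:
    """Thresholds and detector settings for trace selection."""

    min_prebleach_frames: int = 100
    min_snr: float = 4.0
    min_total_intensity: float = 300.0
    #: post-bleach mean must fall below this fraction of the pre-bleach mean
    background_frac: float = 0.25
    #: a secondary step at least this fraction of the main drop voids single-step
    comparable_frac: float = 0.5
    #: shortest segment considered by the change-point search
    min_segment: int = 3
    median_window: int = 5
    #: optional constant per-channel background offsets subtracted before analysis
    donor_offset: float = 0.0
    acceptor_offset: float = 0.0


@dataclass
class QCReport:
    """Per-molecule selection outcome with per-criterion bookkeeping."""

    n_frames_prebleach: int = 0
    snr: float = 0.0
    total_intensity_mean: float = 0.0
    single_step_bleach: bool = True
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # invariant: accepted iff no rejection reasons
        self.accepted = not self.rejection_reasons


@dataclass
class FretTrace:
    """FRET efficiency series of one molecule with its QC verdict.

    ``efficiency`` spans the whole recording; only frames in
    ``[0, analysis_end)`` with ``valid`` True carry meaning (frames with
    non-positive total intensity are invalid and excluded from histograms
    and idealization).
    """

    efficiency: np.ndarray
    valid: np.ndarray
    analysis_end: int
    frame_interval: float
    molecule_id: str = ""
    condition: Condition = field(default_factory=Condition)
    qc: QCReport = field(default_factory=QCReport)

    @property
    def prebleach(self) -> np.ndarray:
        """Valid FRET values before the bleach."""
        return self.efficiency[: self.analysis_end][self.valid[: self.analysis_end]]


def _split_stats(total: np.ndarray, min_segment: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SSE and segment means of every two-segment piecewise-constant split."""
    n = len(total)
    c1 = np.cumsum(total)
    c2 = np.cumsum(total**2)
    ks = np.arange(min_segment, n - min_segment + 1)
    n_l = ks.astype(float)
    n_r = n - n_l
    s_l = c1[ks - 1]
    s_r = c1[-1] - s_l
    sq_l = c2[ks - 1]
    sq_r = c2[-1] - sq_l
    sse = (sq_l - s_l**2 / n_l) + (sq_r - s_r**2 / n_r)
    return ks, sse, s_l / n_l, s_r / n_r


def _two_segment_split(total: np.ndarray, min_segment: int) -> tuple[int, float, float]:
    """Best single change-point (minimal SSE); k indexes the right segment."""
    ks, sse, m_l, m_r = _split_stats(total, min_segment)
    i = int(np.argmin(sse))
    return int(ks[i]), float(m_l[i]), float(m_r[i])


def detect_bleach_step(trace: IntensityTrace,
                       config: QCConfig | None = None) -> tuple[int, bool]:
    """Locate the photobleach and judge whether it is a single step.

    The total intensity is fit with the best two-segment piecewise-constant
    model. The split counts as a bleach only if the post-step mean falls
    below ``background_frac`` of the pre-step mean; otherwise the molecule
    is taken to survive the whole recording (bleach_frame = trace length,
    single_step True). Given a bleach, the trace is single-step unless
    either flanking segment contains a second step of comparable size
    (at least ``comparable_frac`` of the main drop).
    """
    config = config or QCConfig()
    total = trace.total
    n = len(total)
    if n < max(10, 2 * config.min_segment):
        return n, True
    # restrict the change-point search to splits that look like a bleach
    # (post-step mean at background level); a staircase's intermediate
    # plateau would otherwise mask the drop to background
    ks, sse, m_l, m_r = _split_stats(total, config.min_segment)
    qualifies = m_r < config.background_frac * m_l
    if not np.any(qualifies):
        return n, True  # no qualifying bleach within the recording
    i = int(np.argmin(np.where(qualifies, sse, np.inf)))
    k, pre_mean, post_mean = int(ks[i]), float(m_l[i]), float(m_r[i])
    drop = pre_mean - post_mean

    single = True
    for seg in (total[:k], total[k:]):
        if len(seg) < 2 * config.min_segment:
            continue
        _, l_mean, r_mean = _two_segment_split(seg, config.min_segment)
        if (l_mean - r_mean) >= config.comparable_frac * drop:
            single = False
    return k, single


def estimate_snr(trace: IntensityTrace, analysis_end: int,
                 config: QCConfig | None = None) -> float:
    """Signal-to-noise of the pre-bleach total intensity.

    SNR = mean(total) / SD(total - median_filter(total, window)); the
    median filter removes the slow signal so the residual is dominated by
    shot/camera noise. Capped at a large sentinel for noiseless traces.
    """
    config = config or QCConfig()
    if analysis_end < 10:
        return 0.0
    total = trace.total[:analysis_end]
    resid = total - medfilt(total, config.median_window)
    sd = float(np.std(resid))
    mean = float(np.mean(total))
    if sd <= 0:
        return SNR_CAP if mean > 0 else 0.0
    return min(mean / sd, SNR_CAP)


def compute_fret(trace: IntensityTrace, config: QCConfig | None = None) -> FretTrace:
    """Compute per-frame FRET and assemble the QC report for one trace.

    E = I_A / (I_D + I_A) elementwise after optional constant offset
    subtraction; frames with non-positive total are marked invalid rather
    than raising. Bleach detection fixes ``analysis_end``; the four
    selection criteria populate the report (an all-invalid trace is a QC
    rejection, not an exception).
    """
    config = config or QCConfig()
    i_d = trace.i_donor - config.donor_offset
    i_a = trace.i_acceptor - config.acceptor_offset
    corrected = IntensityTrace(i_d, i_a, trace.frame_interval,
                               molecule_id=trace.molecule_id, condition=trace.condition)
    total = corrected.total
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(valid, i_a / np.where(valid, total, 1.0), np.nan)

    bleach_frame, single_step = detect_bleach_step(corrected, config)
    n_pre = int(np.count_nonzero(valid[:bleach_frame]))
    snr = estimate_snr(corrected, bleach_frame, config)
    mean_total = float(np.mean(total[:bleach_frame])) if bleach_frame > 0 else 0.0

    reasons: list[str] = []
    if not single_step:
        reasons.append("multi-step bleach")
    if n_pre < config.min_prebleach_frames:
        reasons.append(f"short trace ({n_pre} < {config.min_prebleach_frames} frames)")
    if snr <= config.min_snr:
        reasons.append(f"low SNR ({snr:.2f} <= {config.min_snr:g})")
    if mean_total <= config.min_total_intensity:
        reasons.append(f"low intensity ({mean_total:.0f} <= {config.min_total_intensity:g})")

    report = QCReport(
        n_frames_prebleach=n_pre,
        snr=snr,
        total_intensity_mean=mean_total,
        single_step_bleach=single_step,
        rejection_reasons=reasons,
    )
    return FretTrace(
        efficiency=eff,
        valid=valid,
        analysis_end=bleach_frame,
        frame_interval=trace.frame_interval,
        molecule_id=trace.molecule_id,
        condition=trace.condition,
        qc=report,
    )


def select_traces(dataset: ConditionDataset | Iterable[IntensityTrace],
                  config: QCConfig | None = None) -> tuple[list[FretTrace], pd.DataFrame]:
    """Apply the four selection criteria to every trace in a dataset.

    Returns the accepted FRET traces and a QC table with one row per
    molecule recording each criterion's outcome. An empty dataset yields
    empty outputs.
    """
    config = config or QCConfig()
    traces = list(dataset)
    rows = []
    accepted: list[FretTrace] = []
    for tr in traces:
        ft = compute_fret(tr, config)
        r = ft.qc
        rows.append({
            "molecule_id": tr.molecule_id,
            "n_frames_prebleach": r.n_frames_prebleach,
            "snr": r.snr,
            "total_intensity_mean": r.total_intensity_mean,
            "single_step_bleach": r.single_step_bleach,
            "accepted": r.accepted,
            "rejection_reasons": "; ".join(r.rejection_reasons),
        })
        if r.accepted:
            accepted.append(ft)
    columns = ["molecule_id", "n_frames_prebleach", "snr", "total_intensity_mean",
               "single_step_bleach", "accepted", "rejection_reasons"]
    table = pd.DataFrame(rows, columns=columns)
    return accepted, table
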