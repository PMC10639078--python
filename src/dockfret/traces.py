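"""Core per-molecule trace containers.

A single-molecule FRET experiment yields, per surface-immobilized molecule,
two background-corrected intensity time series recorded simultaneously:
donor (I_D) and acceptor (I_A). Docking of the pseudoknot moves the dyes
closer together, raising FRET; the two channels are anti-correlated. Frames
are 0-based and time is ``frame_index * frame_interval`` with half-open
frame intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Condition", "IntensityTrace", "ConditionDataset"]


@dataclass(frozen=True)
class Condition:
    """Solution condition a dataset was recorded under.

    Concentrations follow the experimental design: osmolytes in molar,
    Mg2+ in millimolar, the preQ1 ligand in nanomolar.
    """

    urea_M: float = 0.0
    tmao_M: float = 0.0
    mg_mM: float = 0.0
    preq1_nM: float = 100.0
    label: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "urea_M": self.urea_M,
            "tmao_M": self.tmao_M,
            "mg_mM": self.mg_mM,
            "preq1_nM": self.preq1_nM,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Condition":
        return cls(**{k: d[k] for k in ("urea_M", "tmao_M", "mg_mM", "preq1_nM", "label") if k in d})


@dataclass
class IntensityTrace:
    """Donor/acceptor intensity time series for one molecule.

    Intensities are assumed background-corrected (arbitrary units); an
    optional constant per-channel offset can be subtracted downstream.
    """

    i_donor: np.ndarray
    i_acceptor: np.ndarray
    frame_interval: float
    molecule_id: str = ""
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.i_donor = np.asarray(self.i_donor, dtype=float)
        self.i_acceptor = np.asarray(self.i_acceptor, dtype=float)
        if self.i_donor.ndim != 1 or self.i_acceptor.ndim != 1:
            raise ValueError("intensity series must be 1-D")
        if len(self.i_donor) != len(self.i_acceptor):
            raise ValueError("donor and acceptor series must have equal length")
        if len(self.i_donor) < 1:
            raise ValueError("empty trace")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.i_donor)

    @property
    def total(self) -> np.ndarray:
        """Summed donor + acceptor intensity."""
        return self.i_donor + self.i_acceptor

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(len(self)) * self.frame_interval


@dataclass
class ConditionDataset:
    """All traces recorded under one condition (one slide/movie's worth)."""

    traces: list[IntensityTrace]
    condition: Condition = field(default_factory=Condition)
    frame_interval: float = 0.06

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)
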