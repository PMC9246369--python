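"""Shared data containers: well conditions and turbidity traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AdditionEvent:
    """A late-addition/dilution event applied to a running reaction.

    Parameters
    ----------
    time_s : float
        Event time from the start of the incubation (s).
    added_volume_uL : float
        Volume added (μL); solution species are diluted by
        V_old/(V_old + V_add).
    added_inositol_mM : float
        Inositol concentration of the added solution (mM); the final
        concentration is the volume-weighted mixture.
    disruption_fraction : float
        Fraction of the extended-aggregate mass returned to the
        disulfide-locked monomer pool by mixing shear (early aggregates
        are fragile); particle number is rescaled proportionally.
    """

    time_s: float
    added_volume_uL: float = 0.0
    added_inositol_mM: float = 0.0
    disruption_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.added_volume_uL < 0:
            raise ValueError("added_volume_uL must be >= 0")
        if not 0.0 <= self.disruption_fraction <= 1.0:
            raise ValueError("disruption_fraction must be in [0, 1]")


@dataclass(frozen=True)
class WellCondition:
    """Experimental condition of a single plate well."""

    protein_uM: float = 40.0
    variant: str = "W42Q"
    inositol_mM: float = 0.0
    oxd: float = 1.0
    total_glutathione_mM: float = 1.0
    temperature_C: float = 37.0  # metadata only; no Arrhenius scaling
    events: tuple[AdditionEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.protein_uM < 0:
            raise ValueError("protein_uM must be >= 0")
        if not 0.0 <= self.oxd <= 1.0:
            raise ValueError("oxd must be in [0, 1]")
        if self.total_glutathione_mM < 0:
            raise ValueError("total_glutathione_mM must be >= 0")
        if self.inositol_mM < 0:
            raise ValueError("inositol_mM must be >= 0")


@dataclass
class TurbidityTrace:
    """One well's turbidity time series plus its condition metadata."""

    well: str
    condition: WellCondition
    times: np.ndarray
    turbidity: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.turbidity = np.asarray(self.turbidity, dtype=float)
        if self.times.shape != self.turbidity.shape:
            raise ValueError("times and turbidity must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.turbidity)):
            raise ValueError("turbidity must be finite")

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, TurbidityTrace):
            return NotImplemented
        return (
            self.well == other.well
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.turbidity, other.turbidity)
        )
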