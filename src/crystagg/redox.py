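"""Glutathione redox arithmetic, PEGylation gel-band simulation, and the
lens free-water concentration estimator.

The degree of oxidation of a glutathione buffer is

    OxD = 2[GSSG] / ([GSH] + 2[GSSG])

so OxD = 0 is fully reduced and OxD = 1 fully oxidized; the total
[GSH] + 2[GSSG] is conserved by thiol–disulfide exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ParameterError

__all__ = [
    "RedoxBuffer",
    "GelLane",
    "LensConcEstimate",
    "oxd",
    "speciate",
    "lens_free_water_concentration",
    "pegylation_lane",
    "marker_lane",
]


def oxd(gsh_mM: float, gssg_mM: float) -> float:
    """Degree of oxidation 2[GSSG]/([GSH]+2[GSSG]) of a glutathione buffer."""
    if gsh_mM < 0 or gssg_mM < 0:
        raise ParameterError("glutathione concentrations must be >= 0")
    total = gsh_mM + 2.0 * gssg_mM
    if total == 0:
        raise ParameterError("OxD undefined: [GSH] and [GSSG] both zero")
    return 2.0 * gssg_mM / total


def speciate(oxd_value: float, total_mM: float) -> tuple[float, float]:
    """Invert OxD at fixed total glutathione: return ([GSH], [GSSG]) in mM."""
    if not 0.0 <= oxd_value <= 1.0:
        raise ParameterError(f"oxd must be in [0, 1], got {oxd_value!r}")
    if total_mM <= 0:
        raise ParameterError("total glutathione must be > 0")
    gssg = oxd_value * total_mM / 2.0
    gsh = total_mM * (1.0 - oxd_value)
    return gsh, gssg


@dataclass(frozen=True)
class RedoxBuffer:
    """A glutathione redox buffer, constructed from [GSH] and [GSSG]."""

    gsh: float  # mM
    gssg: float  # mM

    def __post_init__(self) -> None:
        if self.gsh < 0 or self.gssg < 0:
            raise ParameterError("glutathione concentrations must be >= 0")

    @classmethod
    def from_oxd(cls, oxd_value: float, total_mM: float) -> "RedoxBuffer":
        gsh, gssg = speciate(oxd_value, total_mM)
        return cls(gsh=gsh, gssg=gssg)

    @property
    def total(self) -> float:
        return self.gsh + 2.0 * self.gssg

    @property
    def oxd(self) -> float:
        return oxd(self.gsh, self.gssg)


@dataclass(frozen=True)
class LensConcEstimate:
    """Metabolite concentration in the free water of lens tissue."""

    tissue_umol_per_g: float
    tissue_se: float
    water_fraction: float
    free_water_fraction: float
    concentration_mM: float
    concentration_se_mM: float


def lens_free_water_concentration(
    tissue_umol_per_g: float,
    tissue_se: float = 0.0,
    water_fraction: float = 0.6,
    free_water_fraction: float = 0.5,
) -> LensConcEstimate:
    """Convert a tissue metabolite content (μmol per g wet tissue) to an
    effective concentration in the free (unbound) water fraction.

    Assuming a free-water density of 1 g/mL, μmol per mL of free water
    equals mM, so

        c = m / (water_fraction × free_water_fraction)

    with the standard error propagated linearly by the same factor.
    Defaults (60% water, 50% of it free) are typical of healthy human
    lens tissue.
    """
    if tissue_umol_per_g < 0 or tissue_se < 0:
        raise ParameterError("tissue content and s.e. must be >= 0")
    if not 0 < water_fraction <= 1 or not 0 < free_water_fraction <= 1:
        raise ParameterError("water fractions must be in (0, 1]")
    factor = 1.0 / (water_fraction * free_water_fraction)
    return LensConcEstimate(
        tissue_umol_per_g=tissue_umol_per_g,
        tissue_se=tissue_se,
        water_fraction=water_fraction,
        free_water_fraction=free_water_fraction,
        concentration_mM=tissue_umol_per_g * factor,
        concentration_se_mM=tissue_se * factor,
    )


@dataclass(frozen=True)
class GelLane:
    """One lane of a PEG-maleimide gel-shift assay.

    ``bands`` maps PEG count (= free-thiol count per molecule) to
    fractional band intensity; fractions sum to 1.
    """

    bands: dict[int, float]
    n_cys: int
    label: str = ""

    def __post_init__(self) -> None:
        fr = np.array(list(self.bands.values()), dtype=float)
        if np.any(fr < 0):
            raise ParameterError("band fractions must be >= 0")
        if fr.size and not np.isclose(fr.sum(), 1.0, atol=1e-9):
            raise ParameterError(f"band fractions must sum to 1, got {fr.sum()!r}")

    def fraction(self, peg_count: int) -> float:
        return self.bands.get(peg_count, 0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.bands.items(), reverse=True),
            columns=["band_peg_count", "fraction"],
        )


def pegylation_lane(thiol_fractions: dict[int, float], n_cys: int = 4,
                    label: str = "") -> GelLane:
    """Build a gel lane from a free-thiol-class fraction table.

    For intramolecular-disulfide chemistry the attainable PEG counts
    are n_cys, n_cys−2 and n_cys−4 (each internal disulfide removes two
    free thiols); any other class is rejected.
    """
    attainable = {n_cys - 2 * k for k in range(n_cys // 2 + 1)}
    bad = set(thiol_fractions) - attainable
    if bad:
        raise ParameterError(
            f"unattainable free-thiol counts {sorted(bad)} for n_cys={n_cys}")
    total = sum(thiol_fractions.values())
    if total <= 0:
        raise ParameterError("thiol fractions must have positive total")
    bands = {int(k): v / total for k, v in thiol_fractions.items()}
    return GelLane(bands=bands, n_cys=n_cys, label=label)


def marker_lane(n_cys: int = 6, labeling_probability: float = 0.5,
                label: str = "marker") -> GelLane:
    """Partial-PEGylation marker lane with independent per-thiol labeling.

    Every free thiol of a fully reduced protein is labeled independently
    with probability p, giving a Binomial(n_cys, p) ladder over PEG
    counts 0..n_cys.
    """
    if not 0.0 <= labeling_probability <= 1.0:
        raise ParameterError("labeling probability must be in [0, 1]")
    ks = np.arange(n_cys + 1)
    pmf = stats.binom.pmf(ks, n_cys, labeling_probability)
    return GelLane(bands={int(k): float(p) for k, p in zip(ks, pmf)},
                   n_cys=n_cys, label=label)
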