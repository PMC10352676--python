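"""Leaf pigment quantification, structural traits, and partitioning of leaf
nitrogen into photosynthetic pools.

Pigments are quantified from 95%-ethanol extract absorbances at 665, 649
and 470 nm with the standard coefficient set for that solvent
(concentrations in µg mL⁻¹):

    Chl a = 13.95*A665 - 6.88*A649
    Chl b = 24.96*A649 - 7.32*A665
    Car   = (1000*A470 - 2.05*Chl a - 114.8*Chl b) / 245

These coefficients are the single source of truth for every pigment number
the package produces; an alternative set can be supplied per call.

The fractions of leaf nitrogen invested in active Rubisco (P_R),
bioenergetics pools (P_B, cytochrome f) and light-harvesting
chlorophyll–protein complexes (P_L) follow the classical partitioning

    P_R = Vcmax / (6.25 * V_cr * M_A * N_mass)
    P_B = Jmax  / (8.06 * J_mc * M_A * N_mass)
    P_L = C_c / (C_B * N_mass)

with V_cr = 20.5 µmol CO₂ (g Rubisco)⁻¹ s⁻¹ and J_mc = 156 µmol electrons
(µmol cyt f)⁻¹ s⁻¹ (both 25°C values, so 25°C-normalized capacities are
used by default), C_B = 2.15 mmol g⁻¹, M_A leaf dry mass per area (g m⁻²)
and N_mass nitrogen per dry mass (g g⁻¹).  C_c is chlorophyll per dry mass
in mmol g⁻¹, converted from area-based content with a mean chlorophyll
molar mass of 901 g mol⁻¹ (≈3:1 a:b mix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbsorbanceReading",
    "LeafSample",
    "PigmentCoefficients",
    "ETHANOL_95",
    "AllocationConstants",
    "ALLOCATION_DEFAULTS",
    "pigments_from_absorbance",
    "structural_traits",
    "allocation_fractions",
    "chl_to_n_ratio",
]

CHL_MOLAR_MASS = 901.0  # g mol⁻¹, mean of chlorophyll a (893.5) and b (907.5), ~3:1
UG_CM2_PER_G_M2 = 100.0  # 1 g m⁻² = 100 µg cm⁻²


@dataclass(frozen=True)
class PigmentCoefficients:
    """Linear absorbance→concentration coefficients for one solvent system."""

    chla_665: float
    chla_649: float
    chlb_649: float
    chlb_665: float
    car_470: float
    car_chla: float
    car_chlb: float
    car_denom: float


ETHANOL_95 = PigmentCoefficients(
    chla_665=13.95,
    chla_649=-6.88,
    chlb_649=24.96,
    chlb_665=-7.32,
    car_470=1000.0,
    car_chla=-2.05,
    car_chlb=-114.8,
    car_denom=245.0,
)


@dataclass
class AbsorbanceReading:
    """Spectrophotometer readings for one leaf extract."""

    a665: float
    a649: float
    a470: float
    volume_ml: float
    leaf_area_cm2: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a665, self.a649, self.a470) < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.volume_ml <= 0 or self.leaf_area_cm2 <= 0 or self.dilution <= 0:
            raise ValueError("volume, area and dilution must be positive")


@dataclass
class LeafSample:
    """Per-leaf trait record (area units µg cm⁻² unless noted)."""

    leaf_id: str
    doy: int
    stage: str
    n_area: float  # µg cm⁻²
    chl_area: float
    car_area: float
    sla: float  # cm² g⁻¹
    m_a: float  # g m⁻²
    n_mass: float  # g g⁻¹

    def validate(self) -> list[str]:
        out = []
        vals = {
            "n_area": self.n_area,
            "chl_area": self.chl_area,
            "car_area": self.car_area,
            "sla": self.sla,
            "m_a": self.m_a,
            "n_mass": self.n_mass,
        }
        for name, v in vals.items():
            if not v > 0:
                out.append(f"sample {self.leaf_id}: nonpositive {name}")
        # n_area (µg cm⁻²) must equal M_A * N_mass expressed in the same unit
        implied = self.m_a * self.n_mass * UG_CM2_PER_G_M2
        if self.n_area > 0 and abs(implied - self.n_area) / self.n_area > 1e-6:
            out.append(
                f"sample {self.leaf_id}: n_area {self.n_area:.4f} µg cm⁻² "
                f"inconsistent with m_a*n_mass = {implied:.4f}"
            )
        return out


def pigments_from_absorbance(
    reading: AbsorbanceReading, coefficients: PigmentCoefficients = ETHANOL_95
) -> tuple[float, float]:
    """Area-based chlorophyll and carotenoid content (µg cm⁻²) from absorbances.

    Negative computed concentrations (possible near the detection limit)
    are clipped to zero with a warning.
    """
    c = coefficients
    chla = c.chla_665 * reading.a665 + c.chla_649 * reading.a649
    chlb = c.chlb_649 * reading.a649 + c.chlb_665 * reading.a665
    car = (c.car_470 * reading.a470 + c.car_chla * chla + c.car_chlb * chlb) / c.car_denom
    clipped = [n for n, v in (("chl_a", chla), ("chl_b", chlb), ("car", car)) if v < 0]
    if clipped:
        warnings.warn(
            f"below-detection pigment concentration clipped to 0: {clipped}",
            stacklevel=2,
        )
    chla, chlb, car = max(chla, 0.0), max(chlb, 0.0), max(car, 0.0)
    scale = reading.volume_ml * reading.dilution / reading.leaf_area_cm2
    return (chla + chlb) * scale, car * scale


def structural_traits(
    dry_mass_g: float, leaf_area_cm2: float, n_mass: float
) -> tuple[float, float, float]:
    """(SLA cm² g⁻¹, M_A g m⁻², N_area µg cm⁻²) from dry mass, area and N_mass."""
    if dry_mass_g <= 0 or leaf_area_cm2 <= 0 or n_mass <= 0:
        raise ValueError("dry mass, leaf area and n_mass must be positive")
    sla = leaf_area_cm2 / dry_mass_g
    m_a = dry_mass_g / leaf_area_cm2 * 1.0e4  # g cm⁻² → g m⁻²
    n_area = m_a * n_mass * UG_CM2_PER_G_M2  # g m⁻² → µg cm⁻²
    return sla, m_a, n_area


@dataclass(frozen=True)
class AllocationConstants:
    """Fixed constants of the nitrogen-partitioning equations."""

    v_cr: float = 20.5  # µmol CO₂ (g Rubisco)⁻¹ s⁻¹ at 25°C
    j_mc: float = 156.0  # µmol electrons (µmol cyt f)⁻¹ s⁻¹ at 25°C
    c_b: float = 2.15  # mmol g⁻¹
    rubisco_n: float = 6.25  # g Rubisco per g N
    bioenergetics_factor: float = 8.06


ALLOCATION_DEFAULTS = AllocationConstants()


@dataclass
class AllocationFractions:
    """Fractions of leaf N in Rubisco, bioenergetics and light harvesting."""

    p_r: float
    p_b: float
    p_l: float


def chl_area_to_cc(chl_area_ug_cm2: float, m_a: float) -> float:
    """Area-based chlorophyll (µg cm⁻²) → C_c, mmol per g leaf dry mass."""
    chl_g_m2 = chl_area_ug_cm2 / UG_CM2_PER_G_M2
    return chl_g_m2 / m_a / CHL_MOLAR_MASS * 1000.0


def allocation_fractions(
    vcmax: float,
    jmax: float,
    chl_area: float,
    m_a: float,
    n_mass: float,
    constants: AllocationConstants = ALLOCATION_DEFAULTS,
    leaf_id: str = "?",
) -> AllocationFractions:
    """Partition leaf nitrogen into P_R, P_B, P_L.

    ``vcmax`` and ``jmax`` should be the 25°C-normalized rates, matching the
    25°C values of V_cr and J_mc; callers that deliberately pass
    leaf-temperature rates get the same arithmetic.  Fractions outside
    (0, 1) indicate implausible inputs and trigger a warning naming the
    leaf, not an error.
    """
    if min(vcmax, jmax, chl_area, m_a, n_mass) <= 0:
        raise ValueError("allocation inputs must all be positive")
    k = constants
    p_r = vcmax / (k.rubisco_n * k.v_cr * m_a * n_mass)
    p_b = jmax / (k.bioenergetics_factor * k.j_mc * m_a * n_mass)
    p_l = chl_area_to_cc(chl_area, m_a) / (k.c_b * n_mass)
    for name, v in (("p_r", p_r), ("p_b", p_b), ("p_l", p_l)):
        if not 0.0 < v < 1.0:
            warnings.warn(
                f"leaf {leaf_id}: allocation fraction {name} = {v:.3f} outside (0, 1)",
                stacklevel=2,
            )
    return AllocationFractions(p_r=p_r, p_b=p_b, p_l=p_l)


def chl_to_n_ratio(samples: pd.DataFrame) -> pd.Series:
    """Per-DOY mean Chl_area/N_area ratio (both in µg cm⁻²).

    Expects columns ``doy``, ``chl_area_ug_cm2``, ``n_area_ug_cm2``.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    if np.any(samples["n_area_ug_cm2"].to_numpy() == 0):
        raise ValueError("zero n_area in samples")
    ratio = samples["chl_area_ug_cm2"] / samples["n_area_ug_cm2"]
    return ratio.groupby(samples["doy"]).mean()
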