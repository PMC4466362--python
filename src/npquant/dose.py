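"""Dose arithmetic linking administered, delivered and intracellular particle doses.

Conversions between particle number and mass concentrations, monolayer surface
coverage, occupied intracellular volume, intracellular number concentration,
uptake efficiency, and the BET specific-surface-area size regression.

Unit conventions: particle diameters in nm, densities in g cm^-3, number
concentrations per mL, mass concentrations in ug mL^-1, areas in um^2 or cm^2
as suffixed, cell volumes in um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

UM3_PER_ML = 1e12  # 1 mL = 1 cm^3 = 1e12 um^3

# BET specific surface area vs diameter, linear fit to bare silica calibration
# sizes 23/35/72 nm; invalid outside that range.
BET_INTERCEPT = 143.2
BET_SLOPE = -1.505
BET_CALIBRATION_RANGE_NM = (23.0, 72.0)


def particle_mass_ug(diameter_nm: float, density_g_cm3: float) -> float:
    """Mass of one spherical particle in micrograms: rho * (pi/6) d^3."""
    if diameter_nm <= 0 or density_g_cm3 <= 0:
        raise ValueError("diameter and density must be positive")
    volume_cm3 = math.pi / 6.0 * (diameter_nm * 1e-7) ** 3
    return density_g_cm3 * volume_cm3 * 1e6  # g -> ug


def mass_from_number(number_per_ml: float, diameter_nm: float, density_g_cm3: float) -> float:
    """Mass concentration (ug mL^-1) for a number concentration (mL^-1)."""
    if number_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return number_per_ml * particle_mass_ug(diameter_nm, density_g_cm3)


def number_from_mass(mass_ug_per_ml: float, diameter_nm: float, density_g_cm3: float) -> float:
    """Number concentration (mL^-1) for a mass concentration (ug mL^-1)."""
    if mass_ug_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return mass_ug_per_ml / particle_mass_ug(diameter_nm, density_g_cm3)


def surface_coverage(per_area_cm2: float, diameter_nm: float) -> float:
    """Projected monolayer area fraction covered by deposited particles.

    coverage = (deposited number per cm^2) x (pi d^2 / 4).  May exceed 1 for
    supersaturated deposition (more than a close-packed monolayer's worth).
    """
    if per_area_cm2 < 0:
        raise ValueError("areal density must be >= 0")
    projected_area_cm2 = math.pi / 4.0 * (diameter_nm * 1e-7) ** 2
    return per_area_cm2 * projected_area_cm2


def volume_occupancy(n_particles: float, diameter_nm: float, cell_volume_um3: float) -> tuple[float, float]:
    """(occupied volume in um^3, fraction of the cell volume) for n particles."""
    if n_particles < 0:
        raise ValueError("particle count must be >= 0")
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    occupied_um3 = n_particles * math.pi / 6.0 * (diameter_nm * 1e-3) ** 3  # nm -> um
    return occupied_um3, occupied_um3 / cell_volume_um3


def intracellular_concentration(n_particles: float, cell_volume_um3: float) -> float:
    """Intracellular number concentration in mL^-1: n / V_cell."""
    if n_particles < 0:
        raise ValueError("particle count must be >= 0")
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    return n_particles / cell_volume_um3 * UM3_PER_ML


def uptake_efficiency(
    n_internalized: float, delivered_per_area_um2: float, cell_area_um2: float
) -> float:
    """Percent of the delivered particles over the cell footprint that entered.

    100 x n_internalized / (delivered areal density x projected cell area),
    with the areal density in um^-2 and the area in um^2.
    """
    if delivered_per_area_um2 <= 0 or cell_area_um2 <= 0:
        raise ValueError("delivered density and cell area must be positive")
    if n_internalized < 0:
        raise ValueError("internalized count must be >= 0")
    return 100.0 * n_internalized / (delivered_per_area_um2 * cell_area_um2)


def bet_surface_area(diameter_nm: float) -> tuple[float, bool]:
    """Extrapolated BET specific surface area (m^2 g^-1) and an in-range flag.

    Linear in diameter: 143.2 - 1.505 d.  The flag is False outside the
    23-72 nm calibration range (the regression has no physical basis there);
    a non-positive extrapolation raises.
    """
    if diameter_nm < 0:
        raise ValueError("diameter must be >= 0")
    value = BET_INTERCEPT + BET_SLOPE * diameter_nm
    if value <= 0:
        raise ValueError(
            f"BET regression extrapolates to {value:.1f} m^2/g at d = {diameter_nm} nm; "
            "out of calibration"
        )
    lo, hi = BET_CALIBRATION_RANGE_NM
    return value, (lo <= diameter_nm <= hi)


@dataclass
class DoseReport:
    """Administered -> delivered -> intracellular dose chain for one condition."""

    diameter_nm: float
    density_g_cm3: float
    administered_per_ml: float
    administered_ug_per_ml: float
    delivered_fraction: float
    delivered_per_cm2: float
    internalized_per_cell: float
    cell_volume_um3: float
    cell_area_um2: float
    intracellular_per_ml: float
    occupied_volume_um3: float
    occupied_volume_fraction: float
    surface_coverage_fraction: float
    uptake_efficiency_pct: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d


def build_dose_report(
    diameter_nm: float,
    density_g_cm3: float,
    administered_per_ml: float,
    delivered_fraction: float,
    column_height_cm: float,
    internalized_per_cell: float,
    cell_volume_um3: float = 1600.0,
    cell_area_um2: float = 1000.0,
) -> DoseReport:
    """Assemble the full dose chain from administered concentration to
    intracellular occupancy; no hidden state, every number derives from the
    arguments."""
    per_cm2 = delivered_fraction * administered_per_ml * column_height_cm
    occupied, vol_fraction = volume_occupancy(internalized_per_cell, diameter_nm, cell_volume_um3)
    coverage = surface_coverage(per_cm2, diameter_nm)
    per_um2 = per_cm2 / 1e8  # cm^2 -> um^2
    flags = []
    if coverage > 1.0:
        flags.append("supersaturated: coverage exceeds a full monolayer")
    return DoseReport(
        diameter_nm=diameter_nm,
        density_g_cm3=density_g_cm3,
        administered_per_ml=administered_per_ml,
        administered_ug_per_ml=mass_from_number(administered_per_ml, diameter_nm, density_g_cm3),
        delivered_fraction=delivered_fraction,
        delivered_per_cm2=per_cm2,
        internalized_per_cell=internalized_per_cell,
        cell_volume_um3=cell_volume_um3,
        cell_area_um2=cell_area_um2,
        intracellular_per_ml=intracellular_concentration(internalized_per_cell, cell_volume_um3),
        occupied_volume_um3=occupied,
        occupied_volume_fraction=vol_fraction,
        surface_coverage_fraction=coverage,
        uptake_efficiency_pct=uptake_efficiency(internalized_per_cell, per_um2, cell_area_um2),
        flags=flags,
    )
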