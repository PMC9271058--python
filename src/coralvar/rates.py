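"""Specimen-level physiology: buoyant-weight calcification, respirometry, geometry.

Converts raw longitudinal measurements on individual corals into the
response variables of the transplantation analysis:

* skeletal dry mass from buoyant mass via Archimedes' principle
  (M_dry = M_buoyant / (1 - rho_sw/rho_aragonite)), with seawater density
  at the weighing-bath temperature and salinity from EOS-80;
* net calcification G = dM * 1000 / (A * t) in mg CaCO3 cm-2 d-1, and the
  mass-normalised alternative in % d-1;
* dark respiration from closed-chamber O2 drawdown with control-vial
  (background plankton) subtraction, in umol O2 cm-2 d-1;
* tissue-covered surface area of the trumpet-shaped calyx from calliper
  geometry, as a cup (truncated-cone frustum, inner + outer lateral faces,
  septa ignored).

The default skeletal aragonite density is 2.793 g cm-3, the species value
derived from bleached Desmophyllum dianthus skeletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from statistics import fmean

from .carbonate import seawater_density

__all__ = [
    "ARAGONITE_DENSITY",
    "SpecimenRecord",
    "WeighingRecord",
    "GeometryRecord",
    "IncubationRecord",
    "RateRecord",
    "dry_mass_from_buoyant",
    "skeletal_density",
    "calcification_rate",
    "relative_calcification",
    "cone_surface_area",
    "respiration_rate",
]

#: skeletal aragonite density of D. dianthus, g cm-3
ARAGONITE_DENSITY = 2.793

#: molar mass of O2, g mol-1 (for the mg L-1 -> umol L-1 I/O converter)
O2_MOLAR_MASS = 31.998


@dataclass(frozen=True)
class SpecimenRecord:
    """One coral: origin, deployment and transplant status."""

    specimen_id: str
    origin_station: str
    deployment_station: str
    transplant_status: str  # "native" | "novel"
    cohort: str = "experimental"

    def __post_init__(self) -> None:
        if self.transplant_status not in ("native", "novel"):
            raise ValueError(f"bad transplant_status {self.transplant_status!r}")
        native = self.origin_station == self.deployment_station
        if native != (self.transplant_status == "native"):
            raise ValueError(
                f"{self.specimen_id}: transplant_status inconsistent with "
                f"origin={self.origin_station}, deployment={self.deployment_station}"
            )


@dataclass(frozen=True)
class WeighingRecord:
    """One buoyant weighing with the bath conditions needed for density."""

    specimen_id: str
    date: date
    buoyant_mass: float  # g
    bath_temperature: float  # degC
    bath_salinity: float  # practical

    def __post_init__(self) -> None:
        if self.buoyant_mass <= 0:
            raise ValueError("buoyant_mass must be positive")


@dataclass(frozen=True)
class GeometryRecord:
    """Calliper geometry of the calyx (mm) and tissue-covered fraction."""

    specimen_id: str
    date: date
    oral_diameter: float
    basal_diameter: float
    height: float
    tissue_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.oral_diameter, self.basal_diameter, self.height) <= 0:
            raise ValueError("calyx dimensions must be positive")
        if self.basal_diameter > self.oral_diameter:
            raise ValueError("trumpet shape requires oral_diameter >= basal_diameter")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class IncubationRecord:
    """Closed-chamber O2 incubation endpoints (umol L-1)."""

    specimen_id: str | None  # None marks a seawater control vial
    o2_start: float
    o2_end: float
    vial_volume: float  # L
    duration: float  # h
    bath_temperature: float  # degC

    def __post_init__(self) -> None:
        if self.vial_volume <= 0 or self.duration <= 0:
            raise ValueError("vial_volume and duration must be positive")
        if self.o2_start < 0 or self.o2_end < 0:
            raise ValueError("O2 concentrations must be >= 0")

    @property
    def is_control(self) -> bool:
        return self.specimen_id is None

    @property
    def delta_o2(self) -> float:
        """O2 drawdown, umol L-1 (positive = consumption)."""
        return self.o2_start - self.o2_end


@dataclass(frozen=True)
class RateRecord:
    """Per-specimen, per-season derived responses."""

    specimen_id: str
    season: str
    calcification_g: float  # mg CaCO3 cm-2 d-1
    calcification_rel: float  # % d-1
    respiration: float | None  # umol O2 cm-2 d-1
    surface_area_used: float  # cm2
    growth_days: float
    respiration_flagged: bool = False

    def __post_init__(self) -> None:
        if self.growth_days <= 0:
            raise ValueError("growth_days must be positive")
        if self.surface_area_used <= 0:
            raise ValueError("surface_area_used must be positive")


# ----------------------------------------------------------------------
# operations


def dry_mass_from_buoyant(
    weighing: WeighingRecord,
    aragonite_density: float = ARAGONITE_DENSITY,
    rho_sw: float | None = None,
) -> float:
    """Skeletal dry mass (g) from a buoyant weighing via Archimedes.

    M_dry = M_buoyant / (1 - rho_sw / rho_aragonite).  The seawater density
    (g cm-3) is evaluated from the bath temperature and salinity (EOS-80)
    unless an explicit ``rho_sw`` is given.
    """
    if rho_sw is None:
        rho_sw = (
            seawater_density(weighing.bath_temperature, weighing.bath_salinity) / 1000.0
        )
    if aragonite_density <= rho_sw:
        raise ValueError(
            f"aragonite density {aragonite_density} g cm-3 must exceed the "
            f"seawater density {rho_sw:.4f} g cm-3"
        )
    return weighing.buoyant_mass / (1.0 - rho_sw / aragonite_density)


def skeletal_density(dry_mass: float, buoyant_mass: float, rho_sw: float) -> float:
    """Skeletal density (g cm-3) from paired dry and buoyant masses.

    rho = M_dry * rho_sw / (M_dry - M_buoyant); algebraic inverse of
    :func:`dry_mass_from_buoyant`.  rho_sw in g cm-3.
    """
    if buoyant_mass <= 0 or dry_mass <= buoyant_mass:
        raise ValueError("requires dry_mass > buoyant_mass > 0")
    return dry_mass * rho_sw / (dry_mass - buoyant_mass)


def calcification_rate(
    mass_start: float, mass_end: float, days: float, area: float
) -> float:
    """Net calcification G (mg CaCO3 cm-2 d-1) over one growth period.

    G = (M_end - M_start) * 1000 / (area * days); negative values indicate
    net dissolution of the skeleton.
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    return (mass_end - mass_start) * 1000.0 / (area * days)


def relative_calcification(mass_start: float, mass_end: float, days: float) -> float:
    """Calcification normalised to initial skeletal mass, % d-1."""
    if mass_start <= 0:
        raise ValueError("mass_start must be positive")
    if days <= 0:
        raise ValueError("days must be positive")
    return 100.0 * (mass_end - mass_start) / (mass_start * days)


def cone_surface_area(geometry: GeometryRecord) -> float:
    """Tissue-covered calyx area (cm2) from the cup approximation.

    The calyx is a truncated cone of oral radius r_o, basal radius r_b and
    height h; the tissue covers both the outer and the congruent inner
    lateral face (wall thickness and septa ignored):

        A = tissue_fraction * 2 * pi * (r_o + r_b) * slant,
        slant = sqrt(h^2 + (r_o - r_b)^2).

    Inputs in mm, output in cm2.
    """
    r_o = geometry.oral_diameter / 2.0
    r_b = geometry.basal_diameter / 2.0
    slant = math.hypot(geometry.height, r_o - r_b)
    lateral_mm2 = math.pi * (r_o + r_b) * slant
    return geometry.tissue_fraction * 2.0 * lateral_mm2 / 100.0


def respiration_rate(
    coral: IncubationRecord,
    controls: list[IncubationRecord],
    area: float,
    duration_tolerance: float = 0.25,
) -> tuple[float, bool]:
    """Blank-corrected dark respiration in umol O2 cm-2 d-1.

    The mean control (seawater-only) drawdown is subtracted from the coral
    vial's drawdown; the net amount is scaled by vial volume, normalised to
    tissue area and expressed per day.  Returns ``(rate, flagged)`` where
    ``flagged`` marks a negative net consumption (kept, not dropped).
    """
    if coral.is_control:
        raise ValueError("first argument must be a coral vial, not a control")
    ctrl = [c for c in controls if c.is_control]
    if not ctrl:
        raise ValueError("at least one control vial is required")
    for c in ctrl:
        if abs(c.duration - coral.duration) > duration_tolerance:
            raise ValueError(
                f"control duration {c.duration} h deviates from coral vial "
                f"duration {coral.duration} h beyond {duration_tolerance} h"
            )
    if area <= 0:
        raise ValueError("area must be positive")
    blank = fmean(c.delta_o2 for c in ctrl)
    net_umol = (coral.delta_o2 - blank) * coral.vial_volume
    rate = net_umol / (area * coral.duration) * 24.0
    return rate, rate < 0.0


def o2_mg_per_l_to_umol(value_mg_per_l: float) -> float:
    """I/O-layer unit converter: O2 in mg L-1 to umol L-1."""
    return value_mg_per_l / O2_MOLAR_MASS * 1000.0
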