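"""Analytical perfusion physics for a parallel-plate culture chamber.

The culture chamber is a shallow rectangular slit (13 mm across the flow,
4 mm along it, 450 µm high) perfused with warm culture medium.  For fully
developed laminar flow between infinite parallel plates the wall shear
stress is

    tau_w = 6 * mu * Q / (h**2 * w),

and the shear decays linearly with height above the wall,
tau(z) = tau_w * |1 - 2 z / h| (zero at mid-gap).  This module also
provides the chamber bookkeeping built on the same geometry: residence
time V/Q, media-exchange rate per unit culture area, culture area and
seeding density.

All quantities are stored in SI units internally; helpers convert the
bench units (µl/h, mm, µm) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ChamberGeometry",
    "FluidProperties",
    "PerfusionConditions",
    "ul_per_h_to_m3_per_s",
    "m3_per_s_to_ul_per_h",
    "wall_shear",
    "shear_at_height",
    "residence_time_min",
    "media_exchange_rate",
    "culture_area_cm2",
    "seeding_density",
    "report",
]

_S_PER_H = 3600.0
_M3_PER_UL = 1e-9


def ul_per_h_to_m3_per_s(q_ul_h: float) -> float:
    """Convert a flow rate from µl/h to m³/s."""
    return q_ul_h * _M3_PER_UL / _S_PER_H


def m3_per_s_to_ul_per_h(q_m3_s: float) -> float:
    """Convert a flow rate from m³/s to µl/h."""
    return q_m3_s / _M3_PER_UL * _S_PER_H


@dataclass(frozen=True)
class ChamberGeometry:
    """Culture-chamber dimensions in metres.

    ``width`` is across the flow, ``length`` along it, ``height`` the gap
    between culture surface and lid.  ``recess`` records how far the
    culture plane sits below the inlet/outlet channels (informational; the
    analytical model uses the full gap).
    """

    width: float = 13e-3
    length: float = 4e-3
    height: float = 450e-6
    recess: float = 120e-6

    def __post_init__(self) -> None:
        for name in ("width", "length", "height", "recess"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def volume_m3(self) -> float:
        return self.width * self.length * self.height

    @property
    def area_m2(self) -> float:
        return self.width * self.length


@dataclass(frozen=True)
class FluidProperties:
    """Culture medium treated as water at 37 °C."""

    viscosity: float = 6.96e-4  # Pa·s
    density: float = 993.2  # kg/m³

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if not self.density > 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class PerfusionConditions:
    """Flow rate plus geometry and fluid; defaults are the bench settings."""

    flow_rate: float = ul_per_h_to_m3_per_s(300.0)  # m³/s
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow rate must be non-negative")


def wall_shear(cond: PerfusionConditions) -> float:
    """Wall shear stress tau_w = 6 mu Q / (h² w), in Pa."""
    g = cond.geometry
    return 6.0 * cond.fluid.viscosity * cond.flow_rate / (g.height**2 * g.width)


def shear_at_height(cond: PerfusionConditions, z: float) -> float:
    """Shear-stress magnitude at height ``z`` (m) above the culture plane.

    Linear decay of the plane-Poiseuille profile: tau_w at the wall, zero
    at mid-gap, returned as a magnitude throughout.
    """
    h = cond.geometry.height
    if not 0 <= z <= h:
        raise ValueError(f"height z must lie in [0, {h}], got {z}")
    return wall_shear(cond) * abs(1.0 - 2.0 * z / h)


def residence_time_min(cond: PerfusionConditions) -> float:
    """Mean residence time V/Q of medium in the chamber, in minutes."""
    if cond.flow_rate <= 0:
        raise ValueError("residence time requires a positive flow rate")
    return cond.geometry.volume_m3 / cond.flow_rate / 60.0


def media_exchange_rate(cond: PerfusionConditions) -> float:
    """Medium replaced per day and per culture area, in ml·day⁻¹·cm⁻²."""
    ml_per_day = cond.flow_rate / _M3_PER_UL * 1e-3 * _S_PER_H * 24.0
    return ml_per_day / (cond.geometry.area_m2 * 1e4)


def culture_area_cm2(geom: ChamberGeometry) -> float:
    """Culture area w x l in cm²."""
    return geom.area_m2 * 1e4


def seeding_density(n_cells: float, geom: ChamberGeometry) -> float:
    """Seeding density in cells/cm² for ``n_cells`` over the culture area."""
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    return n_cells / culture_area_cm2(geom)


def report(cond: PerfusionConditions, z: float = 15e-6) -> dict[str, float]:
    """All chamber quantities as a flat dict (JSON-friendly)."""
    return {
        "flow_ul_h": m3_per_s_to_ul_per_h(cond.flow_rate),
        "wall_shear_Pa": wall_shear(cond),
        f"shear_at_{z * 1e6:g}um_Pa": shear_at_height(cond, z),
        "residence_min": residence_time_min(cond),
        "exchange_ml_day_cm2": media_exchange_rate(cond),
        "area_cm2": culture_area_cm2(cond.geometry),
    }
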