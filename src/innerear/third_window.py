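"""Pathology-parameterized third-window impedances.

Three fluid pathways connect the inner ear to the cerebrospinal fluid
besides the oval and round windows:

* the semicircular canal with a possible dehiscence (SSCD), modeled as a
  hole of area ``A_D`` in the middle of the canal duct — the two 6 mm canal
  limbs (cross-section tapering 2 → 1 mm²) act in parallel and terminate on
  the hole, a 1 mm tube with a 2:1 elliptic cross-section.  As the hole
  grows, each limb shortens by the hole's semi-major axis.  An intact canal
  is a blocked branch; the theoretical "no impedance" bound shorts the
  vestibule to the CSF node.
* the vestibular aqueduct: a 2.3 mm narrow tube (nominal diameter 0.3 mm)
  in series with a 5.7 mm horn opening to an ellipse of radii
  3.25 × 0.27 mm.  Size variation scales the narrow-tube diameter; the
  horn's entry area follows the tube area, its end opening is unchanged.
* the cochlear aqueduct: a 10 mm tube of 0.15 mm diameter, entering the
  scala tympani between the basilar membrane and the round window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import (
    FluidProperties,
    ImpedanceElement,
    combine,
    tapered_or_horn_impedance,
    tube_impedance,
)

__all__ = [
    "PathologyConfig",
    "sscd_impedance",
    "va_impedance",
    "ca_impedance",
    "INTACT",
    "NO_IMPEDANCE",
]

INTACT = "intact"
NO_IMPEDANCE = "no_imp"

# Anatomy of the semicircular canal and its dehiscence (see data/model.yaml
# for the same values in the constants file; kept here as defaults so the
# functions are usable standalone).
_SSC_DEFAULTS = {
    "duct_length_mm": 6.0,
    "area_near_mm2": 2.0,
    "area_mid_mm2": 1.0,
    "hole_length_mm": 1.0,
    "hole_aspect": 2.0,
}
_VA_DEFAULTS = {
    "tube": {"length_mm": 2.3, "diameter_mm": 0.3},
    "horn": {"length_mm": 5.7, "end_radius_a_mm": 3.25, "end_radius_b_mm": 0.27},
    "step_mm": 0.1,
}
_CA_DEFAULTS = {"length_mm": 10.0, "diameter_mm": 0.15}

_MM = 1e-3
_MM2 = 1e-6


@dataclass(frozen=True)
class PathologyConfig:
    """A third-window / reinforcement scenario.

    Parameters
    ----------
    sscd_area_mm2 : float or str
        Dehiscence area in mm² (0 < A_D <= 6), or ``"intact"`` (no hole,
        canal branch blocked) or ``"no_imp"`` (canal branch an ideal short
        to the CSF node — the theoretical upper bound on the SSCD effect).
    va_scale : float
        Diameter scale of the vestibular-aqueduct narrow tube
        (1.0 = nominal 0.3 mm; clinical sweep range 0.5–2).
    ow_stiffness_factor, rw_stiffness_factor : float
        Multipliers (>= 1) on the oval-window (in Z_ME) and round-window
        (in Z_RW) stiffness coefficients; surgical reinforcement.
    """

    sscd_area_mm2: float | str = INTACT
    va_scale: float = 1.0
    ow_stiffness_factor: float = 1.0
    rw_stiffness_factor: float = 1.0

    def __post_init__(self) -> None:
        a = self.sscd_area_mm2
        if isinstance(a, str):
            if a not in (INTACT, NO_IMPEDANCE):
                raise ValueError(f"unknown symbolic dehiscence state {a!r}")
        else:
            if not 0.0 <= float(a) <= 6.0:
                raise ValueError(f"dehiscence area must be in [0, 6] mm², got {a}")
        if not 0.25 <= self.va_scale <= 4.0:
            raise ValueError(f"va_scale must be in [0.25, 4], got {self.va_scale}")
        for f in (self.ow_stiffness_factor, self.rw_stiffness_factor):
            if f < 1.0:
                raise ValueError(f"stiffness factors must be >= 1, got {f}")


def sscd_impedance(
    area_mm2: float | str,
    fluid: FluidProperties = FluidProperties(),
    geom: dict | None = None,
) -> ImpedanceElement:
    """Impedance of the (possibly dehiscent) semicircular-canal branch.

    ``area_mm2`` is the dehiscence area in mm², or one of the symbolic
    states ``"intact"`` / ``"no_imp"``.
    """
    g = {**_SSC_DEFAULTS, **(geom or {})}
    if area_mm2 == INTACT:
        return ImpedanceElement(name="Z_SSC", blocked=True)
    if area_mm2 == NO_IMPEDANCE:
        return ImpedanceElement(name="Z_SSC")  # ideal short
    area = float(area_mm2)
    if area < 0:
        raise ValueError(f"dehiscence area must be non-negative, got {area}")
    if area == 0.0:
        return ImpedanceElement(name="Z_SSC", blocked=True)

    a_d = area * _MM2  # m²
    # dehiscence ellipse: semi-major = aspect * semi-minor, A = pi*a*b
    aspect = g["hole_aspect"]
    semi_minor = np.sqrt(a_d / (np.pi * aspect))
    semi_major = aspect * semi_minor
    hole_len = g["hole_length_mm"] * _MM
    hole_mass = fluid.density * hole_len / a_d
    r_eq4 = (a_d / np.pi) ** 2
    hole_res = 8.0 * fluid.dynamic_viscosity * hole_len / (np.pi * r_eq4)
    hole = ImpedanceElement(name="SSCD_hole", mass=hole_mass, resistance=hole_res)

    # each canal limb: area tapers linearly 2 -> 1 mm² over the original
    # 6 mm; the limb is shortened at the mid-canal end by the hole's
    # semi-major axis
    l_full = g["duct_length_mm"] * _MM
    a_near = g["area_near_mm2"] * _MM2
    a_mid = g["area_mid_mm2"] * _MM2
    l_duct = l_full - semi_major
    if l_duct <= 0:
        raise ValueError(f"dehiscence of {area} mm² consumes the whole canal limb")

    def profile(l: float) -> float:
        return a_near + (a_mid - a_near) * l / l_full

    limb = tapered_or_horn_impedance(l_duct, profile, step=0.1 * _MM, fluid=fluid,
                                     name="SSC_limb")
    limbs = combine([limb, limb], "parallel", name="SSC_limbs")
    return combine([limbs, hole], "series", name="Z_SSC")


def va_impedance(
    diameter_scale: float = 1.0,
    fluid: FluidProperties = FluidProperties(),
    geom: dict | None = None,
) -> ImpedanceElement:
    """Impedance of the vestibular aqueduct (narrow tube + horn).

    The horn's area profile is exponential between its entry (equal to the
    scaled narrow-tube area) and its fixed elliptic end opening — the
    canonical acoustic-horn flare; the constants file records the discretization
    step.
    """
    if diameter_scale <= 0:
        raise ValueError(f"diameter scale must be positive, got {diameter_scale}")
    g = {**_VA_DEFAULTS, **(geom or {})}
    r_tube = 0.5 * g["tube"]["diameter_mm"] * _MM * diameter_scale
    tube = tube_impedance(g["tube"]["length_mm"] * _MM, r_tube, fluid, name="VA_tube")

    a_entry = np.pi * r_tube**2
    a_end = np.pi * (g["horn"]["end_radius_a_mm"] * _MM) * (g["horn"]["end_radius_b_mm"] * _MM)
    horn_len = g["horn"]["length_mm"] * _MM
    ratio = a_end / a_entry

    def profile(l: float) -> float:
        return a_entry * ratio ** (l / horn_len)

    horn = tapered_or_horn_impedance(horn_len, profile, step=g["step_mm"] * _MM,
                                     fluid=fluid, name="VA_horn")
    return combine([tube, horn], "series", name="Z_VA")


def ca_impedance(
    fluid: FluidProperties = FluidProperties(),
    geom: dict | None = None,
) -> ImpedanceElement:
    """Impedance of the cochlear aqueduct (straight narrow tube)."""
    g = {**_CA_DEFAULTS, **(geom or {})}
    r = 0.5 * g["diameter_mm"] * _MM
    el = tube_impedance(g["length_mm"] * _MM, r, fluid, name="Z_CA")
    return el
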