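"""Lumped acoustic impedance elements.

An acoustic impedance relates sound pressure to volume velocity,
``Z = p / U`` in Pa·s·m⁻³.  Elements are built either from lumped
coefficients,

    Z(ω) = jω·M + R + K/(jω),

with acoustic mass ``M`` (kg·m⁻⁴), resistance ``R`` (Pa·s·m⁻³) and
stiffness ``K`` (Pa·m⁻³), or from duct geometry: a straight tube of
length ``L`` and radius ``r`` filled with a viscous fluid has

    M = ρ·L/(π r²)          (fluid column inertia)
    R = 8·η·L/(π r⁴)        (Poiseuille friction)

Tapered ducts and horns are integrated as series chains of short tube
sections evaluated at the section's average cross-section area.  Elliptic
cross-sections use the exact area for the mass term and the
equivalent-circular-radius ``r_eq = sqrt(A/π)`` for the resistance term.

An infinite (blocked) element is represented by an explicit flag, never
by a large float; the network layer drops blocked branches.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "ImpedanceElement",
    "TabulatedImpedance",
    "eval_impedance",
    "tube_impedance",
    "tapered_or_horn_impedance",
    "combine",
    "BlockedElementError",
]


class BlockedElementError(ValueError):
    """Raised when a blocked (infinite) element is evaluated numerically."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid filling the ducts (perilymph/CSF treated as water)."""

    density: float = 1000.0  # kg·m⁻³
    dynamic_viscosity: float = 1.0e-3  # Pa·s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass(frozen=True)
class ImpedanceElement:
    """A lumped acoustic impedance, possibly composite.

    Either a leaf carrying mass/resistance/stiffness coefficients, or a
    series/parallel combination of sub-elements.  Elements are immutable;
    derived elements (scaled stiffness, combinations) are new objects.
    """

    name: str = ""
    mass: float = 0.0
    resistance: float = 0.0
    stiffness: float = 0.0
    blocked: bool = False
    parts: tuple["ImpedanceElement", ...] = ()
    mode: str | None = None  # "series" | "parallel" for composites

    def __post_init__(self) -> None:
        if self.parts and self.mode not in ("series", "parallel"):
            raise ValueError("composite element needs mode 'series' or 'parallel'")

    @property
    def is_blocked(self) -> bool:
        """True if the element passes no flow at any frequency."""
        if self.blocked:
            return True
        if self.mode == "series":
            return any(p.is_blocked for p in self.parts)
        if self.mode == "parallel":
            return bool(self.parts) and all(p.is_blocked for p in self.parts)
        return False

    @property
    def is_zero(self) -> bool:
        """True if the element is an ideal short (identically zero impedance)."""
        if self.is_blocked:
            return False
        if self.parts:
            if self.mode == "series":
                return all(p.is_zero for p in self.parts)
            return any(p.is_zero for p in self.parts if not p.is_blocked)
        return self.mass == 0.0 and self.resistance == 0.0 and self.stiffness == 0.0

    def __call__(self, freq) -> np.ndarray:
        return eval_impedance(self, freq)

    def with_stiffness_factor(self, factor: float, name: str | None = None) -> "ImpedanceElement":
        """Return a copy with the stiffness coefficient multiplied by ``factor``."""
        if factor < 1:
            raise ValueError("reinforcement factor must be >= 1")
        if self.parts:
            raise ValueError("stiffness scaling is defined for leaf elements only")
        return ImpedanceElement(
            name=name or self.name,
            mass=self.mass,
            resistance=self.resistance,
            stiffness=self.stiffness * factor,
            blocked=self.blocked,
        )

    def total_coefficients(self) -> tuple[float, float, float]:
        """(mass, resistance, stiffness) of a leaf or pure-series tree."""
        if self.is_blocked:
            raise BlockedElementError(f"element {self.name!r} is blocked")
        if not self.parts:
            return (self.mass, self.resistance, self.stiffness)
        if self.mode != "series":
            raise ValueError("coefficients are only additive over series trees")
        m = self.mass
        r = self.resistance
        k = self.stiffness
        for p in self.parts:
            pm, pr, pk = p.total_coefficients()
            m, r, k = m + pm, r + pr, k + pk
        return (m, r, k)


class TabulatedImpedance:
    """Impedance defined by a numeric function of frequency.

    Used for loads derived from a solved network (e.g. driving-point
    impedances terminating the scala ducts).  Quacks like an
    :class:`ImpedanceElement` for evaluation purposes.
    """

    is_blocked = False
    is_zero = False
    parts: tuple = ()
    mode = None

    def __init__(self, name: str, func: Callable[[np.ndarray], np.ndarray]):
        self.name = name
        self._func = func

    def __call__(self, freq) -> np.ndarray:
        return eval_impedance(self, freq)


def _as_freq(freq) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError(f"frequency must be finite and positive, got {freq!r}")
    return f


def eval_impedance(element, freq) -> np.ndarray:
    """Evaluate a (possibly composite) element at frequency ``freq`` in Hz.

    Returns a complex array broadcast to the shape of ``freq``.
    """
    f = _as_freq(freq)
    if element.is_blocked:
        raise BlockedElementError(
            f"element {element.name!r} is blocked (infinite impedance); "
            "blocked branches must be dropped, not evaluated"
        )
    if isinstance(element, TabulatedImpedance):
        return np.asarray(element._func(f), dtype=complex)
    jw = 2j * np.pi * f
    if not element.parts:
        return jw * element.mass + element.resistance + element.stiffness / jw
    z_own = jw * element.mass + element.resistance + element.stiffness / jw
    if element.mode == "series":
        return z_own + sum(eval_impedance(p, f) for p in element.parts)
    # parallel: blocked sub-branches carry no flow and are absorbed
    live = [p for p in element.parts if not p.is_blocked]
    y = sum(1.0 / eval_impedance(p, f) for p in live)
    return z_own + 1.0 / y


def tube_impedance(
    length: float,
    radius: float,
    fluid: FluidProperties = FluidProperties(),
    name: str = "tube",
) -> ImpedanceElement:
    """Straight-tube acoustic impedance: column inertia + Poiseuille friction."""
    if radius <= 0:
        raise ValueError(f"tube radius must be positive, got {radius}")
    if length < 0:
        raise ValueError(f"tube length must be non-negative, got {length}")
    area = np.pi * radius**2
    mass = fluid.density * length / area
    resistance = 8.0 * fluid.dynamic_viscosity * length / (np.pi * radius**4)
    return ImpedanceElement(name=name, mass=mass, resistance=resistance)


def tapered_or_horn_impedance(
    length: float,
    area_profile: Callable[[float], float],
    step: float,
    fluid: FluidProperties = FluidProperties(),
    name: str = "horn",
) -> ImpedanceElement:
    """Impedance of a duct with varying cross-section.

    The duct is discretized into axial steps of width ``step``; each step
    contributes the impedance of a straight tube evaluated at the average
    of its end areas.  ``area_profile(l)`` must return the cross-section
    area in m² for axial position ``l`` in [0, length].
    """
    if step <= 0 or step > length:
        raise ValueError(f"step must be in (0, length], got step={step}, length={length}")
    edges = np.arange(0.0, length, step).tolist() + [length]
    mass = 0.0
    resistance = 0.0
    for l0, l1 in zip(edges[:-1], edges[1:]):
        a0, a1 = area_profile(l0), area_profile(l1)
        if a0 <= 0 or a1 <= 0:
            raise ValueError("area profile must be strictly positive over the duct")
        a_avg = 0.5 * (a0 + a1)
        dl = l1 - l0
        mass += fluid.density * dl / a_avg
        r_eq4 = (a_avg / np.pi) ** 2  # r_eq = sqrt(A/pi), so r_eq^4 = (A/pi)^2
        resistance += 8.0 * fluid.dynamic_viscosity * dl / (np.pi * r_eq4)
    return ImpedanceElement(name=name, mass=mass, resistance=resistance)


def combine(
    elements: Sequence[ImpedanceElement],
    mode: str,
    name: str = "",
) -> ImpedanceElement:
    """Series or parallel combination of impedance elements.

    Series: pointwise sum; a blocked member blocks the combination.
    Parallel: reciprocal of summed reciprocals; blocked members are absorbed.
    """
    if mode not in ("series", "parallel"):
        raise ValueError(f"mode must be 'series' or 'parallel', got {mode!r}")
    elements = tuple(elements)
    if not elements:
        raise ValueError("cannot combine an empty list of elements")
    if len(elements) == 1:
        return elements[0]
    blocked = False
    if mode == "series" and any(e.is_blocked for e in elements):
        blocked = True
    if mode == "parallel" and all(e.is_blocked for e in elements):
        blocked = True
    return ImpedanceElement(
        name=name or f"{mode}({', '.join(e.name for e in elements)})",
        parts=elements,
        mode=mode,
        blocked=blocked,
    )
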