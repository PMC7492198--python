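"""Parameterized coiled-cochlea geometry and bone-wave compression sources.

The two scalae are coiled ducts of 2.5 turns discretized into 180 sections
of 5° each.  The coil radius shrinks linearly in winding angle from 5 mm at
the base to 1.6 mm at the apex; cross-sections are half-elliptic with the
stated base/apex widths and heights, linear in angle.  The vestibule is a
straight elliptic duct (5.8 mm, radii 1.55 × 2.45 mm) running from the oval
window to the openings of the semicircular canals and the vestibular
aqueduct.

Bone-conducted excitation travels as a longitudinal one-dimensional wave of
speed ``c``: every bony point shares one acceleration amplitude (attenuation
is neglected over the ~1 cm model span) but carries the phase
``exp(-jω·s/c)`` of its position ``s`` projected on the propagation
direction.  Because the inner-ear fluid is incompressible, the rate of
change of each section's volume — driven by the *difference* of the wall
displacements at its two boundaries — is emitted as a volume-velocity
source, and the per-section sources are condensed onto the lumped network
ports by a current divider over the duct impedances and terminating loads.

The in-plane layout is schematic: the spiral lies in the x-y plane with its
base (and the round window) on the +x axis; the oval window sits a few
millimetres further out along +x, and the vestibule continues from the oval
window away from the cochlea toward the canal and aqueduct openings.  The
default wave direction is along this axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import eval_impedance

__all__ = [
    "CochlearGeometry",
    "BoneWave",
    "ScalaSections",
    "SectionTable",
    "CompressionSections",
    "build_sections",
    "compression_sources",
    "lump_compression",
    "vestibule_compression",
]

_MM = 1e-3


@dataclass(frozen=True)
class CochlearGeometry:
    """Dimensions of the coiled scalae and the vestibule (mm units in names)."""

    turns: float = 2.5
    n_sections: int = 180
    outer_radius_base_mm: float = 5.0
    outer_radius_apex_mm: float = 1.6
    # scala vestibuli half-elliptic cross-section, base -> apex
    sv_width_base_mm: float = 1.8
    sv_height_base_mm: float = 1.2
    sv_width_apex_mm: float = 1.6
    sv_height_apex_mm: float = 0.6
    # scala tympani
    st_width_base_mm: float = 2.5
    st_height_base_mm: float = 1.4
    st_width_apex_mm: float = 1.6
    st_height_apex_mm: float = 0.6
    # vestibule
    vestibule_length_mm: float = 5.8
    vestibule_radius_a_mm: float = 1.55
    vestibule_radius_b_mm: float = 2.45
    window_offset_mm: float = 3.0
    fluid_density: float = 1000.0

    @classmethod
    def from_constants(cls, constants: dict) -> "CochlearGeometry":
        g = constants["geometry"]
        c = g["cochlea"]
        sv, st, v = c["scala_vestibuli"], c["scala_tympani"], g["vestibule"]
        return cls(
            turns=c["turns"],
            n_sections=c["n_sections"],
            outer_radius_base_mm=c["outer_radius_base_mm"],
            outer_radius_apex_mm=c["outer_radius_apex_mm"],
            sv_width_base_mm=sv["width_base_mm"],
            sv_height_base_mm=sv["height_base_mm"],
            sv_width_apex_mm=sv["width_apex_mm"],
            sv_height_apex_mm=sv["height_apex_mm"],
            st_width_base_mm=st["width_base_mm"],
            st_height_base_mm=st["height_base_mm"],
            st_width_apex_mm=st["width_apex_mm"],
            st_height_apex_mm=st["height_apex_mm"],
            vestibule_length_mm=v["length_mm"],
            vestibule_radius_a_mm=v["radius_a_mm"],
            vestibule_radius_b_mm=v["radius_b_mm"],
            window_offset_mm=v.get("window_offset_mm", 3.0),
            fluid_density=constants["fluid"]["density"],
        )

    def __post_init__(self) -> None:
        if self.n_sections < 1 or self.turns <= 0:
            raise ValueError("turns and n_sections must be positive")
        for w in ("sv", "st"):
            if getattr(self, f"{w}_width_apex_mm") > getattr(self, f"{w}_width_base_mm"):
                raise ValueError("scala widths must be non-increasing base -> apex")

    # --- schematic frame anchors (m) -------------------------------------
    @property
    def total_angle(self) -> float:
        return self.turns * 2.0 * np.pi

    @property
    def base_xy(self) -> np.ndarray:
        return np.array([self.outer_radius_base_mm * _MM, 0.0])

    @property
    def apex_xy(self) -> np.ndarray:
        th = self.total_angle
        r = self.outer_radius_apex_mm * _MM
        return np.array([r * np.cos(th), r * np.sin(th)])

    def _centerline_radius_base(self, width_base_mm: float) -> float:
        return (self.outer_radius_base_mm - 0.5 * width_base_mm) * _MM

    @property
    def sv_base_xy(self) -> np.ndarray:
        """Scala-vestibuli centerline at the base (duct entrance)."""
        return np.array([self._centerline_radius_base(self.sv_width_base_mm), 0.0])

    @property
    def st_base_xy(self) -> np.ndarray:
        """Scala-tympani centerline at the base — the round-window region."""
        return np.array([self._centerline_radius_base(self.st_width_base_mm), 0.0])

    @property
    def ow_xy(self) -> np.ndarray:
        """Oval window: offset from the round-window region along +x.

        Both windows sit at the cochlear base; the stapes footplate is a
        few millimetres from the round window along the model axis.
        """
        return self.st_base_xy + np.array([self.window_offset_mm * _MM, 0.0])

    @property
    def vestibule_far_xy(self) -> np.ndarray:
        """Far (canal/aqueduct) end of the vestibule, away from the cochlea."""
        return self.ow_xy + np.array([self.vestibule_length_mm * _MM, 0.0])

    @property
    def vestibule_area(self) -> float:
        return np.pi * self.vestibule_radius_a_mm * _MM * self.vestibule_radius_b_mm * _MM

    def half_elliptic_area(self, width_m: float, height_m: float) -> float:
        """Area of a half-ellipse of full width ``w`` and height ``h``."""
        return 0.5 * np.pi * (width_m / 2.0) * height_m


@dataclass(frozen=True)
class BoneWave:
    """Longitudinal one-dimensional wave in the skull bone.

    ``acceleration`` is the common amplitude of all bony points (m·s⁻²);
    ``speed`` the propagation speed (m·s⁻¹); ``direction`` a unit vector in
    the model plane.  ``speed = inf`` is allowed and means rigid-body motion
    (all phases equal one).
    """

    acceleration: float = 1.0
    speed: float = 300.0
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError(f"wave speed must be positive, got {self.speed}")
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("wave direction must be a nonzero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    def axial(self, xy: np.ndarray) -> np.ndarray:
        """Project positions (…, 2) onto the propagation axis (m)."""
        return np.asarray(xy, float) @ np.asarray(self.direction)

    def phase(self, s, freq) -> np.ndarray:
        """exp(-jω s/c) broadcast over axial positions ``s`` and ``freq``."""
        s = np.atleast_1d(np.asarray(s, float))
        f = np.atleast_1d(np.asarray(freq, float))
        if np.isinf(self.speed):
            return np.ones((s.size, f.size), complex)
        w = 2.0 * np.pi * f
        return np.exp(-1j * np.outer(s, w) / self.speed)

    def displacement(self, s, freq) -> np.ndarray:
        """Complex bone displacement along the wave axis at axial position(s).

        Amplitude ``a/ω²`` (the common acceleration divided by ω²), phased by
        position.  Shape (len(s), len(freq)).
        """
        f = np.atleast_1d(np.asarray(freq, float))
        w = 2.0 * np.pi * f
        return (self.acceleration / w**2) * self.phase(s, f)


@dataclass
class ScalaSections:
    """Per-section discretization of one scala's coiled duct (SI units).

    Positions lie on the duct *centerline* spiral: the stated outer coil
    radius minus half the duct width at that angle — the path the fluid
    column actually follows, which is what the per-section duct masses
    ``ρ·Δl/A`` must integrate along.
    """

    theta_mid: np.ndarray        # winding angle at section midpoints (rad)
    mid_xy: np.ndarray           # (N, 2) centerline midpoint positions (m)
    boundary_xy: np.ndarray      # (N+1, 2) centerline boundary positions (m)
    arc_length: np.ndarray       # (N,) section arc lengths (m)
    area: np.ndarray             # (N,) half-elliptic cross-areas (m²)
    dz_mass: np.ndarray          # (N,) per-section duct acoustic mass (kg·m⁻⁴)

    def __len__(self) -> int:
        return len(self.arc_length)

    @property
    def volume(self) -> np.ndarray:
        return self.arc_length * self.area


@dataclass
class SectionTable:
    """The two scalae, discretized into equal-angle sections."""

    sv: ScalaSections
    st: ScalaSections
    geometry: CochlearGeometry = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.sv)

    # convenience accessors used throughout
    @property
    def area_sv(self):
        return self.sv.area

    @property
    def area_st(self):
        return self.st.area

    @property
    def dz_mass_sv(self):
        return self.sv.dz_mass

    @property
    def dz_mass_st(self):
        return self.st.dz_mass

    @property
    def volume_sv(self):
        return self.sv.volume

    @property
    def volume_st(self):
        return self.st.volume

    def to_frame(self) -> pd.DataFrame:
        """Section table for CSV export / inspection."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "angle_deg": np.degrees(self.sv.theta_mid),
                "sv_x_mm": self.sv.mid_xy[:, 0] / _MM,
                "sv_y_mm": self.sv.mid_xy[:, 1] / _MM,
                "sv_arc_mm": self.sv.arc_length / _MM,
                "sv_area_mm2": self.sv.area / _MM**2,
                "st_arc_mm": self.st.arc_length / _MM,
                "st_area_mm2": self.st.area / _MM**2,
            }
        )


def _scala_sections(geom: CochlearGeometry, n: int, width_base: float,
                    width_apex: float, height_base: float,
                    height_apex: float) -> ScalaSections:
    theta_total = geom.total_angle
    edges = np.linspace(0.0, theta_total, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    def lin(b, a, th):
        return (b + (th / theta_total) * (a - b)) * _MM

    def radius(th):
        outer = lin(geom.outer_radius_base_mm, geom.outer_radius_apex_mm, th)
        return outer - 0.5 * lin(width_base, width_apex, th)

    def xy(th):
        r = radius(th)
        return np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)

    slope = (radius(theta_total) - radius(0.0)) / theta_total
    arc = np.sqrt(radius(mids) ** 2 + slope**2) * np.diff(edges)
    area = np.array([
        geom.half_elliptic_area(w, h)
        for w, h in zip(lin(width_base, width_apex, mids),
                        lin(height_base, height_apex, mids))
    ])
    return ScalaSections(
        theta_mid=mids,
        mid_xy=xy(mids),
        boundary_xy=xy(edges),
        arc_length=arc,
        area=area,
        dz_mass=geom.fluid_density * arc / area,
    )


def build_sections(geom: CochlearGeometry, n_sections: int | None = None) -> SectionTable:
    """Discretize the coiled scalae into equal-angle sections.

    Centerline radius, widths and heights are linear in winding angle; each
    section's area is evaluated at its angular midpoint and its boundary
    positions lie on the centerline spiral.
    """
    n = int(n_sections or geom.n_sections)
    sv = _scala_sections(geom, n, geom.sv_width_base_mm, geom.sv_width_apex_mm,
                         geom.sv_height_base_mm, geom.sv_height_apex_mm)
    st = _scala_sections(geom, n, geom.st_width_base_mm, geom.st_width_apex_mm,
                         geom.st_height_base_mm, geom.st_height_apex_mm)
    return SectionTable(sv=sv, st=st, geometry=geom)


@dataclass
class CompressionSections:
    """Per-section compression volume-velocity sources for one wave/grid."""

    freq: np.ndarray             # (F,)
    du_sv: np.ndarray            # (N, F) complex volume-velocity sources (m³/s)
    du_st: np.ndarray            # (N, F)
    dz_mass_sv: np.ndarray       # (N,) section duct masses (kg·m⁻⁴)
    dz_mass_st: np.ndarray


def compression_sources(
    sections: SectionTable,
    wave: BoneWave,
    freq,
) -> CompressionSections:
    """Per-section compression sources from the wave's phase differences.

    Each section emits ``ΔU = -jω·A·(ξ_far - ξ_near)`` where ξ is the
    complex bone displacement along the wave axis at the section's two
    boundary positions (projected on the propagation direction): the rate
    of section-volume change, expelled into the incompressible fluid.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    jw = 2j * np.pi * f[None, :]

    def du(scala: ScalaSections) -> np.ndarray:
        xi = wave.displacement(wave.axial(scala.boundary_xy), f)  # (N+1, F)
        return -jw * scala.area[:, None] * (xi[1:, :] - xi[:-1, :])

    du_sv = du(sections.sv)
    du_st = du(sections.st)
    return CompressionSections(
        freq=f,
        du_sv=du_sv,
        du_st=du_st,
        dz_mass_sv=sections.dz_mass_sv,
        dz_mass_st=sections.dz_mass_st,
    )


def _load_z(load, f: np.ndarray) -> np.ndarray | None:
    """Evaluate a terminating load; None signals a blocked (infinite) load.

    Accepts an impedance element, a precomputed complex spectrum on ``f``,
    or ``None`` for an ideal short.
    """
    if load is None:
        return np.zeros_like(f, dtype=complex)
    if isinstance(load, np.ndarray):
        if load.shape != f.shape:
            raise ValueError("precomputed load spectrum must match the frequency grid")
        return load.astype(complex)
    if getattr(load, "is_blocked", False):
        return None
    return eval_impedance(load, f)


def lump_compression(
    du: np.ndarray,
    dz_mass: np.ndarray,
    basal_load,
    apical_load,
    freq,
) -> np.ndarray:
    """Condense per-section sources into the equivalent basal-port source.

    Each section's ΔU splits between the basal and apical paths by the
    current divider of cumulative duct impedance plus terminating load on
    either side (half of the section's own duct mass is assigned to each
    side); the basal shares sum to the port source.  A blocked load sends
    everything the other way.

    Parameters
    ----------
    du : (N, F) complex per-section sources;  dz_mass : (N,) section masses.
    basal_load, apical_load : impedance elements terminating the duct
        (``None`` = ideal short), evaluated on ``freq``.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    du = np.atleast_2d(du)
    dz = np.asarray(dz_mass, float)
    if du.shape != (dz.size, f.size):
        raise ValueError(f"shape mismatch: du {du.shape}, expected ({dz.size}, {f.size})")
    jw = 2j * np.pi * f[None, :]
    cum = np.concatenate([[0.0], np.cumsum(dz)])
    mass_basal = cum[:-1] + 0.5 * dz          # duct mass basal of each injection
    mass_apical = cum[-1] - cum[1:] + 0.5 * dz
    zb_load = _load_z(basal_load, f)
    za_load = _load_z(apical_load, f)
    if zb_load is None and za_load is None:
        raise ValueError("both terminating loads are blocked; sources have no path")
    if zb_load is None:
        return np.zeros(f.size, complex)      # basal path blocked: nothing reaches the port
    if za_load is None:
        return du.sum(axis=0)                 # apical blocked: everything goes basal
    zb = jw * mass_basal[:, None] + zb_load[None, :]
    za = jw * mass_apical[:, None] + za_load[None, :]
    frac_basal = za / (zb + za)
    return (du * frac_basal).sum(axis=0)


def vestibule_compression(wave: BoneWave, freq, geom: CochlearGeometry) -> np.ndarray:
    """Compression volume-velocity source of the vestibule space.

    Single-segment volume change rate between the vestibule's two ends
    under the wave's phase gradient; shape (F,).
    """
    f = np.atleast_1d(np.asarray(freq, float))
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    s = wave.axial(np.stack([geom.ow_xy, geom.vestibule_far_xy]))
    xi = wave.displacement(s, f)  # (2, F)
    jw = 2j * np.pi * f
    return -jw * geom.vestibule_area * (xi[1, :] - xi[0, :])
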