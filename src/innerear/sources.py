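"""Excitation sources: wave-derived drives and literature-shaped stand-ins.

Six drives excite the network, solved one at a time by superposition:

================  =====================================================
contributor       sources it activates
================  =====================================================
``fluid_inertia``  series pressure sources P_V, P_SV, P_ST on the
                   vestibule and scala fluid columns (ρ·L_eff·a, phased
                   by the bone wave at each column's centroid)
``compression``    volume-velocity injections U_V, U_SV, U_ST from the
                   wave-driven volume change of the vestibule and the
                   coiled scala sections
``me_inertia``     stapes drive U_SF from ossicle inertia (band-pass
                   stand-in peaking at the 1–2 kHz middle-ear resonance)
``ear_canal``      stapes drive from the BC sound pressure in the open
                   ear canal, via the middle-ear transfer stand-in
``csf_pressure``   intracranial pressure P_IC at the CSF node, shared by
                   the vestibular-aqueduct and dehiscence terminations
``ac_drive``       air conduction: ear-canal pressure through the
                   middle-ear transfer stand-in and the 3.85 mm² stapes
                   footplate
================  =====================================================

All stapes-path drives (``ac_drive``, ``me_inertia``, ``ear_canal``) are
applied as a Thévenin pressure source in series with Z_ME, computed so the
stand-in curve equals the stapes volume velocity under the healthy
inner-ear load.  Under pathology the network re-loads the source, so
stiffening the oval window feeds back on stapes flow.  The absolute scale
of every stand-in curve is arbitrary; reported outputs are ratio/change
quantities that cancel it, or power sums evaluated where one contributor
dominates (checked at run time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .elements import eval_impedance
from .geometry import (
    BoneWave,
    CochlearGeometry,
    SectionTable,
    compression_sources,
    lump_compression,
    vestibule_compression,
)
from .network import SourceSpec

__all__ = [
    "BC_CONTRIBUTORS",
    "AC_TAG",
    "StandInCurve",
    "InertialSources",
    "inertial_pressure_sources",
    "fluid_inertia_spec",
    "compression_spec",
    "stapes_thevenin_spec",
    "ac_drive",
    "me_inertia_drive",
    "csf_pressure_source",
    "calibrate_contributors",
]

BC_CONTRIBUTORS = ("fluid_inertia", "compression", "me_inertia", "ear_canal",
                   "csf_pressure")
AC_TAG = "ac_drive"


@dataclass(frozen=True)
class StandInCurve:
    """Piecewise log-log-linear magnitude/phase spectrum with a scale factor.

    Magnitudes are dB re an arbitrary reference; interpolation is linear in
    log10(f) and exact at the breakpoints.  ``min_valid_hz`` marks curves
    (the CSF pressure) whose absolute levels are unusable below a limit;
    change/ratio quantities remain defined everywhere.
    """

    freq_hz: tuple[float, ...]
    mag_db: tuple[float, ...]
    phase_deg: tuple[float, ...]
    scale: float = 1.0
    min_valid_hz: float = 0.0
    name: str = ""

    @classmethod
    def from_config(cls, cfg: dict, name: str = "") -> "StandInCurve":
        return cls(
            freq_hz=tuple(float(x) for x in cfg["freq_hz"]),
            mag_db=tuple(float(x) for x in cfg["mag_db"]),
            phase_deg=tuple(float(x) for x in cfg["phase_deg"]),
            min_valid_hz=float(cfg.get("min_valid_hz", 0.0)),
            name=name,
        )

    def with_scale(self, scale: float) -> "StandInCurve":
        return replace(self, scale=scale)

    def __call__(self, freq) -> np.ndarray:
        f = np.atleast_1d(np.asarray(freq, float))
        lf = np.log10(f)
        lb = np.log10(np.asarray(self.freq_hz))
        mag = np.interp(lf, lb, np.asarray(self.mag_db))
        ph = np.interp(lf, lb, np.asarray(self.phase_deg))
        return self.scale * 10.0 ** (mag / 20.0) * np.exp(1j * np.radians(ph))

    def peak_frequency(self) -> float:
        """Frequency of the magnitude maximum (a breakpoint, by construction)."""
        return self.freq_hz[int(np.argmax(self.mag_db))]


# ---------------------------------------------------------------------------
# wave-derived sources
# ---------------------------------------------------------------------------

@dataclass
class InertialSources:
    """Fluid-inertia pressure sources and their network placement."""

    freq: np.ndarray
    p_v: np.ndarray    # vestibule column (total over both halves)
    p_sv: np.ndarray   # scala-vestibuli column
    p_st: np.ndarray   # scala-tympani column
    branch_pressure: dict[str, np.ndarray]


def inertial_pressure_sources(
    wave: BoneWave,
    geom: CochlearGeometry,
    freq,
    sections: SectionTable | None = None,
) -> InertialSources:
    """Pressure sources from fluid-column inertia, ``ρ·L_eff·a`` each.

    Each fluid column contributes the line integral ``ρ·a·∫φ(s)·ds`` of
    the phased inertial body force along its axial extent projected on the
    wave direction (for rigid-body motion, φ = 1, this is ρ·L_eff·a).  The
    vestibule column spans the oval window to the canal/aqueduct openings
    and is split over the two Z_V halves; the scala-vestibuli entrance
    branch Z_SV spans the oval window to the spiral base;
    the coiled-scala columns are integrated section by section and split
    over the basal/apical halves of their duct ladders, with the
    scala-tympani ladder traversed apex → base.  Because the assignment is
    the line integral of one conservative field, every closed fluid loop
    has zero net source at infinite wave speed and the oval-to-round-window
    drive equals ρ·a times the window separation, as it must for rigid-body
    motion.  The membrane branches (Z_ME, Z_RW, Z_C, Z_H) carry no source.
    """
    from .geometry import build_sections

    f = np.atleast_1d(np.asarray(freq, float))
    rho = geom.fluid_density
    a = wave.acceleration
    sections = sections if sections is not None else build_sections(geom)

    def column(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
        s0, s1 = wave.axial(p_from), wave.axial(p_to)
        mid = 0.5 * (s0 + s1)
        return rho * a * (s1 - s0) * wave.phase(mid, f)[0]

    def spiral(scala, lo: int, hi: int, reverse: bool = False) -> np.ndarray:
        """ρ·a·Σ Δs·φ over a section range of one coil (base → apex order)."""
        s = wave.axial(scala.boundary_xy)
        ds = s[lo + 1:hi + 1] - s[lo:hi]
        mid = 0.5 * (s[lo:hi] + s[lo + 1:hi + 1])
        phase = wave.phase(mid, f)
        total = rho * a * (ds[:, None] * phase).sum(axis=0)
        return -total if reverse else total

    ow, far = geom.ow_xy, geom.vestibule_far_xy
    mid_vest = 0.5 * (ow + far)
    n = len(sections)
    n2 = n // 2

    p_v = column(ow, far)
    p_sv = spiral(sections.sv, 0, n)
    p_st = spiral(sections.st, 0, n, reverse=True)
    branch_pressure = {
        "Z_V_ow": column(ow, mid_vest),
        "Z_V_v": column(mid_vest, far),
        "Z_SV": column(ow, geom.sv_base_xy),
        "Z_SVD_basal": spiral(sections.sv, 0, n2),
        "Z_SVD_apical": spiral(sections.sv, n2, n),
        "Z_STD_apical": spiral(sections.st, n2, n, reverse=True),
        "Z_STD_basal": spiral(sections.st, 0, n2, reverse=True),
    }
    return InertialSources(freq=f, p_v=p_v, p_sv=p_sv, p_st=p_st,
                           branch_pressure=branch_pressure)


def fluid_inertia_spec(wave: BoneWave, geom: CochlearGeometry, freq,
                       sections: SectionTable | None = None) -> SourceSpec:
    """The fluid-inertia contributor as a solver-ready source set."""
    src = inertial_pressure_sources(wave, geom, freq, sections)
    return SourceSpec(tag="fluid_inertia", branch_pressure=src.branch_pressure)


def compression_spec(
    wave: BoneWave,
    geom: CochlearGeometry,
    sections: SectionTable,
    freq,
    sv_loads: tuple,
    st_loads: tuple,
) -> SourceSpec:
    """The compression contributor: U_V, U_SV, U_ST injections.

    ``sv_loads`` / ``st_loads`` are (basal_load, apical_load) pairs
    terminating each scala duct, used by the current divider that condenses
    the per-section sources onto the duct port nodes.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    comp = compression_sources(sections, wave, f)
    u_sv = lump_compression(comp.du_sv, comp.dz_mass_sv, sv_loads[0], sv_loads[1], f)
    u_st = lump_compression(comp.du_st, comp.dz_mass_st, st_loads[0], st_loads[1], f)
    u_v = vestibule_compression(wave, f, geom)
    return SourceSpec(
        tag="compression",
        node_injection={"V": u_v, "SV_PORT": u_sv, "ST_PORT": u_st},
    )


# ---------------------------------------------------------------------------
# stapes-path drives (Thévenin behind Z_ME) and the CSF pressure
# ---------------------------------------------------------------------------

def stapes_thevenin_spec(tag: str, u_sf: np.ndarray, z_me, z_input, freq) -> SourceSpec:
    """Convert a target healthy-load stapes volume velocity into a source.

    ``z_input`` is the healthy inner-ear driving-point impedance at the
    oval window (Z_ME excluded).  The Thévenin pressure
    ``P = U_SF·(Z_ME + Z_in)`` reproduces ``u_sf`` through the Z_ME branch
    in the healthy ear and re-loads consistently under pathology.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    p_th = np.asarray(u_sf, complex) * (eval_impedance(z_me, f) + np.asarray(z_input, complex))
    return SourceSpec(tag=tag, branch_pressure={"Z_ME": p_th})


def ac_drive(
    ear_canal_pressure,
    freq,
    middle_ear: StandInCurve,
    footplate_area_m2: float = 3.85e-6,
) -> np.ndarray:
    """Stapes volume velocity U_SF for an ear-canal sound pressure (AC).

    ``middle_ear`` is the stand-in loaded middle-ear transfer function,
    stapes velocity per Pa at the tympanic membrane; the volume velocity is
    the velocity times the stapes footplate area.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    p_ec = np.broadcast_to(np.asarray(ear_canal_pressure, complex), f.shape)
    v_stapes = p_ec * middle_ear(f)
    return v_stapes * footplate_area_m2


def me_inertia_drive(
    wave: BoneWave,
    freq,
    curve: StandInCurve,
    footplate_area_m2: float = 3.85e-6,
) -> np.ndarray:
    """Stapes volume velocity from middle-ear ossicle inertia.

    The stand-in stapes-velocity curve is band-pass shaped around the
    ossicular resonance (its peak lies between 1 and 2 kHz) and scales with
    the bone acceleration.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    return wave.acceleration * curve(f) * footplate_area_m2


def csf_pressure_source(wave: BoneWave, freq, curve: StandInCurve) -> SourceSpec:
    """Intracranial pressure P_IC at the CSF node.

    One shared source terminates both the vestibular-aqueduct and
    dehiscence branches (the two openings are physically close).  Absolute
    contribution plots are meaningful only above ``curve.min_valid_hz``.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    p_ic = wave.acceleration * curve(f)
    return SourceSpec(tag="csf_pressure", branch_pressure={"P_IC": p_ic})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_contributors(
    raw_flows: dict[str, np.ndarray],
    freq,
    calibration: dict[str, dict],
    reference: str = "fluid_inertia",
) -> dict[str, float]:
    """Scale factors pinning each stand-in contributor to the reference.

    ``raw_flows`` maps contributor tag -> BM-flow spectrum computed with
    unit-scale curves in the healthy ear.  Each calibration entry
    ``{offset_db, at}`` requests that the contributor sit ``offset_db``
    relative to the reference (fluid inertia) at frequency ``at``
    (``"peak"`` = the contributor's own spectral maximum).  Scales multiply
    the stand-in curves; an infeasible request (zero raw flow at the
    anchor) is reported, never silently clipped.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    ref = np.abs(raw_flows[reference])
    scales = {reference: 1.0}
    for tag, flow in raw_flows.items():
        if tag == reference or tag not in calibration:
            scales.setdefault(tag, 1.0)
            continue
        spec = calibration[tag]
        at = spec.get("at", "peak")
        mag = np.abs(flow)
        idx = int(np.argmax(mag)) if at == "peak" else int(np.argmin(np.abs(f - float(at))))
        if mag[idx] == 0.0:
            raise ValueError(
                f"calibration of {tag!r} infeasible: zero BM flow at anchor "
                f"frequency {f[idx]:g} Hz"
            )
        target = ref[idx] * 10.0 ** (float(spec["offset_db"]) / 20.0)
        scales[tag] = target / mag[idx]
    return scales
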