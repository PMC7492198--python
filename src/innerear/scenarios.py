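"""End-to-end simulation scenarios: SSCD, vestibular-aqueduct size, window
reinforcement.

:class:`InnerEarModel` wires the pieces together: it loads the constants
and stand-in source curves, builds the coiled-scala sections, calibrates
the stand-in contributors against fluid inertia in the healthy ear, and
caches per-pathology solves.  The scenario functions compare a pathological
ear with a reference ear and report

* the AC threshold change (dB; AC drive only, source scale cancels),
* the BC threshold change (dB; power sum over the five BC contributors),
* per-contributor changes, and
* the air–bone gap, ABG = BC change − AC change (positive = gap; AC
  worsening and BC improvement both widen it).

Negative change values mean reduced sensitivity (worse thresholds).
All scenario outputs are deterministic given the constants and source
files; there is no randomness anywhere in the model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    build_impedance_table,
    frequency_grid,
    load_model_constants,
    load_source_config,
)
from .elements import FluidProperties, ImpedanceElement, eval_impedance
from .geometry import BoneWave, CochlearGeometry, build_sections
from .network import (
    Netlist,
    SourceSpec,
    assemble,
    db_change,
    input_impedance,
    solve,
)
from .sources import (
    AC_TAG,
    BC_CONTRIBUTORS,
    StandInCurve,
    ac_drive,
    calibrate_contributors,
    compression_spec,
    csf_pressure_source,
    fluid_inertia_spec,
    me_inertia_drive,
    stapes_thevenin_spec,
)
from .third_window import INTACT, PathologyConfig

__all__ = [
    "InnerEarModel",
    "ScenarioResult",
    "HEALTHY",
    "sscd_sweep",
    "va_sweep",
    "reinforcement",
    "abg",
]

HEALTHY = PathologyConfig()
ALL_TAGS = BC_CONTRIBUTORS + (AC_TAG,)


@dataclass
class ScenarioResult:
    """Change spectra of one condition against its reference ear."""

    freq: np.ndarray
    ac_change: np.ndarray
    bc_change: np.ndarray
    contributor_change: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def abg(self) -> np.ndarray:
        """Air–bone gap: BC change minus AC change, positive = gap."""
        return self.bc_change - self.ac_change

    def max_abg(self) -> tuple[float, float]:
        """(maximum ABG in dB, frequency of the maximum in Hz)."""
        gap = self.abg
        i = int(np.argmax(gap))
        return float(gap[i]), float(self.freq[i])

    def at(self, freq_hz: float, column: str = "abg") -> float:
        """Value of a change column at an on-grid frequency."""
        idx = int(np.argmin(np.abs(self.freq - freq_hz)))
        if not np.isclose(self.freq[idx], freq_hz, rtol=1e-9):
            raise ValueError(f"{freq_hz} Hz is not on the frequency grid")
        col = getattr(self, column) if column in ("ac_change", "bc_change", "abg") \
            else self.contributor_change[column]
        return float(col[idx])

    def to_frame(self) -> pd.DataFrame:
        out = {"freq_hz": self.freq, "ac_change_db": self.ac_change,
               "bc_change_db": self.bc_change, "abg_db": self.abg}
        for tag, col in self.contributor_change.items():
            out[f"{tag}_change_db"] = col
        return pd.DataFrame(out)


class InnerEarModel:
    """The assembled inner-ear model: constants, sources, solver, cache.

    Parameters
    ----------
    constants, source_config : dict or path, optional
        Override the packaged ``model.yaml`` / ``sources.yaml``.
    calibrate : bool
        Pin the stand-in contributors to fluid inertia in the healthy ear
        (default).  With ``False`` the raw unit-scale curves are used.
    """

    def __init__(self, constants=None, source_config=None, calibrate: bool = True):
        if constants is None or isinstance(constants, (str, Path)):
            constants = load_model_constants(constants)
        if source_config is None or isinstance(source_config, (str, Path)):
            source_config = load_source_config(source_config)
        self.constants = constants
        self.source_config = source_config
        self.freq = frequency_grid(constants)
        self.fluid = FluidProperties(
            density=constants["fluid"]["density"],
            dynamic_viscosity=constants["fluid"]["viscosity"],
        )
        self.elements = build_impedance_table(constants)
        self.geometry = CochlearGeometry.from_constants(constants)
        self.sections = build_sections(self.geometry)
        w = constants["wave"]
        self.wave = BoneWave(acceleration=w.get("acceleration_m_s2", 1.0),
                             speed=w["speed_m_s"], direction=tuple(w["direction"]))
        self.curves = {name: StandInCurve.from_config(cfg, name)
                       for name, cfg in source_config["curves"].items()}
        self.footplate_area = constants["geometry"]["stapes_footplate_area_mm2"] * 1e-6

        # healthy-ear machinery: oval-window load for the Thévenin drives
        self._flow_cache: dict[PathologyConfig, dict[str, np.ndarray]] = {}
        healthy_net = self.netlist(HEALTHY)
        self._z_in_ow = input_impedance(healthy_net, "OW", self.freq, exclude=("Z_ME",))
        self._stapes_specs = self._build_stapes_specs()
        self.scales = {tag: 1.0 for tag in ALL_TAGS}
        if calibrate:
            raw = {tag: flow for tag, flow in self._solve_all(HEALTHY).items()
                   if tag != AC_TAG}
            self.scales.update(calibrate_contributors(
                raw, self.freq, source_config.get("calibration", {})))
        self._flow_cache.clear()  # cached flows predate calibration scales

    # -- construction ------------------------------------------------------

    def netlist(self, pathology: PathologyConfig) -> Netlist:
        return assemble(pathology, self.elements, self.fluid,
                        self.constants["geometry"])

    def _build_stapes_specs(self) -> dict[str, SourceSpec]:
        """Thévenin sources for the three stapes-path drives (fixed per model)."""
        f = self.freq
        z_me = self.elements["Z_ME"]
        me_tf = self.curves["middle_ear_transfer"]
        u_ac = ac_drive(1.0, f, me_tf, self.footplate_area)
        p_ec_bc = self.wave.acceleration * self.curves["ear_canal"](f)
        u_ec = ac_drive(p_ec_bc, f, me_tf, self.footplate_area)
        u_mi = me_inertia_drive(self.wave, f, self.curves["me_inertia"],
                                self.footplate_area)
        return {
            AC_TAG: stapes_thevenin_spec(AC_TAG, u_ac, z_me, self._z_in_ow, f),
            "ear_canal": stapes_thevenin_spec("ear_canal", u_ec, z_me, self._z_in_ow, f),
            "me_inertia": stapes_thevenin_spec("me_inertia", u_mi, z_me, self._z_in_ow, f),
        }

    def contributor_specs(self, netlist: Netlist) -> dict[str, SourceSpec]:
        """Unit-scale source sets for all six drives on this netlist."""
        f = self.freq
        sv_basal = input_impedance(netlist, "SV_BASE", f,
                                   exclude=("Z_SVD_basal", "Z_SVD_apical"))
        sv_apical = input_impedance(netlist, "SV_APEX", f,
                                    exclude=("Z_SVD_basal", "Z_SVD_apical"))
        st_basal = input_impedance(netlist, "ST_BASE", f,
                                   exclude=("Z_STD_basal", "Z_STD_apical"))
        st_apical = input_impedance(netlist, "ST_APEX", f,
                                    exclude=("Z_STD_basal", "Z_STD_apical"))
        specs = {
            "fluid_inertia": fluid_inertia_spec(self.wave, self.geometry, f,
                                                self.sections),
            "compression": compression_spec(self.wave, self.geometry, self.sections,
                                            f, (sv_basal, sv_apical),
                                            (st_basal, st_apical)),
            "csf_pressure": csf_pressure_source(self.wave, f,
                                                self.curves["csf_pressure"]),
        }
        specs.update(self._stapes_specs)
        return specs

    # -- solving -----------------------------------------------------------

    def _solve_all(self, pathology: PathologyConfig) -> dict[str, np.ndarray]:
        netlist = self.netlist(pathology)
        specs = self.contributor_specs(netlist)
        return {tag: solve(netlist, spec, self.freq).u_c
                for tag, spec in specs.items()}

    def flows(self, pathology: PathologyConfig = HEALTHY) -> dict[str, np.ndarray]:
        """Calibrated per-contributor BM-flow spectra for one pathology."""
        if pathology not in self._flow_cache:
            raw = self._solve_all(pathology)
            self._flow_cache[pathology] = {
                tag: self.scales.get(tag, 1.0) * flow for tag, flow in raw.items()
            }
        return self._flow_cache[pathology]

    def solve_contributor(self, pathology: PathologyConfig, tag: str):
        """Full network solution (flows and node pressures) for one drive."""
        netlist = self.netlist(pathology)
        spec = self.contributor_specs(netlist)[tag]
        return solve(netlist, spec.scaled(self.scales.get(tag, 1.0)), self.freq)

    def dominance_margin_db(self, pathology: PathologyConfig, freq_hz: float,
                            tag: str = "fluid_inertia") -> float:
        """How far ``tag`` sits above the strongest other BC contributor (dB)."""
        flows = self.flows(pathology)
        idx = int(np.argmin(np.abs(self.freq - freq_hz)))
        lead = np.abs(flows[tag][idx])
        rest = max(np.abs(flows[t][idx]) for t in BC_CONTRIBUTORS if t != tag)
        return 20.0 * np.log10(lead / rest)

    # -- comparisons -------------------------------------------------------

    def compare(self, pathology: PathologyConfig,
                reference: PathologyConfig = HEALTHY) -> ScenarioResult:
        """Change spectra of ``pathology`` against ``reference``."""
        ref = self.flows(reference)
        new = self.flows(pathology)
        ac = db_change([new[AC_TAG]], [ref[AC_TAG]])
        bc = db_change([new[t] for t in BC_CONTRIBUTORS],
                       [ref[t] for t in BC_CONTRIBUTORS])
        per = {tag: db_change([new[tag]], [ref[tag]]) for tag in ALL_TAGS}
        meta = {
            "pathology": _pathology_meta(pathology),
            "reference": _pathology_meta(reference),
            "calibration_scales": {k: float(np.abs(v)) for k, v in self.scales.items()},
            "constants_sha256": self.constants_hash(),
            "wave": {"speed_m_s": self.wave.speed,
                     "acceleration_m_s2": self.wave.acceleration,
                     "direction": list(self.wave.direction)},
        }
        return ScenarioResult(freq=self.freq, ac_change=ac, bc_change=bc,
                              contributor_change=per, meta=meta)

    def constants_hash(self) -> str:
        text = json.dumps(self.constants, sort_keys=True, default=float)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def source_table(self, pathology: PathologyConfig = HEALTHY) -> pd.DataFrame:
        """Resolved source set (per contributor magnitude/phase) for audit."""
        netlist = self.netlist(pathology)
        rows = []
        for tag, spec in self.contributor_specs(netlist).items():
            scale = self.scales.get(tag, 1.0)
            for kind, table in (("branch", spec.branch_pressure),
                                ("node", spec.node_injection)):
                for where, values in table.items():
                    v = scale * values
                    rows.append(pd.DataFrame({
                        "contributor": tag, "kind": kind, "at": where,
                        "freq_hz": self.freq, "magnitude": np.abs(v),
                        "phase_rad": np.angle(v),
                    }))
        return pd.concat(rows, ignore_index=True)


def _pathology_meta(p: PathologyConfig) -> dict:
    return {
        "sscd_area_mm2": p.sscd_area_mm2 if isinstance(p.sscd_area_mm2, str)
        else float(p.sscd_area_mm2),
        "va_scale": p.va_scale,
        "ow_stiffness_factor": p.ow_stiffness_factor,
        "rw_stiffness_factor": p.rw_stiffness_factor,
    }


# ---------------------------------------------------------------------------
# the experiments
# ---------------------------------------------------------------------------

DEFAULT_AREAS = (0.1, 0.5, 1.0, 3.0, 6.0, "no_imp")
DEFAULT_VA_SCALES = (0.5, 0.75, 1.5, 2.0)


def sscd_sweep(model: InnerEarModel,
               areas=DEFAULT_AREAS) -> dict[object, ScenarioResult]:
    """Dehiscence-area sweep against the intact healthy ear.

    ``areas`` are dehiscence areas in mm² (0.1–6) and/or ``"no_imp"`` for
    the zero-impedance theoretical bound.
    """
    out = {}
    for area in areas:
        if not isinstance(area, str) and not 0.1 <= float(area) <= 6.0:
            raise ValueError(f"dehiscence areas must lie in [0.1, 6] mm², got {area}")
        out[area] = model.compare(PathologyConfig(sscd_area_mm2=area))
    return out


def va_sweep(model: InnerEarModel,
             scales=DEFAULT_VA_SCALES) -> dict[float, ScenarioResult]:
    """Vestibular-aqueduct size sweep (intact canal) against nominal size."""
    out = {}
    for s in scales:
        if s <= 0:
            raise ValueError(f"aqueduct diameter scales must be positive, got {s}")
        out[s] = model.compare(PathologyConfig(va_scale=float(s)))
    return out


def reinforcement(model: InnerEarModel, ow_factor: float = 1.0,
                  rw_factor: float = 1.0,
                  sscd_area=INTACT) -> ScenarioResult:
    """Window stiffening (possibly with a dehiscence) vs the healthy ear.

    Both change columns are referenced to the normal, unreinforced,
    intact ear.
    """
    p = PathologyConfig(sscd_area_mm2=sscd_area, ow_stiffness_factor=ow_factor,
                        rw_stiffness_factor=rw_factor)
    return model.compare(p)


def abg(result: ScenarioResult) -> tuple[np.ndarray, float, float]:
    """ABG spectrum with its maximum and argmax frequency."""
    spectrum = result.abg
    peak, f_peak = result.max_abg()
    return spectrum, peak, f_peak
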