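"""Assembly and frequency-domain solution of the inner-ear acoustic network.

The network is the acoustic-circuit analog of the inner ear: nodes carry
sound pressure (Pa), branches carry volume velocity (m³·s⁻¹), impedance
branches may hold a series pressure source, and nodes may receive
volume-velocity injections.  The ambient (cranial-exterior) pressure is the
ground reference.

Canonical topology (one branch per anatomical impedance)::

    ambient --[Z_ME]-- OW
    OW --[Z_V/2]-- A --[Z_V/2]-- V      (vestibule, toward the third windows)
    V --[Z_SSC]-- CSF          (dehiscent canal; absent when intact,
    V --[Z_VA]---- CSF          an ideal short in the "no_imp" bound)
    ambient --[P_IC]-- CSF     (ideal pressure branch: CSF reservoir)
    OW --[Z_SV]-- SV_BASE               (basal hook of scala vestibuli)
    SV_BASE --[Z_C]-- ST_BASE           (basilar-membrane branch, flow = U_C)
    SV_BASE --[Z_SVD/2]-- SV_PORT --[Z_SVD/2]-- SV_APEX
    SV_APEX --[Z_H]-- ST_APEX           (helicotrema)
    ST_APEX --[Z_STD/2]-- ST_PORT --[Z_STD/2]-- ST_BASE
    ST_BASE --[Z_CA]-- CSF
    ST_BASE --[Z_RW]-- ambient

The scala-duct ladder (Z_SVD, Z_H, Z_STD) runs from the base to the
helicotrema and back, in parallel with the basilar-membrane branch Z_C —
so third-window shunts at the vestibule stop affecting the BM drive once
their mass reactance exceeds the cochlear input impedance (above ~1 kHz),
and the vestibule is a side branch between the oval window and the
third-window openings rather than part of the scala path.

Pressure-reporting positions: A mid-vestibule (between the two Z_V
halves), B at the oval-window / scala-vestibuli border, C mid scala
vestibuli, D mid scala tympani.

Solution is by modified nodal analysis: per frequency, impedance branches
are stamped as admittances (series sources become Norton injections) and
ideal pressure branches add one current unknown each; the dense complex
system is solved directly.  Superposition over per-contributor solves is
exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import ImpedanceElement, eval_impedance
from .third_window import (
    INTACT,
    NO_IMPEDANCE,
    PathologyConfig,
    ca_impedance,
    sscd_impedance,
    va_impedance,
)

__all__ = [
    "Branch",
    "Netlist",
    "SolveResult",
    "assemble",
    "solve",
    "db_change",
    "pressure_at",
]

GROUND = "ambient"
POSITIONS = {"A": "A", "B": "OW", "C": "SV_PORT", "D": "ST_PORT"}


@dataclass(frozen=True)
class Branch:
    """A two-terminal branch: impedance or ideal pressure source.

    ``kind="impedance"`` branches need an element; ``kind="pressure"``
    branches enforce ``P(n_to) - P(n_from) = E`` for a series source E
    (E = 0 is an ideal short).
    """

    name: str
    n_from: str
    n_to: str
    element: object | None = None
    kind: str = "impedance"

    def __post_init__(self) -> None:
        if self.kind not in ("impedance", "pressure"):
            raise ValueError(f"unknown branch kind {self.kind!r}")
        if self.kind == "impedance" and self.element is None:
            raise ValueError(f"impedance branch {self.name!r} needs an element")
        if self.n_from == self.n_to:
            raise ValueError(f"branch {self.name!r} connects a node to itself")


@dataclass
class Netlist:
    """The assembled acoustic network."""

    branches: list[Branch]
    pathology: PathologyConfig | None = None
    positions: dict[str, str] = field(default_factory=lambda: dict(POSITIONS))

    def __post_init__(self) -> None:
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError("branch names must be unique")
        self._index = {b.name: b for b in self.branches}
        nodes: list[str] = [GROUND]
        for b in self.branches:
            for n in (b.n_from, b.n_to):
                if n not in nodes:
                    nodes.append(n)
        self.nodes = nodes
        self._check_connected()

    def _check_connected(self) -> None:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for b in self.branches:
            if b.kind == "impedance" and b.element.is_blocked:
                continue
            adj[b.n_from].add(b.n_to)
            adj[b.n_to].add(b.n_from)
        seen = {GROUND}
        stack = [GROUND]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        missing = set(self.nodes) - seen
        if missing:
            raise ValueError(f"network is disconnected; unreachable nodes: {sorted(missing)}")

    def branch(self, name: str) -> Branch:
        return self._index[name]

    def has_branch(self, name: str) -> bool:
        return name in self._index

    def to_edge_list(self) -> pd.DataFrame:
        """Plain-text edge list for audit."""
        return pd.DataFrame(
            [
                {
                    "branch": b.name,
                    "from": b.n_from,
                    "to": b.n_to,
                    "kind": b.kind,
                    "blocked": bool(b.kind == "impedance" and b.element.is_blocked),
                }
                for b in self.branches
            ]
        )


@dataclass
class SourceSpec:
    """Right-hand side of one contributor's solve.

    ``branch_pressure`` maps branch name -> complex series-source spectrum
    (orientation: a positive source drives flow from ``n_from`` to
    ``n_to``); ``node_injection`` maps node name -> complex
    volume-velocity spectrum injected into the node.
    """

    tag: str = ""
    branch_pressure: dict[str, np.ndarray] = field(default_factory=dict)
    node_injection: dict[str, np.ndarray] = field(default_factory=dict)

    def scaled(self, factor: complex) -> "SourceSpec":
        return SourceSpec(
            tag=self.tag,
            branch_pressure={k: factor * v for k, v in self.branch_pressure.items()},
            node_injection={k: factor * v for k, v in self.node_injection.items()},
        )


@dataclass
class SolveResult:
    """Solution of one contributor's sources over the frequency grid."""

    tag: str
    freq: np.ndarray
    u_c: np.ndarray                       # BM-branch volume velocity (complex)
    node_pressure: dict[str, np.ndarray]  # per internal node
    branch_flow: dict[str, np.ndarray]    # per live branch, n_from -> n_to

    def to_frame(self) -> pd.DataFrame:
        out = {"freq_hz": self.freq,
               "u_c_mag": np.abs(self.u_c),
               "u_c_phase_rad": np.angle(self.u_c)}
        for pos in ("A", "B", "C", "D"):
            p = pressure_at(self, pos)
            out[f"p_{pos}_mag"] = np.abs(p)
            out[f"p_{pos}_phase_rad"] = np.angle(p)
        return pd.DataFrame(out)

    positions: dict[str, str] = field(default_factory=lambda: dict(POSITIONS))


def assemble(
    pathology: PathologyConfig,
    elements: dict[str, ImpedanceElement],
    fluid=None,
    geometry: dict | None = None,
) -> Netlist:
    """Build the canonical netlist for a pathology configuration.

    ``elements`` is the Table-style lumped-impedance dictionary (Z_ME, Z_V,
    Z_SV, Z_SVD, Z_STD, Z_C, Z_H, Z_RW); the pathology-parameterized
    third-window elements are constructed from geometry.  Window
    reinforcement multiplies the stiffness coefficient of Z_ME (oval
    window) and Z_RW (round window).
    """
    from .elements import FluidProperties

    fluid = fluid or FluidProperties()
    geometry = geometry or {}
    z_me = elements["Z_ME"].with_stiffness_factor(pathology.ow_stiffness_factor, "Z_ME")
    z_rw = elements["Z_RW"].with_stiffness_factor(pathology.rw_stiffness_factor, "Z_RW")
    half = 0.5
    z_v = elements["Z_V"]
    z_v_half = ImpedanceElement(name="Z_V/2", mass=z_v.mass * half,
                                resistance=z_v.resistance * half,
                                stiffness=z_v.stiffness * half)
    z_svd = elements["Z_SVD"]
    z_std = elements["Z_STD"]
    z_svd_half = ImpedanceElement(name="Z_SVD/2", mass=half * z_svd.mass,
                                  resistance=half * z_svd.resistance)
    z_std_half = ImpedanceElement(name="Z_STD/2", mass=half * z_std.mass,
                                  resistance=half * z_std.resistance)

    branches = [
        Branch("Z_ME", GROUND, "OW", z_me),
        Branch("Z_V_ow", "OW", "A", z_v_half),
        Branch("Z_V_v", "A", "V", z_v_half),
        Branch("Z_VA", "V", "CSF", va_impedance(pathology.va_scale, fluid,
                                                geometry.get("vestibular_aqueduct"))),
        Branch("P_IC", GROUND, "CSF", kind="pressure"),
        Branch("Z_SV", "OW", "SV_BASE", elements["Z_SV"]),
        Branch("Z_C", "SV_BASE", "ST_BASE", elements["Z_C"]),
        Branch("Z_SVD_basal", "SV_BASE", "SV_PORT", z_svd_half),
        Branch("Z_SVD_apical", "SV_PORT", "SV_APEX", z_svd_half),
        Branch("Z_H", "SV_APEX", "ST_APEX", elements["Z_H"]),
        Branch("Z_STD_apical", "ST_APEX", "ST_PORT", z_std_half),
        Branch("Z_STD_basal", "ST_PORT", "ST_BASE", z_std_half),
        Branch("Z_CA", "ST_BASE", "CSF", ca_impedance(fluid,
                                                      geometry.get("cochlear_aqueduct"))),
        Branch("Z_RW", "ST_BASE", GROUND, z_rw),
    ]
    area = pathology.sscd_area_mm2
    if area == NO_IMPEDANCE:
        branches.insert(3, Branch("Z_SSC", "V", "CSF", kind="pressure"))  # ideal short
    elif area != INTACT and float(area) > 0.0:
        branches.insert(3, Branch("Z_SSC", "V", "CSF",
                                  sscd_impedance(area, fluid,
                                                 geometry.get("semicircular_canal"))))
    # intact: canal branch absent (blocked)
    return Netlist(branches=branches, pathology=pathology)


def solve(netlist: Netlist, sources: SourceSpec, freq) -> SolveResult:
    """Solve the network for one contributor's sources over ``freq``.

    Modified nodal analysis with a dense complex solve per frequency.
    Raises with the offending configuration named if the system is
    singular.
    """
    f = np.atleast_1d(np.asarray(freq, float))
    live = [b for b in netlist.branches
            if not (b.kind == "impedance" and b.element.is_blocked)]
    for name in sources.branch_pressure:
        if not netlist.has_branch(name):
            raise ValueError(f"source on unknown branch {name!r}")
        if netlist.branch(name) not in live:
            raise ValueError(f"source on blocked branch {name!r}")
    for node in sources.node_injection:
        if node not in netlist.nodes or node == GROUND:
            raise ValueError(f"injection at invalid node {node!r}")

    nodes = [n for n in netlist.nodes if n != GROUND]
    nidx = {n: i for i, n in enumerate(nodes)}
    p_branches = [b for b in live if b.kind == "pressure"]
    z_branches = [b for b in live if b.kind == "impedance"]
    n_nodes = len(nodes)
    n_unknowns = n_nodes + len(p_branches)

    def e_of(branch: Branch, k: int) -> complex:
        arr = sources.branch_pressure.get(branch.name)
        return 0.0 if arr is None else arr[k]

    z_eval = {b.name: eval_impedance(b.element, f) for b in z_branches}
    u_c = np.zeros(f.size, complex)
    node_pressure = {n: np.zeros(f.size, complex) for n in nodes}
    branch_flow = {b.name: np.zeros(f.size, complex) for b in live}

    for k in range(f.size):
        m = np.zeros((n_unknowns, n_unknowns), complex)
        rhs = np.zeros(n_unknowns, complex)
        for b in z_branches:
            z = z_eval[b.name][k]
            if z == 0:
                raise ValueError(
                    f"impedance branch {b.name!r} evaluates to zero at {f[k]:g} Hz; "
                    "use a pressure-kind branch for ideal shorts"
                )
            y = 1.0 / z
            e = e_of(b, k)
            i_f = nidx.get(b.n_from)
            i_t = nidx.get(b.n_to)
            # flow from -> to: U = (P_from - P_to + E) * y
            if i_f is not None:
                m[i_f, i_f] += y
                if i_t is not None:
                    m[i_f, i_t] -= y
                rhs[i_f] -= e * y
            if i_t is not None:
                m[i_t, i_t] += y
                if i_f is not None:
                    m[i_t, i_f] -= y
                rhs[i_t] += e * y
        for j, b in enumerate(p_branches):
            row = n_nodes + j
            e = e_of(b, k)
            i_f = nidx.get(b.n_from)
            i_t = nidx.get(b.n_to)
            # constraint: P_to - P_from = E ; unknown current q flows from -> to
            if i_t is not None:
                m[row, i_t] += 1.0
                m[i_t, row] -= 1.0  # current q enters n_to
            if i_f is not None:
                m[row, i_f] -= 1.0
                m[i_f, row] += 1.0  # current q leaves n_from
            rhs[row] = e
        for node, inj in sources.node_injection.items():
            rhs[nidx[node]] += inj[k]
        try:
            x = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular network at {f[k]:g} Hz (pathology="
                f"{netlist.pathology!r}); check for isolated or all-blocked paths"
            ) from err
        pres = {n: x[i] for n, i in nidx.items()}
        pres[GROUND] = 0.0
        for n in nodes:
            node_pressure[n][k] = pres[n]
        for b in z_branches:
            e = e_of(b, k)
            branch_flow[b.name][k] = (pres[b.n_from] - pres[b.n_to] + e) / z_eval[b.name][k]
        for j, b in enumerate(p_branches):
            branch_flow[b.name][k] = x[n_nodes + j]
        if "Z_C" in branch_flow:
            u_c[k] = branch_flow["Z_C"][k]

    return SolveResult(tag=sources.tag, freq=f, u_c=u_c,
                       node_pressure=node_pressure, branch_flow=branch_flow,
                       positions=dict(netlist.positions))


def input_impedance(netlist: Netlist, node: str, freq,
                    exclude: tuple[str, ...] = ()) -> np.ndarray:
    """Driving-point impedance seen from ``node`` to ambient.

    All sources off; branches named in ``exclude`` are removed first.
    """
    kept = [b for b in netlist.branches if b.name not in exclude]
    sub = Netlist(branches=kept, pathology=netlist.pathology)
    f = np.atleast_1d(np.asarray(freq, float))
    spec = SourceSpec(tag="probe", node_injection={node: np.ones(f.size, complex)})
    res = solve(sub, spec, f)
    return res.node_pressure[node]


def db_change(after, before) -> np.ndarray:
    """Power-summed level change in dB.

    ``10·log10(Σ|after|² / Σ|before|²)`` per frequency over the listed
    contributor spectra; for a single contributor this reduces to
    ``20·log10`` of the magnitude ratio.  Negative values mean reduced
    sensitivity.  A zero reference power is flagged, not silently infinite.
    """
    after = [np.atleast_1d(np.asarray(a)) for a in np.atleast_2d(after)]
    before = [np.atleast_1d(np.asarray(b)) for b in np.atleast_2d(before)]
    if len(after) != len(before):
        raise ValueError("contributor counts differ between conditions")
    p_after = sum(np.abs(a) ** 2 for a in after)
    p_before = sum(np.abs(b) ** 2 for b in before)
    if np.any(p_before == 0):
        raise ValueError("zero reference power in dB change")
    return 10.0 * np.log10(p_after / p_before)


def pressure_at(result: SolveResult, position: str) -> np.ndarray:
    """Node pressure spectrum at one of the reporting positions A–D."""
    try:
        node = result.positions[position]
    except KeyError:
        raise ValueError(f"unmapped position {position!r}; expected one of A, B, C, D")
    return result.node_pressure[node]
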