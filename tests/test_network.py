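"""Network assembly and the frequency-domain solver: Ohm-law cases,
superposition, passivity bookkeeping and intra-cochlear pressure positions."""

import numpy as np
import pytest

from innerear import HEALTHY, InnerEarModel, PathologyConfig, pressure_at
from innerear.constants import build_impedance_table
from innerear.elements import FluidProperties, ImpedanceElement
from innerear.network import (
    Branch,
    Netlist,
    SourceSpec,
    assemble,
    db_change,
    input_impedance,
    solve,
)
from innerear.third_window import NO_IMPEDANCE


def two_element_loop(z1, z2):
    return Netlist(branches=[
        Branch("Z1", "ambient", "n1", z1),
        Branch("Z2", "n1", "ambient", z2),
    ])


class TestSolver:
    def test_single_loop_ohm_law(self):
        z1 = ImpedanceElement(mass=1e5, resistance=2e8)
        z2 = ImpedanceElement(resistance=5e8, stiffness=1e12)
        net = two_element_loop(z1, z2)
        f = np.array([250.0, 2000.0])
        p = np.array([1.0 + 0.5j, 2.0 - 1.0j])
        res = solve(net, SourceSpec(tag="t", branch_pressure={"Z1": p}), f)
        expect = p / (z1(f) + z2(f))
        np.testing.assert_allclose(res.branch_flow["Z1"], expect, rtol=1e-12)
        np.testing.assert_allclose(res.branch_flow["Z2"], expect, rtol=1e-12)

    def test_superposition_is_exact(self, model, grid):
        """Joint solve equals the complex sum of single-source solves to
        machine precision."""
        net = model.netlist(HEALTHY)
        specs = model.contributor_specs(net)
        a, b = specs["ac_drive"], specs["csf_pressure"]
        joint = SourceSpec(tag="joint",
                           branch_pressure={**a.branch_pressure, **b.branch_pressure},
                           node_injection={**a.node_injection, **b.node_injection})
        u_joint = solve(net, joint, grid).u_c
        u_sum = solve(net, a, grid).u_c + solve(net, b, grid).u_c
        np.testing.assert_allclose(u_joint, u_sum, rtol=1e-12)

    def test_random_passive_network_against_dense_nodal_oracle(self):
        """A seeded 6-node network with one source matches an independently
        assembled admittance solve."""
        rng = np.random.default_rng(7)
        nodes = ["ambient", "n1", "n2", "n3", "n4", "n5"]
        edges = [("ambient", "n1"), ("n1", "n2"), ("n2", "n3"), ("n3", "ambient"),
                 ("n1", "n4"), ("n4", "n5"), ("n5", "ambient"), ("n2", "n5"),
                 ("n3", "n4")]
        f = 440.0
        jw = 2j * np.pi * f
        branches, zvals = [], []
        for i, (a, b) in enumerate(edges):
            m, r, k = rng.uniform(1e4, 1e6), rng.uniform(1e7, 1e9), rng.uniform(1e10, 1e12)
            branches.append(Branch(f"b{i}", a, b, ImpedanceElement(mass=m, resistance=r,
                                                                   stiffness=k)))
            zvals.append(jw * m + r + k / jw)
        net = Netlist(branches=branches)
        inj = {"n3": np.array([1.0 - 0.3j])}
        res = solve(net, SourceSpec(tag="t", node_injection=inj), [f])
        # independent oracle: textbook nodal admittance assembly
        idx = {n: i for i, n in enumerate(nodes[1:])}
        y = np.zeros((5, 5), complex)
        for (a, b), z in zip(edges, zvals):
            ia, ib = idx.get(a), idx.get(b)
            if ia is not None:
                y[ia, ia] += 1 / z
            if ib is not None:
                y[ib, ib] += 1 / z
            if ia is not None and ib is not None:
                y[ia, ib] -= 1 / z
                y[ib, ia] -= 1 / z
        rhs = np.zeros(5, complex)
        rhs[idx["n3"]] = 1.0 - 0.3j
        p = np.linalg.solve(y, rhs)
        for n in ("n1", "n2", "n3", "n4", "n5"):
            assert res.node_pressure[n][0] == pytest.approx(p[idx[n]], rel=1e-10)

    def test_passivity_power_balance(self, model):
        """Source input power equals the summed dissipation 0.5·Re(Z)·|U|²
        over all branches, at three frequencies."""
        net = model.netlist(PathologyConfig(sscd_area_mm2=2.0))
        f = np.array([125.0, 1000.0, 8000.0])
        e = np.ones(3, complex) * 2.0
        res = solve(net, SourceSpec(tag="t", branch_pressure={"Z_ME": e}), f)
        from innerear.elements import eval_impedance

        p_in = 0.5 * np.real(e * np.conj(res.branch_flow["Z_ME"]))
        p_diss = np.zeros(3)
        for b in net.branches:
            if b.kind != "impedance" or b.element.is_blocked:
                continue
            z = eval_impedance(b.element, f)
            assert np.all(z.real >= 0)
            p_diss += 0.5 * z.real * np.abs(res.branch_flow[b.name]) ** 2
        np.testing.assert_allclose(p_in, p_diss, rtol=1e-9)
        assert np.all(p_in > 0)

    def test_singular_configuration_diagnosed(self):
        iso = Netlist(branches=[
            Branch("Z1", "ambient", "n1", ImpedanceElement(mass=1e5)),
            Branch("Z2", "ambient", "n1", ImpedanceElement(mass=1e5)),
        ])
        # injection balanced by nothing resistive is fine; a disconnected
        # node is caught at construction time
        with pytest.raises(ValueError, match="disconnected"):
            Netlist(branches=[
                Branch("Z1", "ambient", "n1", ImpedanceElement(mass=1e5)),
                Branch("Z2", "n2", "n3", ImpedanceElement(mass=1e5)),
            ])
        del iso

    def test_source_on_blocked_branch_rejected(self, model):
        net = model.netlist(HEALTHY)  # intact: no canal branch at all
        with pytest.raises(ValueError):
            solve(net, SourceSpec(tag="t",
                                  branch_pressure={"Z_SSC": np.ones(1, complex)}),
                  [100.0])


class TestAssembly:
    def test_intact_canal_absent(self, model):
        net = model.netlist(HEALTHY)
        assert not net.has_branch("Z_SSC")

    def test_no_impedance_bound_shorts_vestibule_to_csf(self, model, grid):
        net = model.netlist(PathologyConfig(sscd_area_mm2=NO_IMPEDANCE))
        assert net.branch("Z_SSC").kind == "pressure"
        spec = model.contributor_specs(net)["ac_drive"]
        res = solve(net, spec, grid)
        np.testing.assert_allclose(res.node_pressure["V"], res.node_pressure["CSF"],
                                   rtol=1e-9, atol=1e-30)

    def test_window_reinforcement_scales_stiffness_terms(self, constants, fluid):
        table = build_impedance_table(constants)
        net = assemble(PathologyConfig(ow_stiffness_factor=10, rw_stiffness_factor=100),
                       table, fluid)
        assert net.branch("Z_ME").element.stiffness == pytest.approx(10 * 8.1e13)
        assert net.branch("Z_RW").element.stiffness == pytest.approx(100 * 7e12)
        assert net.branch("Z_ME").element.mass == table["Z_ME"].mass

    def test_edge_list_export(self, model):
        frame = model.netlist(HEALTHY).to_edge_list()
        assert {"branch", "from", "to", "kind"} <= set(frame.columns)
        assert "Z_C" in set(frame["branch"])


class TestDbChange:
    def test_doubled_amplitude(self):
        assert db_change([np.array([2.0])], [np.array([1.0])])[0] == pytest.approx(
            6.02, abs=0.01)

    def test_power_summation_pair(self):
        after = [np.array([6.0]), np.array([8.0])]
        before = [np.array([3.0]), np.array([4.0])]
        assert db_change(after, before)[0] == pytest.approx(6.02, abs=0.01)

    def test_new_contributor_adds_3db(self):
        after = [np.array([1.0]), np.array([1.0])]
        before = [np.array([1.0]), np.array([0.0])]
        assert db_change(after, before)[0] == pytest.approx(3.01, abs=0.01)

    def test_zero_reference_flagged(self):
        with pytest.raises(ValueError, match="zero reference"):
            db_change([np.array([1.0])], [np.array([0.0])])


class TestPressurePositions:
    def test_ac_vestibule_positions_nearly_identical(self, model):
        """With AC drive the pressures at A (mid-vestibule) and B (oval
        window) agree within 1 dB at all frequencies."""
        res = model.solve_contributor(HEALTHY, "ac_drive")
        pa, pb = np.abs(pressure_at(res, "A")), np.abs(pressure_at(res, "B"))
        assert np.max(np.abs(20 * np.log10(pa / pb))) < 1.0

    def test_ac_mid_scala_slightly_below_b_at_high_frequency(self, model):
        """Position C falls a few dB below B above 1 kHz (duct mass drop)."""
        res = model.solve_contributor(HEALTHY, "ac_drive")
        pb, pc = np.abs(pressure_at(res, "B")), np.abs(pressure_at(res, "C"))
        drop = 20 * np.log10(pb / pc)[model.freq > 1000]
        assert np.all((drop > 0.5) & (drop < 5.0))

    def test_bc_oval_window_below_mid_vestibule(self, model, grid):
        """With inertial BC drive, B sits a handful of dB below A at the
        comparison frequencies."""
        res = model.solve_contributor(HEALTHY, "fluid_inertia")
        pa, pb = np.abs(pressure_at(res, "A")), np.abs(pressure_at(res, "B"))
        sel = (grid >= 250) & (grid <= 1000)
        drop = 20 * np.log10(pa / pb)[sel]
        assert np.all((drop > 0) & (drop < 10))

    def test_unmapped_position_rejected(self, model):
        res = model.solve_contributor(HEALTHY, "ac_drive")
        with pytest.raises(ValueError):
            pressure_at(res, "E")


class TestInputImpedance:
    def test_matches_series_reduction_on_simple_loop(self):
        z1 = ImpedanceElement(mass=2e5, resistance=1e8)
        z2 = ImpedanceElement(resistance=4e8)
        net = two_element_loop(z1, z2)
        f = np.array([300.0])
        z_in = input_impedance(net, "n1", f)
        expect = 1.0 / (1.0 / z1(f) + 1.0 / z2(f))
        np.testing.assert_allclose(z_in, expect, rtol=1e-10)
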