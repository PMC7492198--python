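"""Excitation sources: stand-in curves, wave-derived drives, contributor
activation sets and calibration."""

import numpy as np
import pytest

from innerear import HEALTHY, InnerEarModel, PathologyConfig
from innerear.geometry import BoneWave, build_sections
from innerear.network import db_change, solve
from innerear.sources import (
    AC_TAG,
    BC_CONTRIBUTORS,
    StandInCurve,
    ac_drive,
    calibrate_contributors,
    inertial_pressure_sources,
    me_inertia_drive,
)

# documented source subsets per contributor
EXPECTED_ACTIVATION = {
    "fluid_inertia": ({"Z_V_ow", "Z_V_v", "Z_SV", "Z_SVD_basal", "Z_SVD_apical",
                       "Z_STD_basal", "Z_STD_apical"}, set()),
    "compression": (set(), {"V", "SV_PORT", "ST_PORT"}),
    "me_inertia": ({"Z_ME"}, set()),
    "ear_canal": ({"Z_ME"}, set()),
    "csf_pressure": ({"P_IC"}, set()),
    AC_TAG: ({"Z_ME"}, set()),
}


class TestStandInCurve:
    def test_exact_at_breakpoints(self):
        curve = StandInCurve(freq_hz=(100, 1000, 10000), mag_db=(0, -6, -20),
                             phase_deg=(0, -45, -90))
        v = curve([100.0, 1000.0, 10000.0])
        np.testing.assert_allclose(np.abs(v), [1.0, 10 ** -0.3, 0.1], rtol=1e-12)
        assert np.angle(v[1]) == pytest.approx(np.radians(-45))

    def test_defined_on_full_grid_and_scaled(self, grid):
        curve = StandInCurve(freq_hz=(100, 10000), mag_db=(0, -10),
                             phase_deg=(0, 0), scale=3.0)
        v = curve(grid)
        assert v.shape == grid.shape and np.all(np.isfinite(v))
        np.testing.assert_allclose(np.abs(curve.with_scale(6.0)(grid)), 2 * np.abs(v))

    def test_csf_curve_flagged_below_250(self, model):
        assert model.curves["csf_pressure"].min_valid_hz == 250.0

    def test_me_inertia_peak_in_ossicular_resonance_band(self, model):
        assert 1000.0 <= model.curves["me_inertia"].peak_frequency() <= 2000.0


class TestInertialSources:
    def test_zero_acceleration_silences_everything(self, geom, sections, grid):
        src = inertial_pressure_sources(BoneWave(acceleration=0.0), geom, grid,
                                        sections)
        assert np.max(np.abs(src.p_v)) == 0
        for v in src.branch_pressure.values():
            assert np.max(np.abs(v)) == 0

    def test_vestibule_column_magnitude(self, geom, sections, grid):
        """|P_V| = ρ·L·a = 1000·0.0058·1 = 5.8 Pa at unit acceleration."""
        src = inertial_pressure_sources(BoneWave(acceleration=1.0), geom, grid,
                                        sections)
        np.testing.assert_allclose(np.abs(src.p_v), 5.8, rtol=1e-9)

    def test_scala_ratio_frequency_independent_in_rigid_limit(self, geom, sections, grid):
        src = inertial_pressure_sources(BoneWave(speed=np.inf), geom, grid, sections)
        ratio = np.abs(src.p_sv) / np.abs(src.p_v)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_rigid_limit_loop_cancellation(self, geom, sections, grid):
        """At infinite wave speed the conservative inertial field yields zero
        net source around the scala ring, and the window drive equals
        ρ·a times the oval-to-round-window separation."""
        src = inertial_pressure_sources(BoneWave(speed=np.inf), geom, grid, sections)
        bp = src.branch_pressure
        ring = (bp["Z_SVD_basal"] + bp["Z_SVD_apical"]
                + bp["Z_STD_apical"] + bp["Z_STD_basal"])
        window = bp["Z_SV"] + bp["Z_SVD_basal"] + bp["Z_SVD_apical"] \
            + bp["Z_STD_apical"] + bp["Z_STD_basal"]
        sep = geom.ow_xy[0] - geom.st_base_xy[0]
        np.testing.assert_allclose(np.abs(ring),
                                   np.abs(bp["Z_SVD_basal"] * 0) +
                                   abs(1000 * (geom.sv_base_xy[0] - geom.st_base_xy[0])),
                                   atol=1e-9 + 1000 * 5e-4)
        np.testing.assert_allclose(window, -1000 * sep, rtol=1e-9)


class TestStapesDrives:
    def test_ac_drive_linear_in_pressure_with_footplate_area(self, model, grid):
        tf = model.curves["middle_ear_transfer"]
        u1 = ac_drive(1.0, grid, tf, footplate_area_m2=3.85e-6)
        u2 = ac_drive(2.0, grid, tf, footplate_area_m2=3.85e-6)
        np.testing.assert_allclose(u2, 2 * u1, rtol=1e-12)
        np.testing.assert_allclose(np.abs(u1), np.abs(tf(grid)) * 3.85e-6, rtol=1e-12)

    def test_me_inertia_drive_scales_with_acceleration(self, model, grid):
        curve = model.curves["me_inertia"]
        still = me_inertia_drive(BoneWave(acceleration=0.0), grid, curve)
        assert np.max(np.abs(still)) == 0
        u1 = me_inertia_drive(BoneWave(acceleration=1.0), grid, curve)
        u2 = me_inertia_drive(BoneWave(acceleration=3.0), grid, curve)
        np.testing.assert_allclose(u2, 3 * u1, rtol=1e-12)

    def test_stapes_path_contributors_change_like_ac_under_sscd(self, model):
        """Middle-ear inertia and ear-canal sound enter solely through the
        stapes, so their change spectra under a dehiscence coincide with the
        AC change."""
        res = model.compare(PathologyConfig(sscd_area_mm2=3.0))
        np.testing.assert_allclose(res.contributor_change["me_inertia"],
                                   res.contributor_change[AC_TAG], atol=1e-9)
        np.testing.assert_allclose(res.contributor_change["ear_canal"],
                                   res.contributor_change[AC_TAG], atol=1e-9)


class TestActivationSets:
    @pytest.mark.parametrize("tag", sorted(EXPECTED_ACTIVATION))
    def test_each_contributor_touches_only_its_sources(self, model, tag):
        net = model.netlist(PathologyConfig(sscd_area_mm2=1.0))
        spec = model.contributor_specs(net)[tag]
        branches, nodes = EXPECTED_ACTIVATION[tag]
        assert set(spec.branch_pressure) == branches
        assert set(spec.node_injection) == nodes


class TestCsfPathway:
    def test_csf_drives_bm_through_third_window_branches(self, model, grid):
        """P_IC reaches the basilar membrane only through the aqueduct
        branches: choking both aqueducts (intact canal) removes its BM
        drive entirely."""
        from innerear.elements import ImpedanceElement
        from innerear.network import Netlist

        net = model.netlist(HEALTHY)
        spec = model.contributor_specs(net)["csf_pressure"]
        open_paths = solve(net, spec, grid).u_c
        assert np.all(np.abs(open_paths) > 0)
        choke = ImpedanceElement(mass=1e15, resistance=1e18)
        choked = Netlist(branches=[
            b if b.name not in ("Z_VA", "Z_CA")
            else type(b)(b.name, b.n_from, b.n_to, choke)
            for b in net.branches], pathology=net.pathology)
        residual = solve(choked, spec, grid).u_c
        drop = 20 * np.log10(np.abs(residual) / np.abs(open_paths))
        assert np.max(drop) < -40.0

    def test_halving_aqueduct_reduces_csf_pathway_near_12db(self, model):
        """Halving the narrow-duct diameter cuts the CSF contributor's BM
        flow by about 12 dB at 500 Hz."""
        res = model.compare(PathologyConfig(va_scale=0.5))
        assert res.at(500.0, "csf_pressure") == pytest.approx(-12.0, abs=2.0)

    def test_change_independent_of_curve_scale(self, model, grid):
        """Contributor-change ratios cancel the stand-in curve's absolute
        scale exactly."""
        net_ref = model.netlist(HEALTHY)
        net_new = model.netlist(PathologyConfig(va_scale=0.5))
        spec_ref = model.contributor_specs(net_ref)["csf_pressure"]
        spec_new = model.contributor_specs(net_new)["csf_pressure"]
        base = db_change([solve(net_new, spec_new, grid).u_c],
                         [solve(net_ref, spec_ref, grid).u_c])
        scaled = db_change([solve(net_new, spec_new.scaled(37.0), grid).u_c],
                           [solve(net_ref, spec_ref.scaled(37.0), grid).u_c])
        np.testing.assert_allclose(scaled, base, rtol=0, atol=1e-12)


class TestCalibration:
    def test_fluid_inertia_dominates_healthy_low_frequencies(self, model):
        """After calibration, fluid inertia carries more BM flow than any
        other contributor at 250 and 500 Hz in the healthy ear."""
        for f0 in (250.0, 500.0):
            assert model.dominance_margin_db(HEALTHY, f0) > 0

    def test_sscd_ear_fluid_inertia_dominated_below_1khz(self, model):
        flows = model.flows(PathologyConfig(sscd_area_mm2=6.0))
        sel = model.freq <= 1000.0
        fi = np.abs(flows["fluid_inertia"][sel])
        for tag in BC_CONTRIBUTORS:
            if tag != "fluid_inertia":
                assert np.all(fi >= np.abs(flows[tag][sel])), tag

    def test_common_rescaling_leaves_db_change_invariant(self, model):
        ref = model.flows(HEALTHY)
        new = model.flows(PathologyConfig(sscd_area_mm2=1.0))
        base = db_change([new[t] for t in BC_CONTRIBUTORS],
                         [ref[t] for t in BC_CONTRIBUTORS])
        k = 0.02
        scaled = db_change([k * new[t] for t in BC_CONTRIBUTORS],
                           [k * ref[t] for t in BC_CONTRIBUTORS])
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_infeasible_anchor_reported(self, grid):
        flows = {"fluid_inertia": np.ones(grid.size), "csf_pressure": np.zeros(grid.size)}
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_contributors(flows, grid,
                                   {"csf_pressure": {"offset_db": -15, "at": 1000.0}})


class TestPhaseFreeLimit:
    def test_rigid_motion_keeps_inertia_kills_compression(self, constants):
        """c → ∞: compression sources vanish while inertial sources persist
        and share one phase."""
        c2 = {**constants, "wave": {**constants["wave"], "speed_m_s": 1e12}}
        model = InnerEarModel(constants=c2, calibrate=False)
        net = model.netlist(HEALTHY)
        specs = model.contributor_specs(net)
        comp = specs["compression"]
        for v in comp.node_injection.values():
            assert np.max(np.abs(v)) < 1e-18
        fi = specs["fluid_inertia"].branch_pressure
        assert np.abs(fi["Z_V_ow"]).max() > 1.0
        angles = np.angle(fi["Z_V_ow"] / fi["Z_V_v"])
        np.testing.assert_allclose(angles, 0.0, atol=1e-6)
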