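"""Structural FEM: meshing, equilibrium, oracles, lumen sampling."""

import numpy as np
import pytest

from plaquemech import benchmarks as bm
from plaquemech import constitutive as ct
from plaquemech import fem_solid as fem
from plaquemech import synthetic_cohort as sc
from plaquemech.units import mmhg_to_kpa

from conftest import RING_PRESSURE_KPA, RING_RI, RING_RO, midwall_hoop_stress


def lipid_slice(seed=4):
    return sc.generate_slice(sc.SliceSpec(
        lumen_radius=1.4, lumen_eccentricity=0.3, wall_thickness=1.0,
        lipid_arc=100.0, lipid_thickness=0.4, cap_thickness=0.12,
        noise_amplitude=0.02, seed=seed))


class TestBuildMesh:
    def test_annulus_single_region(self, ring_mesh):
        assert set(ring_mesh.regions) == {"wall"}
        assert len(ring_mesh.lumen_loop) > 0 and len(ring_mesh.outer_loop) > 0
        # two closed boundary loops at the correct radii
        r_in = np.linalg.norm(ring_mesh.nodes[ring_mesh.lumen_loop], axis=1)
        r_out = np.linalg.norm(ring_mesh.nodes[ring_mesh.outer_loop], axis=1)
        assert np.allclose(r_in, RING_RI, atol=0.01)
        assert np.allclose(r_out, RING_RO, atol=0.01)

    def test_region_areas_match_polygons(self):
        """Component-fitted meshing: mesh region areas within 1% of the
        polygon areas once h resolves the inclusion (h = 0.1 mm)."""
        sl = lipid_slice()
        mesh = fem.build_mesh(sl, 0.1)
        poly = mesh.region_polygon_areas
        got = mesh.region_areas()
        for region, a in poly.items():
            assert got[region] == pytest.approx(a, rel=0.01), region

    def test_refinement_quadruples_elements(self):
        sl = bm.ring_slice(1.5, 3.0)
        n1 = fem.build_mesh(sl, 0.3).n_elements
        n2 = fem.build_mesh(sl, 0.15).n_elements
        assert 2.0 <= n2 / n1 <= 6.0     # ~4x within +-50%

    def test_conforming_no_hanging_nodes(self, ring_mesh):
        """Every interior edge is shared by exactly two elements."""
        from collections import Counter
        edges = Counter()
        for el in ring_mesh.elements:
            for a, b in ((el[0], el[1]), (el[1], el[2]), (el[2], el[0])):
                edges[frozenset((int(a), int(b)))] += 1
        counts = np.array(list(edges.values()))
        assert set(counts) <= {1, 2}
        # boundary (count-1) edges match the two loops' vertex-edge counts
        assert (counts == 1).sum() == (len(ring_mesh.lumen_loop) // 2
                                       + len(ring_mesh.outer_loop) // 2)

    def test_degenerate_geometry_raises_with_region(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = lambda r: np.column_stack([r * np.cos(th), r * np.sin(th)])
        bad = sc.SliceContours(0, 0.0, {"lumen": ring(2.0),
                                        "outer": ring(1.0)})
        with pytest.raises(fem.MeshingError) as exc:
            fem.build_mesh(bad, 0.2)
        assert exc.value.region in ("lumen", "outer", "wall")


class TestSolveStatic:
    def test_zero_pressure_is_reference_state(self, ring_mesh, vessel_mat):
        sol = fem.solve_static(ring_mesh, {"wall": vessel_mat},
                               fem.SolveConfig(pressure=0.0, load_steps=1))
        assert np.allclose(sol.displacements, 0.0, atol=1e-12)
        assert np.allclose(sol.cauchy, 0.0, atol=1e-10)

    def test_ring_inflation_matches_ode_oracle(self, ring_solution,
                                               ring_oracle):
        """Mid-wall hoop Cauchy stress within 2% of the incompressible
        radial-equilibrium ODE oracle at 100 mmHg."""
        hoop = midwall_hoop_stress(ring_solution)
        ref = ring_oracle["hoop_stress"](0.5 * (RING_RI + RING_RO))
        assert hoop == pytest.approx(ref, rel=0.02)

    def test_ring_lumen_area_matches_oracle(self, ring_solution, ring_oracle):
        area = fem.deformed_lumen_area(ring_solution)
        assert area == pytest.approx(ring_oracle["lumen_area"], rel=0.01)

    def test_small_load_matches_lame_isotropic(self, ring_slice_session):
        """Calcification (isotropic) ring at 0.1 kPa vs the classical Lamé
        thick-wall closed form (modulus-free stresses)."""
        mesh = fem.build_mesh(ring_slice_session, 0.2)
        sol = fem.solve_static(mesh,
                               {"wall": ct.material_preset("calcification")},
                               fem.SolveConfig(pressure=0.1, load_steps=1))
        hoop = midwall_hoop_stress(sol)
        ref = bm.lame_hoop_stress(RING_RI, RING_RO, 0.1, 2.25)
        assert hoop == pytest.approx(ref, rel=0.05)

    def test_small_load_matches_orthotropic_closed_form(
            self, ring_slice_session, vessel_mat):
        """Vessel preset (circumferential fiber -> cylindrically orthotropic
        tangent) vs the Lekhnitskii power-law ring solution."""
        mesh = fem.build_mesh(ring_slice_session, 0.2)
        sol = fem.solve_static(mesh, {"wall": vessel_mat},
                               fem.SolveConfig(pressure=0.1, load_steps=1))
        hoop = midwall_hoop_stress(sol)
        ref = bm.orthotropic_ring_hoop_stress(vessel_mat, RING_RI, RING_RO,
                                              0.1, 2.25)
        assert hoop == pytest.approx(ref, rel=0.05)

    def test_global_equilibrium(self, ring_solution):
        """The assembled follower load is self-equilibrated: net force of
        the external vector vanishes relative to its magnitude."""
        f = ring_solution.external_force.reshape(-1, 2)
        net = np.abs(f.sum(axis=0)).max()
        scale = np.abs(f).sum()
        assert net / scale < 1e-8
        assert ring_solution.residual_norm < 1e-6

    def test_follower_linearity_at_small_load(self, ring_mesh, vessel_mat):
        u1 = fem.solve_static(ring_mesh, {"wall": vessel_mat},
                              fem.SolveConfig(pressure=0.02, load_steps=1)
                              ).displacements
        u2 = fem.solve_static(ring_mesh, {"wall": vessel_mat},
                              fem.SolveConfig(pressure=0.04, load_steps=1)
                              ).displacements
        ratio = np.abs(u2).max() / np.abs(u1).max()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_lumen_area_increases_with_pressure(self, ring_mesh, vessel_mat):
        areas = [fem.deformed_lumen_area(fem.solve_static(
            ring_mesh, {"wall": vessel_mat},
            fem.SolveConfig(pressure=p, load_steps=5)))
            for p in (2.0, 6.0, 12.0)]
        assert areas[0] < areas[1] < areas[2]

    def test_lipid_raises_cap_stress(self):
        """A thin-cap lipid slice carries higher peak PWS than the same
        geometry with the lipid replaced by wall tissue."""
        sl = lipid_slice()
        mesh = fem.build_mesh(sl, 0.2)
        cfg = fem.SolveConfig(pressure=mmhg_to_kpa(110.0), load_steps=8)
        wall = ct.material_preset("vessel")
        soft = fem.solve_static(mesh, {"wall": wall,
                                       "lipid": ct.material_preset("lipid")},
                                cfg)
        stiff = fem.solve_static(mesh, {"wall": wall, "lipid": wall}, cfg)
        assert fem.sample_lumen(soft).PWS.max() \
            > fem.sample_lumen(stiff).PWS.max()

    def test_missing_material_raises(self, ring_mesh):
        with pytest.raises(ValueError):
            fem.solve_static(ring_mesh, {},
                             fem.SolveConfig(pressure=1.0))


class TestThinLayer:
    def test_unit_stretch_equals_plane_strain(self, ring_mesh, vessel_mat,
                                              ring_slice_session):
        """TL with lambda_z = 1 reduces exactly to the 2D plane-strain
        solve (same discrete problem)."""
        cfg2d = fem.SolveConfig(pressure=5.0, load_steps=4)
        cfgtl = fem.SolveConfig(pressure=5.0, load_steps=4,
                                variant=fem.THIN_LAYER, axial_stretch=1.0)
        s2d = fem.solve_static(ring_mesh, {"wall": vessel_mat}, cfg2d)
        stl = fem.thin_layer_solve(ring_slice_session, {"wall": vessel_mat},
                                   cfgtl, mesh=ring_mesh)
        assert np.abs(stl.displacements - s2d.displacements).max() < 1e-8

    def test_axial_stretch_generates_axial_stress(self, ring_mesh,
                                                  vessel_mat,
                                                  ring_slice_session):
        cfg = fem.SolveConfig(pressure=5.0, load_steps=4,
                              variant=fem.THIN_LAYER,
                              axial_stretch=1.0 / 0.9)
        sol = fem.thin_layer_solve(ring_slice_session, {"wall": vessel_mat},
                                   cfg, mesh=ring_mesh)
        assert np.abs(sol.cauchy[:, 2, 2]).max() > 1.0   # kPa

    def test_hoop_stress_differs_from_plane_strain(self, ring_mesh,
                                                   vessel_mat,
                                                   ring_slice_session):
        cfg2d = fem.SolveConfig(pressure=RING_PRESSURE_KPA, load_steps=6)
        cfgtl = fem.SolveConfig(pressure=RING_PRESSURE_KPA, load_steps=6,
                                variant=fem.THIN_LAYER,
                                axial_stretch=1.0 / 0.9)
        h2d = midwall_hoop_stress(
            fem.solve_static(ring_mesh, {"wall": vessel_mat}, cfg2d))
        htl = midwall_hoop_stress(
            fem.thin_layer_solve(ring_slice_session, {"wall": vessel_mat},
                                 cfgtl, mesh=ring_mesh))
        assert h2d != pytest.approx(htl, rel=1e-3)

    def test_wrong_variant_rejected(self, ring_slice_session, vessel_mat):
        with pytest.raises(ValueError):
            fem.thin_layer_solve(ring_slice_session, {"wall": vessel_mat},
                                 fem.SolveConfig(pressure=1.0))


class TestSampleLumen:
    def test_axisymmetric_pws_nearly_constant(self, ring_solution):
        prof = fem.sample_lumen(ring_solution)
        assert prof.n == 100
        assert prof.PWS.std() / prof.PWS.mean() < 0.02
        assert np.all(prof.PWSn >= -0.5)

    def test_rotation_equivariance(self, vessel_mat):
        """Rotating the slice by 90 deg cyclically shifts the PWS array by
        n/4 (within one index)."""
        sl = lipid_slice(seed=12)
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        rot = sl.transformed(lambda p: (R @ np.asarray(p).T).T)
        cfg = fem.SolveConfig(pressure=8.0, load_steps=5)
        mats = {"wall": vessel_mat, "lipid": ct.material_preset("lipid")}
        p0 = fem.sample_lumen(fem.solve_static(fem.build_mesh(sl, 0.2),
                                               mats, cfg)).PWS
        p90 = fem.sample_lumen(fem.solve_static(fem.build_mesh(rot, 0.2),
                                                mats, cfg)).PWS
        shifts = [np.abs(np.roll(p90, -(25 + d)) - p0).mean()
                  for d in (-1, 0, 1)]
        baseline = np.abs(p90 - p0).mean()
        assert min(shifts) < 0.25 * baseline

    def test_small_n_principal_values_by_hand(self, ring_solution):
        """n = 4 samples reproduce principal_max of the interpolated nodal
        tensors evaluated directly."""
        prof = fem.sample_lumen(ring_solution, n=4)
        assert prof.n == 4
        for k in range(4):
            # each sampled PWS must lie within the range of nodal principal
            # values on the lumen loop (interpolation cannot overshoot)
            loop_sig = ring_solution.nodal_cauchy[
                ring_solution.mesh.lumen_loop]
            pmax = np.linalg.eigvalsh(loop_sig)[:, -1]
            assert pmax.min() - 1e-9 <= prof.PWS[k] <= pmax.max() + 1e-9

    def test_nonconverged_rejected(self, ring_solution):
        import copy
        bad = copy.copy(ring_solution)
        bad.converged = False
        with pytest.raises(ValueError):
            fem.sample_lumen(bad)


class TestMeshConvergence:
    def test_ring_benchmark_terminates_and_matches_oracle(self, vessel_mat,
                                                          ring_oracle,
                                                          ring_slice_session):
        """10% refinement steps, <1% stopping rule; the converged mean PWS
        agrees with the inner-surface hoop stress of the ODE oracle."""
        cfg = fem.SolveConfig(pressure=RING_PRESSURE_KPA, load_steps=6)
        sol, table = fem.mesh_convergence(ring_slice_session,
                                          {"wall": vessel_mat}, cfg,
                                          start_h=0.35, max_refinements=6)
        assert len(table) <= 7
        assert table["rel_change"].iloc[-1] < 0.01
        assert table["n_elements"].is_monotonic_increasing
        # h shrinks by 10% per refinement
        h = table["h_mm"].to_numpy()
        assert np.allclose(h[1:] * 1.1, h[:-1], rtol=1e-12)
        mean_pws = table["mean_PWS_kPa"].iloc[-1]
        ref = ring_oracle["hoop_stress"](RING_RI)
        assert mean_pws == pytest.approx(ref, rel=0.02)


class TestExport:
    def test_vtk_and_profile_csv(self, tmp_path, ring_solution):
        fem.write_vtk(tmp_path / "ring.vtk", ring_solution)
        txt = (tmp_path / "ring.vtk").read_text()
        assert txt.startswith("# vtk DataFile")
        assert "VECTORS displacement" in txt
        prof = fem.sample_lumen(ring_solution)
        fem.profile_to_csv(prof, tmp_path / "prof.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "prof.csv")
        assert list(df.columns) == ["point_index", "arc_s", "x", "y",
                                    "PWS_kPa", "PWSn", "FSS_dyncm2"]
        assert len(df) == 100
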