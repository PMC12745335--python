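"""Forward-penalty stress: patch/Laplace benchmarks, determinacy, mapping."""

import numpy as np
import pytest

import aortagrow as ag
from aortagrow import fem
from aortagrow import stress as st


class TestFEMBenchmarks:
    def test_single_hex_patch_is_exact(self):
        # uniaxial traction on a unit cube with symmetric supports
        nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                          [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
        hexes = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
        fixed = []
        for i, (x, y, z) in enumerate(nodes):
            if x == 0:
                fixed.append(3 * i)
            if y == 0:
                fixed.append(3 * i + 1)
            if z == 0:
                fixed.append(3 * i + 2)
        forces = fem.traction_forces(nodes, np.array([[1, 2, 6, 5]]),
                                     np.array([10.0]), np.array([[1.0, 0, 0]]))
        assert np.allclose(forces[:, 0].sum(), 10.0)
        res = fem.solve_elasticity(nodes, hexes, np.array([1000.0]), 0.3,
                                   forces, np.array(fixed))
        assert np.allclose(res.node_stress[:, 0], 10.0, rtol=1e-8)
        assert np.abs(res.node_stress[:, 1:]).max() < 1e-8
        assert np.allclose(res.displacement[1, 0], 0.01, rtol=1e-8)

    def test_zero_load_gives_zero_everything(self, cylinder_fixture):
        tr = np.zeros(len(cylinder_fixture.load_facets))
        f = st.forward_penalty_stress(cylinder_fixture, tr, fixed_ends="axial")
        assert np.abs(f.displacement).max() == 0.0
        assert np.abs(f.max_principal).max() == 0.0

    def test_laplace_limit_mid_wall_hoop(self, cylinder_fixture, laplace_solution):
        field = laplace_solution["field"]
        p = laplace_solution["pressure_kpa"]
        expected = p * 14.0 / 2.0          # P r_i / t thin-wall estimate
        z = cylinder_fixture.nodes[:, 2]
        mid = (z > 30.0) & (z < 70.0)      # away from end restraints
        mean_hoop = field.max_principal[mid].mean()
        assert abs(mean_hoop - expected) / expected < 0.05

    def test_penalty_displacement_is_negligible(self, laplace_solution):
        assert laplace_solution["field"].max_displacement <= 1e-2

    def test_uniform_stiffness_rescale_leaves_stress(self, cylinder_fixture,
                                                     laplace_solution):
        base = laplace_solution["field"]
        p = laplace_solution["pressure_kpa"]
        tr = np.full(len(cylinder_fixture.load_facets), p)
        doubled = st.forward_penalty_stress(
            cylinder_fixture, tr,
            st.MaterialSpec(E_wall=1.0e6, E_thrombus=5.0e4),
            fixed_ends="axial")
        scale = np.abs(base.max_principal).max()
        assert np.abs(doubled.max_principal - base.max_principal).max() < 1e-9 * scale
        assert np.isclose(doubled.max_displacement,
                          base.max_displacement / 2.0, rtol=1e-9)

    def test_mesh_refinement_changes_peak_von_mises_little(self):
        p = 16.0
        results = []
        for n_circ, n_axial in ((32, 24), (64, 48)):
            cyl = ag.make_cylinder_fixture(r=14.0, t=2.0, L=100.0, n_layers=4,
                                           n_circ=n_circ, n_axial=n_axial)
            tr = np.full(len(cyl.load_facets), p)
            f = st.forward_penalty_stress(cyl, tr, fixed_ends="axial")
            z = cyl.nodes[:, 2]
            results.append(f.von_mises[(z > 30) & (z < 70)].max())
        coarse, fine = results
        assert abs(fine - coarse) / fine < 0.02


class TestPressureMapping:
    def _samples(self, pressures, zs, lumen=0):
        n = len(pressures)
        pts = np.column_stack([np.full(n, 14.0), np.zeros(n), zs])
        return type("F", (), {"points": pts,
                              "pressure_mmhg": np.asarray(pressures, float),
                              "lumen": np.full(n, lumen)})()

    def test_uniform_field_maps_to_uniform_tractions(self, cylinder_fixture):
        field = self._samples([120.0] * 8, np.linspace(0, 100, 8))
        tr = st.map_pressure_to_solid(field, cylinder_fixture)
        assert np.allclose(tr, 120.0 * st.MMHG_TO_KPA, rtol=1e-12)
        assert np.isclose(tr[0], 16.0, atol=0.01)    # 120 mmHg ~ 16 kPa

    def test_axial_ramp_reproduced(self, cylinder_fixture):
        zs = np.linspace(0.0, 100.0, 51)
        field = self._samples(100.0 + zs, zs)
        tr = st.map_pressure_to_solid(field, cylinder_fixture, k=2)
        centers = cylinder_fixture.nodes[cylinder_fixture.load_facets].mean(axis=1)
        expected = (100.0 + centers[:, 2]) * st.MMHG_TO_KPA
        assert np.abs(tr - expected).max() < 2.5 * st.MMHG_TO_KPA

    def test_flap_loaded_from_both_lumens(self, dissected_scene, dissected_solid):
        na, nc = dissected_scene.grid.shape[:2]
        pts = dissected_scene.grid.reshape(-1, 3)
        lum = np.zeros((na, nc), dtype=int)
        fl = dissected_scene.flap
        for j in fl.axial_indices:
            lum[j, fl.false_side_columns] = 1
        field = type("F", (), {
            "points": pts,
            "pressure_mmhg": np.where(lum.ravel() == 1, 110.0, 120.0),
            "lumen": lum.ravel()})()
        tr = st.map_pressure_to_solid(field, dissected_solid)
        tl = tr[dissected_solid.facet_lumen == 0]
        flv = tr[dissected_solid.facet_lumen == 1]
        assert np.allclose(tl, 120.0 * st.MMHG_TO_KPA, rtol=1e-9)
        assert np.allclose(flv, 110.0 * st.MMHG_TO_KPA, rtol=1e-9)
        # net flap load: 10 mmHg toward the false lumen
        assert np.isclose(tl.mean() - flv.mean(), 10.0 * st.MMHG_TO_KPA)

    def test_empty_samples_raise(self, cylinder_fixture):
        field = type("F", (), {"points": np.zeros((0, 3)),
                               "pressure_mmhg": np.zeros(0),
                               "lumen": np.zeros(0)})()
        with pytest.raises(ValueError):
            st.map_pressure_to_solid(field, cylinder_fixture)


class TestSensitivity:
    def test_uniform_scaling_gives_zero_mape(self, dissected_solid,
                                             dissected_tractions):
        base = st.forward_penalty_stress(dissected_solid, dissected_tractions)
        scaled = st.forward_penalty_stress(
            dissected_solid, dissected_tractions,
            region_factors={r: 1.5 for r in
                            ("tl_wall", "fl_wall", "flap", "thrombus")})
        scale = np.abs(base.max_principal).max()
        assert np.abs(scaled.max_principal - base.max_principal).max() < 1e-8 * scale

    def test_single_region_perturbations_stay_small(self, dissected_solid,
                                                    dissected_tractions):
        tab = st.stiffness_sensitivity(dissected_solid, dissected_tractions,
                                       regions=("flap",))
        assert (tab["mape_max_principal_pct"] <= 10.0).all()


class TestRegisterToStructured:
    def test_coincident_nodes_copy_exactly(self, straight_tube_structured):
        pts = straight_tube_structured.points()
        vals = np.arange(len(pts), dtype=float)
        out = st.register_stress_to_structured(vals, pts,
                                               straight_tube_structured)
        assert np.array_equal(out.ravel(), vals)

    def test_uniform_field_stays_uniform(self, straight_tube_structured,
                                         dissected_solid):
        vals = np.full(dissected_solid.n_nodes, 7.25)
        out = st.register_stress_to_structured(vals, dissected_solid.nodes,
                                               straight_tube_structured)
        assert np.allclose(out, 7.25)

    def test_axial_gradient_reproduced(self, straight_tube_structured,
                                       dissected_solid):
        vals = dissected_solid.nodes[:, 2].copy()      # field = z coordinate
        out = st.register_stress_to_structured(vals, dissected_solid.nodes,
                                               straight_tube_structured)
        z_nodes = straight_tube_structured.nodes[..., 2]
        spacing = 200.0 / 39                            # solid axial spacing
        assert np.abs(out - z_nodes).max() < 1.5 * spacing

    def test_empty_inputs_raise(self, straight_tube_structured):
        with pytest.raises(ValueError):
            st.register_stress_to_structured(np.zeros(0), np.zeros((0, 3)),
                                             straight_tube_structured)


def test_material_spec_validation():
    assert st.MaterialSpec().E_wall / st.MaterialSpec().E_thrombus == 20.0
    with pytest.raises(ValueError):
        st.MaterialSpec(poisson=0.6)
    with pytest.raises(ValueError):
        st.MaterialSpec(E_wall=-1.0)
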