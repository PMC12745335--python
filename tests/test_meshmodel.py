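"""Structured parameterization, frames, diameters, partitions, solid mesh."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import aortagrow as ag
from aortagrow import fem
from aortagrow.meshmodel import (StructuredSurface, ThicknessSpec,
                                 layer_diameters, local_frames,
                                 parameterize_surface, partition_regions,
                                 structured_triangles)


def _circle_surface(radius=12.0, n_layers=20, n_circ=50, z_step=2.0):
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    nodes = np.empty((n_layers, n_circ, 3))
    for j in range(n_layers):
        nodes[j, :, 0] = radius * np.cos(theta)
        nodes[j, :, 1] = radius * np.sin(theta)
        nodes[j, :, 2] = j * z_step
    return StructuredSurface(nodes, landmark_layer=min(5, n_layers))


class TestParameterize:
    def test_straight_tube_radii(self, straight_tube_structured):
        s = straight_tube_structured
        assert s.nodes.shape == (200, 50, 3)
        r = np.linalg.norm(s.nodes - s.layer_centers[:, None, :], axis=2)
        assert np.allclose(r, 15.0, atol=0.05)

    def test_cone_radii_linear_in_layer_index(self):
        scene = ag.make_dissected_aorta(
            ag.AortaSpec(shape="straight", radius=10.0, distal_radius=20.0,
                         length=200.0, flap_angle=None))
        s = parameterize_surface(scene)
        d = layer_diameters(s)
        expected = 2.0 * (10.0 + 10.0 * s.layer_arclengths / 200.0)
        assert np.allclose(d, expected, rtol=5e-3)

    def test_reparameterization_is_idempotent(self, straight_tube_structured):
        v, f = structured_triangles(straight_tube_structured)
        z0, z1 = v[:, 2].min(), v[:, 2].max()   # open tube: stay inside
        centerline = np.column_stack([np.zeros(50), np.zeros(50),
                                      np.linspace(z0, z1, 50)])
        again = parameterize_surface((v, f), centerline)
        # interior layers land back on the same cylinder of nodes
        r0 = np.linalg.norm(straight_tube_structured.nodes[5:-5]
                            - straight_tube_structured.layer_centers[5:-5, None, :], axis=2)
        r1 = np.linalg.norm(again.nodes[5:-5] - again.layer_centers[5:-5, None, :], axis=2)
        assert np.allclose(r0, r1, atol=0.05)

    def test_non_tube_input_raises(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2]])
        centerline = np.array([[0, 0, -5.0], [0, 0, 5.0]])
        with pytest.raises(ValueError, match="tube"):
            parameterize_surface((verts, faces), centerline)


class TestLocalFrames:
    def test_straight_tube_axial_is_global_axis(self, straight_tube_structured):
        fr = straight_tube_structured.frames
        axial = fr[:, :, 2, :]
        assert np.allclose(axial, [0.0, 0.0, 1.0], atol=1e-6)

    def test_orthonormal_everywhere(self, straight_tube_structured):
        fr = straight_tube_structured.frames
        gram = np.einsum("jiab,jicb->jiac", fr, fr)
        assert np.abs(gram - np.eye(3)).max() < 1e-8
        # right-handed: radial x circumferential = axial
        rxc = np.cross(fr[:, :, 0, :], fr[:, :, 1, :])
        assert np.allclose(rxc, fr[:, :, 2, :], atol=1e-8)

    def test_bend_axial_follows_arc_tangent(self):
        scene = ag.make_dissected_aorta(ag.AortaSpec(flap_angle=None))
        s = parameterize_surface(scene)
        # analytic tangent from the centerline
        t_true = np.gradient(s.layer_centers, axis=0)
        t_true /= np.linalg.norm(t_true, axis=1, keepdims=True)
        axial = s.frames[:, :, 2, :].mean(axis=1)
        axial /= np.linalg.norm(axial, axis=1, keepdims=True)
        dots = np.sum(axial[1:-1] * t_true[1:-1], axis=1)
        # tolerance: two layer-to-layer turn angles of the arch
        spec = ag.AortaSpec()
        step = (s.layer_arclengths[1] - s.layer_arclengths[0]) / spec.arch_radius
        assert dots.min() > np.cos(2.0 * step)

    def test_degenerate_centers_raise(self):
        s = _circle_surface(n_layers=3, z_step=0.0)       # coincident layers
        with pytest.raises(ValueError, match="degenerate|coincident"):
            local_frames(StructuredSurface(s.nodes, landmark_layer=2))


class TestLayerDiameters:
    def test_circle(self):
        assert np.allclose(layer_diameters(_circle_surface(12.0)), 24.0)

    def test_ellipse_mean_radius(self):
        a, b = 10.0, 20.0
        theta = 2 * np.pi * np.arange(50) / 50
        nodes = np.zeros((2, 50, 3))
        for j in range(2):
            nodes[j, :, 0] = a * np.cos(theta)
            nodes[j, :, 1] = b * np.sin(theta)
            nodes[j, :, 2] = float(j)
        s = StructuredSurface(nodes, landmark_layer=1)
        expected = 2.0 * np.hypot(a * np.cos(theta), b * np.sin(theta)).mean()
        assert np.allclose(layer_diameters(s), expected)

    def test_rigid_motion_invariance(self):
        from aortagrow.registration import RigidTransform

        s = _circle_surface(12.0)
        rig = RigidTransform.about_axis("x", 33.0, t=(5.0, 6.0, 7.0))
        moved = StructuredSurface(rig.apply(s.points()).reshape(s.nodes.shape),
                                  landmark_layer=s.landmark_layer)
        assert np.allclose(layer_diameters(moved), layer_diameters(s), atol=1e-9)


class TestPartition:
    def test_landmark_49_gives_uniform_regions(self):
        p = partition_regions(49)
        sizes = np.array(p.stops) - np.array(p.starts) + 1
        assert p.n_regions == 50
        assert np.all(sizes == 4)
        assert p.n_descending == 38
        assert p.starts[12] == 49 and p.stops[-1] == 200

    def test_landmark_42_near_equal_blocks(self):
        p = partition_regions(42)
        sizes = np.array(p.stops) - np.array(p.starts) + 1
        asc, desc = sizes[:12], sizes[12:]
        assert p.stops[11] == 41 and p.starts[12] == 42
        assert asc.max() - asc.min() <= 1
        assert desc.max() - desc.min() <= 1
        assert sizes.sum() == 200

    def test_boundary_landmark_13_is_valid(self):
        p = partition_regions(13)
        sizes = np.array(p.stops) - np.array(p.starts) + 1
        assert np.all(sizes[:12] == 1)

    @pytest.mark.parametrize("bad", [12, 164, 1, 200])
    def test_out_of_range_landmarks_raise(self, bad):
        with pytest.raises(ValueError):
            partition_regions(bad)

    @settings(max_examples=40, deadline=None)
    @given(hst.integers(min_value=13, max_value=163))
    def test_partition_tiles_layers(self, landmark):
        p = partition_regions(landmark)
        covered = np.concatenate([p.layers(k + 1) for k in range(p.n_regions)])
        assert np.array_equal(covered, np.arange(200))
        sizes = np.array(p.stops) - np.array(p.starts) + 1
        assert sizes[:12].max() - sizes[:12].min() <= 1
        assert sizes[12:].max() - sizes[12:].min() <= 1


class TestSolidMesh:
    def test_tube_offsets_and_counts(self, straight_tube_scene):
        solid = ag.build_solid_mesh(straight_tube_scene)
        na, nc = straight_tube_scene.grid.shape[:2]
        assert solid.n_nodes == na * nc * 5        # 4 hex layers -> 5 sheets
        assert solid.n_elements == (na - 1) * nc * 4
        r = np.hypot(solid.nodes[:, 0], solid.nodes[:, 1])
        assert abs(r.min() - 14.0) < 1e-6          # 1 mm inward offset
        assert abs(r.max() - 16.0) < 1e-6          # 1 mm outward offset
        assert set(solid.material.tolist()) == {"wall"}

    def test_thickness_spec_consistency(self):
        with pytest.raises(ValueError, match="true_lumen_wall"):
            ThicknessSpec(true_lumen_wall=3.0, false_lumen_wall=1.0, flap=1.0)

    def test_all_jacobians_positive(self, dissected_solid):
        dj = fem.hex_jacobians(dissected_solid.nodes, dissected_solid.hexes)
        assert dj.min() > 0

    def test_excessive_offset_raises(self):
        scene = ag.make_dissected_aorta(
            ag.AortaSpec(shape="straight", radius=0.9, length=50.0,
                         flap_angle=None))
        with pytest.raises(ValueError, match="offset"):
            ag.build_solid_mesh(scene)

    def test_flap_junction_is_conforming(self, dissected_scene, dissected_solid):
        # flap elements share node ids with wall elements
        flap_nodes = set(np.unique(
            dissected_solid.hexes[dissected_solid.region == "flap"]).tolist())
        wall_nodes = set(np.unique(
            dissected_solid.hexes[dissected_solid.region != "flap"]).tolist())
        assert flap_nodes & wall_nodes


class TestAvgGrowth:
    def test_identical_surfaces_give_zero(self, straight_tube_structured):
        assert ag.avg_descending_growth(straight_tube_structured,
                                        straight_tube_structured, 2.0) == 0.0

    def test_uniform_two_mm_per_year(self):
        base = _circle_surface(12.0, n_layers=100)
        follow = _circle_surface(13.0, n_layers=100)
        assert np.isclose(ag.avg_descending_growth(base, follow, 1.0), 2.0)

    def test_half_length_growth_averages(self):
        base = _circle_surface(12.0, n_layers=100)
        nodes = base.nodes.copy()
        scale = np.where(np.arange(100) >= base.landmark_layer - 1 + 48, 14.0 / 12.0, 1.0)
        nodes[:, :, 0] *= scale[:, None]
        nodes[:, :, 1] *= scale[:, None]
        follow = StructuredSurface(nodes, landmark_layer=base.landmark_layer)
        # descending = layers 5..100 (96 layers); +4 mm on the last 48 over 2 yr
        expected = 4.0 * 48 / 96 / 2.0
        assert np.isclose(ag.avg_descending_growth(base, follow, 2.0), expected)

    def test_nonpositive_years_raise(self, straight_tube_structured):
        with pytest.raises(ValueError):
            ag.avg_descending_growth(straight_tube_structured,
                                     straight_tube_structured, 0.0)
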