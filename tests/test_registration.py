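"""Rigid/nonrigid registration and growth-strain conversion."""

import numpy as np
import pytest

import aortagrow as ag
from aortagrow.registration import (Deformation, RigidTransform,
                                    _face_centers_normals, _varifold_data_grad,
                                    _varifold_inner, growth_strain, icp_align,
                                    nonrigid_register, varifold_distance)


def _random_cloud(rng, n=200):
    return rng.normal(size=(n, 3)) * np.array([20.0, 10.0, 40.0])


class TestICP:
    def test_identity_on_identical_clouds(self):
        rng = np.random.default_rng(0)
        pts = _random_cloud(rng)
        got = icp_align(pts, pts)
        assert np.abs(got.R - np.eye(3)).max() < 1e-6
        assert np.abs(got.t).max() < 1e-6

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        pts = _random_cloud(rng)
        true = RigidTransform.about_axis("z", 30.0, t=(5.0, 0.0, 0.0))
        got = icp_align(pts, true.apply(pts))
        assert np.abs(got.R - true.R).max() < 1e-3
        assert np.abs(got.t - true.t).max() < 1e-3

    def test_axis_rotation_fallback_handles_gross_misalignment(self):
        # 30-degree misalignment about x: one of the manual axis
        # pre-rotations starts at the exact pose, so the fallback search
        # must converge to the true transform regardless of the identity
        # basin
        rng = np.random.default_rng(7)
        pts = _random_cloud(rng, 400)
        true = RigidTransform.about_axis("x", 30.0, t=(0.0, 2.0, 1.0))
        got = icp_align(pts, true.apply(pts), try_axis_rotations=True)
        assert np.abs(got.R - true.R).max() < 1e-3
        assert np.abs(got.t - true.t).max() < 1e-3

    def test_degenerate_inputs_raise(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            icp_align(line, line)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestVarifold:
    def test_zero_on_identical_surfaces(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(12, 3))
        f = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]])
        assert varifold_distance((v, f), (v, f), 20.0) == 0.0

    def test_two_facet_closed_form(self):
        # same normal, centers d apart: D = 2 W (1 - exp(-d^2/w^2))
        d, w = 7.0, 20.0
        t1 = (np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
              np.array([[0, 1, 2]]))
        t2 = (np.array([[d, 0, 0], [d + 1, 0, 0], [d, 1, 0]], float),
              np.array([[0, 1, 2]]))
        W = 0.5 ** 2   # squared facet area weight
        expected = 2.0 * W * (1.0 - np.exp(-d ** 2 / w ** 2))
        assert np.isclose(varifold_distance(t1, t2, w), expected, rtol=1e-12)

    def test_symmetry_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            v1 = rng.normal(size=(9, 3))
            v2 = rng.normal(size=(9, 3)) + 0.5
            f = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
            a = varifold_distance((v1, f), (v2, f), 10.0)
            b = varifold_distance((v2, f), (v1, f), 10.0)
            assert np.isclose(a, b, rtol=1e-10)
            assert a >= 0.0

    def test_zero_normal_raises(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)  # collinear
        f = np.array([[0, 1, 2]])
        with pytest.raises(ValueError, match="normal"):
            varifold_distance((v, f), (v, f), 10.0)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        VT = rng.normal(size=(9, 3))
        FT = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8], [0, 4, 8]])
        VS = rng.normal(size=(6, 3)) + 0.3
        FS = np.array([[0, 1, 2], [3, 4, 5]])
        cs, ns = _face_centers_normals(VS, FS)
        a_s = np.linalg.norm(ns, axis=1)
        ss = _varifold_inner(cs, ns, cs, ns, 2.0)
        _, grad = _varifold_data_grad(VT, FT, cs, ns, a_s, 2.0, ss)
        eps = 1e-6
        for i in (0, 4, 8):
            for j in range(3):
                vp, vm = VT.copy(), VT.copy()
                vp[i, j] += eps
                vm[i, j] -= eps
                fp, _ = _varifold_data_grad(vp, FT, cs, ns, a_s, 2.0, ss)
                fm, _ = _varifold_data_grad(vm, FT, cs, ns, a_s, 2.0, ss)
                fd = (fp - fm) / (2 * eps)
                assert abs(fd - grad[i, j]) < 1e-6 * max(abs(fd), 1.0)


class TestNonrigid:
    def test_identity_target_keeps_momenta_small(self, straight_tube_structured):
        dfm, deformed, info = nonrigid_register(
            straight_tube_structured, straight_tube_structured, max_iter=30)
        disp = np.linalg.norm(deformed - straight_tube_structured.nodes, axis=2)
        assert disp.max() < 1e-9
        assert np.abs(dfm.momenta).max() < 1e-12
        # residual cost is at the arithmetic noise floor of the large
        # self-terms, i.e. vanishing relative to the surface measure
        from aortagrow.meshmodel import structured_triangles

        v, f = structured_triangles(straight_tube_structured, 4, 2)
        from aortagrow.registration import _face_centers_normals

        c, n = _face_centers_normals(v, f)
        self_term = _varifold_inner(c, n, c, n, 20.0)
        assert abs(info["final_cost"]) < 1e-6 * self_term

    def test_cost_not_above_initial(self, straight_tube_structured):
        grown = ag.grow_aorta(straight_tube_scene_or(straight_tube_structured),
                              ag.GrowthField.uniform(1.05))
        target = ag.parameterize_surface(grown)
        from aortagrow.meshmodel import structured_triangles

        v0, f0 = structured_triangles(straight_tube_structured, 4, 2)
        v1, f1 = structured_triangles(target, 4, 2)
        initial = varifold_distance((v0, f0), (v1, f1), 20.0)
        _, _, info = nonrigid_register(straight_tube_structured, target)
        assert info["final_cost"] <= initial

    def test_uniform_dilation_recovers_radial_displacement(
            self, straight_tube_structured):
        grown = ag.grow_aorta(straight_tube_scene_or(straight_tube_structured),
                              ag.GrowthField.uniform(1.05))
        target = ag.parameterize_surface(grown)
        _, deformed, _ = nonrigid_register(straight_tube_structured, target)
        base = straight_tube_structured.nodes
        # analytic displacement: 5% of the radial offset
        analytic = 0.05 * (base - straight_tube_structured.layer_centers[:, None, :])
        got = deformed - base
        mid = slice(20, 180)
        err = np.linalg.norm(got[mid] - analytic[mid], axis=2)
        mag = np.linalg.norm(analytic[mid], axis=2)
        assert (err / mag).mean() < 0.10

    def test_deformation_validates(self):
        with pytest.raises(ValueError):
            Deformation(np.zeros((0, 3)), np.zeros((0, 3)), 20.0)
        with pytest.raises(ValueError):
            Deformation(np.zeros((2, 3)), np.zeros((2, 3)), -1.0)


def straight_tube_scene_or(structured):
    """Rebuild the canonical straight tube scene used by the fixture."""
    return ag.make_dissected_aorta(
        ag.AortaSpec(shape="straight", radius=15.0, length=200.0,
                     flap_angle=None))


class TestGrowthStrain:
    def test_uniform_dilation_closed_form(self, straight_tube_structured):
        s = straight_tube_structured
        deformed = (s.layer_centers[:, None, :]
                    + 1.1 * (s.nodes - s.layer_centers[:, None, :]))
        gm = growth_strain(s, deformed, years=2.0)
        expected = 100.0 * np.log(1.1) / 2.0     # 4.77 %/year
        assert np.allclose(gm.rates[gm.valid], expected, atol=1e-8)

    def test_identity_gives_zero(self, straight_tube_structured):
        gm = growth_strain(straight_tube_structured,
                           straight_tube_structured.nodes, years=3.0)
        assert np.allclose(gm.rates, 0.0)
        assert gm.valid.all()

    def test_prescribed_field_with_perfect_correspondence(
            self, straight_tube_structured):
        s = straight_tube_structured
        gf = ag.GrowthField.sigmoid(1.0, 1.2, s_mid=100.0, width=20.0,
                                    duration=2.0)
        stretch = gf.stretch(s.layer_arclengths)
        deformed = (s.layer_centers[:, None, :]
                    + stretch[:, None, None] * (s.nodes - s.layer_centers[:, None, :]))
        gm = growth_strain(s, deformed, years=2.0)
        expected = 100.0 * np.log(stretch) / 2.0
        assert np.abs(gm.rates - expected[:, None]).max() < 0.01 * np.abs(expected).max()

    def test_negative_growth_permitted(self, straight_tube_structured):
        s = straight_tube_structured
        deformed = (s.layer_centers[:, None, :]
                    + 0.95 * (s.nodes - s.layer_centers[:, None, :]))
        gm = growth_strain(s, deformed, years=1.0)
        assert np.all(gm.rates[gm.valid] < 0.0)

    def test_invalid_years_raise(self, straight_tube_structured):
        with pytest.raises(ValueError):
            growth_strain(straight_tube_structured,
                          straight_tube_structured.nodes, years=0.0)
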