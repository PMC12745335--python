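"""Region sampling, thrombus rules, and the mixed-effects model."""

import numpy as np
import pandas as pd
import pytest

import aortagrow as ag
from aortagrow.meshmodel import StructuredSurface, partition_regions
from aortagrow.mixedlm import GrowthLME, ftest_fixed_slope
from aortagrow.regions import (pearson_by_patient, region_average,
                               thrombus_presence, thrombus_region_indicator)
from aortagrow.synthetic import CohortSpec, make_cohort


@pytest.fixture(scope="module")
def partition():
    return partition_regions(49)


class TestRegionAverage:
    def test_constant_field(self, partition):
        vals = np.full((200, 50), 3.5)
        assert np.allclose(region_average(vals, partition), 3.5)

    def test_layer_index_field_region13(self, partition):
        # field = 1-based layer index; region 13 = layers 49..52 -> 50.5
        vals = np.tile(np.arange(1, 201, dtype=float)[:, None], (1, 50))
        avg = region_average(vals, partition)
        assert np.isclose(avg[0], 50.5)

    def test_within_layer_permutation_invariance(self, partition):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(200, 50))
        perm = vals[:, rng.permutation(50)]
        assert np.allclose(region_average(vals, partition),
                           region_average(perm, partition))

    def test_all_invalid_region_gives_nan(self, partition):
        vals = np.ones((200, 50))
        valid = np.ones((200, 50), dtype=bool)
        valid[48:53] = False                   # kill region 13 (layers 49..52)
        avg = region_average(vals, partition, valid)
        assert np.isnan(avg[0]) and np.isfinite(avg[1:]).all()


class TestThrombus:
    def _tube(self, radius=15.0):
        theta = 2 * np.pi * np.arange(50) / 50
        nodes = np.empty((200, 50, 3))
        nodes[..., 0] = radius * np.cos(theta)
        nodes[..., 1] = radius * np.sin(theta)
        nodes[..., 2] = np.arange(200)[:, None]
        return StructuredSurface(nodes, landmark_layer=49)

    def test_coincident_point_is_present(self):
        s = self._tube()
        tb = thrombus_presence(s, s.nodes[100, 3][None, :])
        assert tb[100, 3] == 1

    def test_distant_points_all_absent(self):
        s = self._tube()
        tb = thrombus_presence(s, np.array([[500.0, 500.0, 500.0]]))
        assert tb.sum() == 0

    def test_hemi_annular_extent_follows_distance_rule(self):
        # thrombus points hugging the wall (radius 14) over the upper
        # half-circumference; the presence rule (distance < node local
        # radius 15) covers the arc plus an analytic angular margin
        # dtheta* = arccos(r_t / (2 r_n)) on either side
        s = self._tube()
        theta = np.linspace(0.0, np.pi, 80)
        layers = np.arange(80, 120)
        pts = []
        for z in layers:
            for t in theta:
                pts.append([14.0 * np.cos(t), 14.0 * np.sin(t), float(z)])
        tb = thrombus_presence(s, np.array(pts))
        covered = tb[90:110]
        node_theta = 2 * np.pi * np.arange(50) / 50
        margin = np.arccos(14.0 / (2.0 * 15.0))
        ang_dist = np.minimum(np.abs(node_theta - np.clip(node_theta, 0, np.pi)),
                              np.abs(2 * np.pi - node_theta))
        spacing = 2 * np.pi / 50
        definitely_in = ang_dist < margin - spacing
        definitely_out = ang_dist > margin + spacing
        assert covered[:, definitely_in].all()
        assert not covered[:, definitely_out].any()

    def test_no_thrombus_gives_absent_map(self):
        s = self._tube()
        assert thrombus_presence(s, None).sum() == 0

    @pytest.mark.parametrize("avg,expected", [(0.6, 1), (0.5, 0), (0.0, 0)])
    def test_indicator_strict_half_rule(self, partition, avg, expected):
        vals = np.zeros((200, 50))
        vals[48:52] = avg                     # region 13 exactly
        tb = thrombus_region_indicator(vals, partition)
        assert tb[0] == expected


class TestGrowthLME:
    def test_noise_free_line_recovered_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 10.0, 80)
        g = np.repeat(np.arange(4), 20)
        fit = GrowthLME(2 * x + 1, np.column_stack([np.ones(80), x]), g).fit()
        assert np.allclose(fit.fe_params.values, [1.0, 2.0], atol=1e-6)
        assert fit.sd_b0 < 1e-6 and fit.sd_b1 < 1e-6 and fit.sd_eps < 1e-6
        assert fit.boundary["sd_b1"]

    def test_two_patient_symmetric_lines(self):
        x = np.tile(np.linspace(1.0, 10.0, 20), 2)
        g = np.repeat([0, 1], 20)
        y = np.where(g == 0, x, 3 * x)
        fit = GrowthLME(y, np.column_stack([np.ones(40), x]), g).fit()
        assert np.isclose(fit.fe_params.iloc[1], 2.0, atol=1e-3)
        b1 = fit.blups["b1"].to_numpy()
        assert b1[0] < 0 < b1[1]
        assert np.isclose(b1[0], -b1[1], atol=1e-3)

    def test_agrees_with_statsmodels_mixedlm(self):
        import warnings

        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import (MixedLM,
                                                               MixedLMParams)

        coh = make_cohort(CohortSpec(seed=3))
        t = coh.table.copy()
        # standardize the predictor so statsmodels' optimizer is
        # well-conditioned; my implementation works on the raw scale
        mu, sd = t["stress_kpa"].mean(), t["stress_kpa"].std()
        t["z"] = (t["stress_kpa"] - mu) / sd
        mine = GrowthLME(t["growth_pct_per_year"].to_numpy(),
                         np.column_stack([np.ones(len(t)), t["z"]]),
                         t["patient_id"].to_numpy()).fit()
        X = sm.add_constant(t["z"].to_numpy())
        free = MixedLMParams.from_components(fe_params=np.ones(2),
                                             cov_re=np.eye(2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(t["growth_pct_per_year"], X, groups=t["patient_id"],
                          exog_re=X).fit(reml=False, free=free, method="lbfgs")
        assert np.allclose(mine.fe_params.values, ref.fe_params.values,
                           rtol=1e-3, atol=1e-3)
        # same (or better) maximized likelihood
        assert mine.llf >= ref.llf - 1e-3
        assert np.isclose(mine.sd_eps, np.sqrt(ref.scale), rtol=5e-2)

    def test_information_criteria_identities(self):
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=5)).table).fit()
        k = len(fit.fe_params) + 3
        assert np.isclose(fit.aic, -2 * fit.llf + 2 * k)
        assert np.isclose(fit.bic, -2 * fit.llf + k * np.log(fit.n_obs))

    def test_patient_relabeling_invariance(self):
        coh = make_cohort(CohortSpec(seed=8))
        t = coh.table
        fit1 = GrowthLME.from_dataframe(t).fit()
        relabeled = t.copy()
        mapping = {f"P{i}": f"Q{9 - i}" for i in range(1, 10)}
        relabeled["patient_id"] = relabeled["patient_id"].map(mapping)
        fit2 = GrowthLME.from_dataframe(relabeled).fit()
        assert np.isclose(fit1.llf, fit2.llf, rtol=1e-8)
        assert np.allclose(fit1.fe_params.values, fit2.fe_params.values,
                           rtol=1e-6)

    def test_quadratic_term_with_null_truth_changes_aic_little(self):
        deltas = []
        for seed in range(10):
            t = make_cohort(CohortSpec(seed=200 + seed)).table
            base = GrowthLME.from_dataframe(t).fit()
            quad = GrowthLME.from_dataframe(t, quadratic=True).fit()
            deltas.append(quad.aic - base.aic)
        assert abs(np.mean(deltas)) < 2.0

    def test_profile_ci_brackets_estimate_and_is_asymmetric(self):
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=3)).table).fit()
        lo, hi = fit.sd_profile_ci("b1")
        assert lo < fit.sd_b1 < hi
        # profile intervals for SDs are right-skewed
        assert (hi - fit.sd_b1) > (fit.sd_b1 - lo)

    def test_fixed_effects_only_comparison_runs(self):
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=3)).table).fit()
        ols = fit.ols_comparison()
        # pooled OLS has far smaller (overly optimistic) standard errors
        assert ols.bse[1] < fit.bse.iloc[1]

    def test_plot_returns_axes_with_patient_lines(self):
        import matplotlib

        matplotlib.use("Agg")
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=3)).table).fit()
        ax = fit.plot()
        assert len(ax.lines) == 10          # 9 patient lines + fixed effect
        import matplotlib.pyplot as plt

        plt.close(ax.figure)

    def test_summary_mentions_key_quantities(self):
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=3)).table).fit()
        text = fit.summary()
        for token in ("F-test", "AIC", "sd(b1)", "stress_kpa"):
            assert token in text

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            GrowthLME(np.ones(4), np.ones((4, 2)), np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            GrowthLME(np.ones(4), np.column_stack([np.ones(4), np.arange(4.0)]),
                      np.zeros(4))


class TestFTest:
    def test_zero_slope_gives_f_zero_p_one(self):
        # construct data whose GLS slope is exactly zero by symmetry
        x = np.tile([1.0, 2.0, 3.0], 4)
        y = np.tile([5.0, 5.0, 5.0], 4)
        g = np.repeat(np.arange(4), 3)
        y = y + np.repeat([1.0, -1.0, 2.0, -2.0], 3)   # pure intercept shifts
        fit = GrowthLME(y, np.column_stack([np.ones(12), x]), g).fit()
        F, p = ftest_fixed_slope(fit, ddf="residual")
        assert F < 1e-12
        assert p > 1.0 - 1e-9

    def test_residual_and_satterthwaite_df_ordering(self):
        fit = GrowthLME.from_dataframe(make_cohort(CohortSpec(seed=3)).table).fit()
        _, p_res = fit.f_test_slope(ddf="residual")
        _, p_sat = fit.f_test_slope(ddf="satterthwaite")
        assert fit.satterthwaite_df() <= fit.df_resid
        assert p_sat >= p_res          # fewer df -> more conservative


class TestPearson:
    def _table(self, rng, n_pat=4, n=38):
        rows = []
        for m in range(n_pat):
            x = rng.uniform(0, 300, n)
            y = 0.1 * x + rng.normal(0, 5, n)
            for xi, yi in zip(x, y):
                rows.append((f"P{m}", xi, yi))
        return pd.DataFrame(rows, columns=["patient_id", "x", "y"])

    def test_perfect_line_gives_r_one(self):
        t = pd.DataFrame({"patient_id": ["A"] * 10,
                          "x": np.arange(10.0), "y": np.arange(10.0)})
        out = pearson_by_patient(t, "x", "y")
        assert np.isclose(out["r"].iloc[0], 1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        t = self._table(rng)
        a = pearson_by_patient(t, "x", "y")
        t2 = t.assign(x=3.0 * t["x"] - 7.0)
        b = pearson_by_patient(t2, "x", "y")
        assert np.allclose(a["r"], b["r"])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(60):
            x = rng.uniform(0, 1, 38)
            y = rng.normal(0, 1, 38)
            t = pd.DataFrame({"patient_id": "A", "x": x, "y": y})
            ps.append(pearson_by_patient(t, "x", "y")["p"].iloc[0])
        ps = np.asarray(ps)
        assert 0.25 < (ps < 0.5).mean() < 0.75
        assert (ps < 0.05).mean() < 0.2

    def test_degenerate_patients_flagged(self):
        t = pd.DataFrame({"patient_id": ["A"] * 5, "x": [1.0] * 5,
                          "y": np.arange(5.0)})
        out = pearson_by_patient(t, "x", "y")
        assert out["flag"].iloc[0] == "degenerate"
        assert np.isnan(out["r"].iloc[0])
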