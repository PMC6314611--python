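"""Maximum-entropy core: feature expansion, fitting, prediction, replicates.

The fitting contract is checked against an independent oracle: a
generic convex optimization of the same penalized likelihood written
from scratch (smoothed L1, Nelder-Mead / BFGS), never through the
package's own solver path.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

import tickenm
from tickenm.maxent import (
    MaxentModel,
    SuitabilityGrid,
    build_feature_spec,
    expand_features,
    fit_maxent,
    fit_replicates,
    median_and_range,
    predict,
    regularization_path,
)

VAR_NAMES = [f"var{i:02d}" for i in range(1, 7)]


class TestExpandFeatures:
    def test_linear_only_column_count(self):
        bg = np.random.default_rng(0).uniform(0, 1, (50, 2))
        spec = build_feature_spec(("linear",), ["a", "b"], bg)
        F, names, classes, _ = expand_features(bg, spec)
        assert F.shape[1] == 2 and classes == ["linear", "linear"]

    def test_lqp_combinatorial_count(self):
        bg = np.random.default_rng(0).uniform(0, 1, (50, 3))
        spec = build_feature_spec(("linear", "quadratic", "product"), ["a", "b", "c"], bg)
        F, _, _, _ = expand_features(bg, spec)
        assert F.shape[1] == 3 + 3 + 3  # linear + quadratic + pairwise products

    def test_hinge_forward_and_reverse(self):
        bg = np.random.default_rng(0).uniform(0, 1, (200, 1))
        spec = build_feature_spec(("hinge",), ["a"], bg, n_hinge_knots=5)
        F, names, _, _ = expand_features(bg, spec)
        assert F.shape[1] == 10  # 5 knots x (forward + reverse)
        assert F.min() >= 0 and F.max() <= 1 + 1e-12

    def test_constant_variable_excluded(self):
        bg = np.column_stack([np.ones(30), np.linspace(0, 1, 30)])
        spec = build_feature_spec(("linear",), ["const", "ok"], bg)
        assert spec.var_names == ["ok"]

    def test_scaling_uses_background_bounds(self):
        bg = np.linspace(10, 20, 50)[:, None]
        spec = build_feature_spec(("linear",), ["a"], bg)
        F, _, _, oor = expand_features(np.array([[10.0], [20.0], [25.0]]), spec)
        assert F[0, 0] == 0.0 and F[1, 0] == 1.0
        assert oor.tolist() == [False, False, True]


class TestFit:
    def test_no_signal_shrinks_to_uniform(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 1, (500, 2))
        pres = rng.uniform(0, 1, (100, 2))  # presences ~ background distribution
        spec = build_feature_spec(("linear", "quadratic"), ["a", "b"], bg, pres)
        m = fit_maxent(pres, bg, spec, 1.0)
        # the fitted density stays essentially uniform over the background
        raw, _ = m.raw(bg, clamp=False)
        assert m.entropy == pytest.approx(np.log(len(bg)), rel=0.01)
        kl_from_uniform = float(np.sum(raw * np.log(raw * len(bg))))
        assert kl_from_uniform < 0.05

    def test_one_dim_sign_and_oracle(self):
        """Fitted lambda matches an independent smoothed-L1 scalar optimization."""
        rng = np.random.default_rng(2)
        bg = rng.uniform(0, 1, (400, 2))
        # presences concentrated at high x of the first variable
        pres = np.column_stack([rng.beta(5, 1.5, 120), rng.uniform(0, 1, 120)])
        spec = build_feature_spec(("linear",), ["a", "b"], bg, pres)
        m = fit_maxent(pres, bg, spec, 1.0)
        lam_a = m.lambdas[0]
        assert lam_a > 0
        # oracle: optimize the identical penalized objective over lambda_a
        # with lambda_b fixed at the fitted value, by golden-section search
        Fp, _, _, _ = expand_features(pres, spec)
        Fb, _, _, _ = expand_features(bg, spec)
        n = len(pres)
        betas = m.betas

        def neg_pen_ll(la):
            lam = np.array([la, m.lambdas[1]])
            eta_b = Fb @ lam
            z = np.log(np.exp(eta_b).sum())
            ll = (Fp @ lam).sum() - n * z
            return -(ll - betas[0] * abs(la) - betas[1] * abs(lam[1]))

        res = minimize_scalar(neg_pen_ll, bounds=(0, 20), method="bounded",
                              options={"xatol": 1e-10})
        assert lam_a == pytest.approx(res.x, abs=1e-3)

    def test_regularization_path_monotone(self, presence_values, background):
        """Nonzero-coefficient count never increases along the 17-multiplier grid."""
        from tickenm.calibration import parse_multiplier_spec

        mults = parse_multiplier_spec("0.1-1 by 0.1; 1-6 by 1; 8; 10")
        spec = build_feature_spec(
            ("linear", "quadratic", "product", "hinge"),
            VAR_NAMES, background, presence_values, n_hinge_knots=5,
        )
        models = regularization_path(presence_values, background, spec, mults)
        ks = [m.k for m in models]
        assert all(k2 <= k1 for k1, k2 in zip(ks, ks[1:]))
        assert ks[-1] < ks[0]  # strong regularization does prune features

    def test_raw_normalizes_over_background(self, lq_model, background):
        raw, _ = lq_model.raw(background, clamp=False)
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_truth_recovery(self, lq_model, species, env6):
        """lq model on 200 presences recovers the Gaussian-niche truth surface."""
        cl, _ = lq_model.cloglog(env6.table())
        rho = spearmanr(species.truth_grid[env6.mask], cl).statistic
        assert rho >= 0.8

    def test_serialization_round_trip(self, lq_model, background):
        back = MaxentModel.from_json(lq_model.to_json())
        r1, _ = lq_model.raw(background[:100])
        r2, _ = back.raw(background[:100])
        np.testing.assert_array_equal(r1, r2)


class TestPredict:
    def test_training_stack_not_clamped(self, lq_model, env6, background):
        grid = predict(lq_model, env6, clamp=True)
        # background spans the full grid value range here, so nothing clamps
        assert not grid.clamped_mask.any()
        assert grid.output_scale == "cloglog"
        v = grid.values[grid.valid_mask]
        assert np.all((v >= 0) & (v <= 1))

    def test_clamped_cell_equals_boundary_prediction(self, lq_model, env6):
        shifted = env6.with_layers(
            {n: a + (5.0 if n == "var01" else 0.0) for n, a in env6.layers.items()}
        )
        g = predict(lq_model, shifted, clamp=True)
        assert g.clamped_mask.any()
        # pin var01 at its training max: prediction must match exactly
        hi = lq_model.feature_spec.var_max[lq_model.feature_spec.var_names.index("var01")]
        pinned = env6.with_layers(
            {n: (np.full_like(a, hi) if n == "var01" else a + 0.0) for n, a in shifted.layers.items()}
        )
        g2 = predict(lq_model, pinned, clamp=True)
        hi_cells = shifted.layers["var01"] > hi
        np.testing.assert_allclose(g.values[hi_cells], g2.values[hi_cells], rtol=1e-12)

    def test_raw_grid_sums_to_one_on_full_background(self, presence_values, env6):
        bg_all = env6.table()  # every valid cell is background
        spec = build_feature_spec(("linear", "quadratic"), VAR_NAMES, bg_all, presence_values)
        m = fit_maxent(presence_values, bg_all, spec, 1.0)
        g = predict(m, env6, clamp=False, output_scale="raw")
        assert np.nansum(g.values) == pytest.approx(1.0, abs=1e-6)

    def test_missing_variable_rejected(self, lq_model, env6):
        partial = env6.subset(VAR_NAMES[:3])
        with pytest.raises(KeyError):
            predict(lq_model, partial)


class TestReplicates:
    def test_no_bootstrap_single_rep_equals_fit(self, presence_values, background):
        spec = build_feature_spec(("linear",), VAR_NAMES, background, presence_values)
        single = fit_maxent(presence_values, background, spec, 1.0)
        reps = fit_replicates(presence_values, background, spec, 1.0, n_replicates=1,
                              seed=0, bootstrap=False)
        np.testing.assert_allclose(reps[0].lambdas, single.lambdas, atol=1e-10)

    def test_deterministic_given_seed(self, presence_values, background):
        spec = build_feature_spec(("linear",), VAR_NAMES, background, presence_values)
        a = fit_replicates(presence_values, background, spec, 1.0, 3, seed=9)
        b = fit_replicates(presence_values, background, spec, 1.0, 3, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.lambdas, mb.lambdas)

    def test_replicate_spread_nondegenerate(self, presence_values, background, env6):
        spec = build_feature_spec(("linear", "quadratic"), VAR_NAMES, background, presence_values)
        reps = fit_replicates(presence_values, background, spec, 1.0, 5, seed=3)
        grids = [predict(m, env6) for m in reps]
        med, rng = median_and_range(grids)
        assert np.nanmax(rng) > 0


class TestMedianRange:
    def test_identical_grids_zero_range(self, lq_model, env6):
        g = predict(lq_model, env6)
        med, rng = median_and_range([g, g, g])
        np.testing.assert_allclose(med.values[g.valid_mask], g.values[g.valid_mask])
        assert np.nanmax(rng) == 0

    def test_cellwise_arithmetic(self):
        mask = np.ones((1, 1), bool)
        grids = [
            SuitabilityGrid(np.array([[v]]), "cloglog", np.zeros((1, 1), bool), mask)
            for v in (0.2, 0.4, 0.9)
        ]
        med, rng = median_and_range(grids)
        assert med.values[0, 0] == pytest.approx(0.4)
        assert rng[0, 0] == pytest.approx(0.7)

    def test_median_within_bounds_property(self):
        rng_ = np.random.default_rng(5)
        mask = np.ones((8, 8), bool)
        grids = [
            SuitabilityGrid(rng_.uniform(0, 1, (8, 8)), "cloglog", np.zeros((8, 8), bool), mask)
            for _ in range(7)
        ]
        med, spread = median_and_range(grids)
        stack = np.stack([g.values for g in grids])
        assert (med.values >= stack.min(axis=0) - 1e-12).all()
        assert (med.values <= stack.max(axis=0) + 1e-12).all()
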