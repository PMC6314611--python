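"""Calibration machinery: enumeration, partial ROC, omission, AICc, selection."""

import numpy as np
import pytest

import tickenm
from tickenm.calibration import (
    CandidateResult,
    CandidateSpec,
    all_class_combos,
    compute_aicc,
    enumerate_candidates,
    omission_rate,
    parse_multiplier_spec,
    partial_roc,
    select_models,
)
from tickenm.maxent import build_feature_spec, expand_features, fit_maxent


class TestEnumeration:
    def test_seventeen_multipliers(self):
        """The published multiplier grid parses to exactly 17 unique values."""
        mults = parse_multiplier_spec("0.1-1 by 0.1; 1-6 by 1; 8; 10")
        assert len(mults) == 17
        assert mults[0] == pytest.approx(0.1) and mults[-1] == 10

    def test_overlap_deduplicated(self):
        assert parse_multiplier_spec("1-3 by 1; 3-5 by 1") == [1, 2, 3, 4, 5]

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            parse_multiplier_spec("5-1 by 1")
        with pytest.raises(ValueError):
            parse_multiplier_spec("")

    def test_product_counts(self):
        specs = enumerate_candidates([("linear",)], parse_multiplier_spec("0.1-1 by 0.1; 1-6 by 1; 8; 10"), ["a", "b", "c"])
        assert len(specs) == 51  # 1 x 17 x 3
        combos = all_class_combos()
        assert len(combos) == 31  # all non-empty subsets of the 5 classes
        specs = enumerate_candidates(combos, parse_multiplier_spec("0.1-1 by 0.1; 1-6 by 1; 8; 10"), ["a", "b", "c"])
        assert len(specs) == 31 * 17 * 3  # 1,581

    def test_stable_ordering(self):
        specs = enumerate_candidates([("linear",), ("hinge",)], [1.0, 2.0], ["v1", "v2"])
        assert [s.varset_id for s in specs[:4]] == ["v1"] * 4
        assert specs[0].feature_classes == ("linear",)

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates([], [1.0], ["a"])


class TestPartialRoc:
    def test_truth_model_significant(self, species, env6):
        """Suitability equal to the species truth is highly significant."""
        rng = np.random.default_rng(0)
        truth = species.truth_grid[env6.mask]
        # evaluation points sampled proportional to truth
        idx = rng.choice(len(truth), size=60, p=truth / truth.sum())
        ratio, p = partial_roc(truth[idx], truth, 0.05, n_boot=500, seed=1)
        assert ratio > 1
        assert p < 0.05

    def test_null_type_one_error_calibrated(self):
        """Random-prediction suitability is rejected at ~ the nominal rate."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            grid = rng.uniform(0, 1, 2000)
            test = rng.uniform(0, 1, 40)
            _, p = partial_roc(test, grid, 0.05, n_boot=500, seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        # binomial 99% CI around alpha = 0.05
        lo = 0.05 - 2.576 * np.sqrt(0.05 * 0.95 / n_sims)
        hi = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_sims)
        assert lo <= rejections / n_sims <= hi

    def test_domain_shrinks_with_e(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(0, 1, 1000)
        test = rng.uniform(0, 1, 50) ** 0.5
        r1, _ = partial_roc(test, grid, 0.45, n_boot=50, seed=0)
        r2, _ = partial_roc(test, grid, 0.05, n_boot=50, seed=0)
        assert np.isfinite(r1) and np.isfinite(r2)

    def test_constant_grid_non_significant(self):
        ratio, p = partial_roc(np.linspace(0, 1, 20), np.full(100, 0.5), 0.05, 50, seed=0)
        assert np.isnan(ratio) and p == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            partial_roc(np.ones(5), np.linspace(0, 1, 50), 0.05)


class TestOmission:
    def test_eval_equals_cal_rate_below_e(self):
        cal = np.linspace(0.01, 1.0, 100)
        thr, rate = omission_rate(cal, cal, 0.05)
        assert rate <= 0.05

    def test_eval_above_max_zero_omission(self):
        thr, rate = omission_rate(np.linspace(0, 0.5, 20), np.full(10, 0.9), 0.05)
        assert rate == 0.0

    def test_order_statistic_arithmetic(self):
        cal = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        thr, rate = omission_rate(cal, np.array([0.05, 0.5]), 0.05)
        assert thr == pytest.approx(0.1)  # ceil(0.05*10) = 1st smallest
        assert rate == pytest.approx(0.5)  # only 0.05 falls strictly below

    def test_equality_retained(self):
        thr, rate = omission_rate(np.array([0.2, 0.3, 0.4]), np.array([0.2, 0.1]), 0.1)
        assert thr == pytest.approx(0.2)
        assert rate == pytest.approx(0.5)


class TestAicc:
    def _toy_model(self, k):
        class M:
            pass

        m = M()
        m.k = k
        return m

    def test_uniform_model_closed_form(self, presence_values, background):
        """k=0 model: lnL = -n ln(G), AICc = 2 n ln(G)."""
        spec = build_feature_spec(("linear",), [f"var{i:02d}" for i in range(1, 7)], background, presence_values)
        model = fit_maxent(presence_values, background, spec, beta_multiplier=1e6)  # crush to uniform
        assert model.k == 0
        n, g = len(presence_values), 400
        raw = np.full(n, 1.0 / g)
        aicc, k = compute_aicc(model, raw, 1.0)
        assert k == 0
        assert aicc == pytest.approx(2 * n * np.log(g), rel=1e-12)

    def test_singularity_at_k_near_n(self, lq_model):
        raw = np.full(10, 0.1)
        aicc, k = compute_aicc(lq_model, raw, 1.0)  # lq_model has k=12 >= 10-1
        assert np.isinf(aicc)

    def test_matches_log_sum_oracle(self, lq_model, presence_values, background):
        raw_occ, _ = lq_model.raw(presence_values[:50], clamp=False)
        raw_bg, _ = lq_model.raw(background, clamp=False)
        s = float(raw_bg.sum())
        aicc, k = compute_aicc(lq_model, raw_occ, s)
        # independent oracle: explicit log-sum arithmetic
        n = 50
        lnl = sum(np.log(r / s) for r in raw_occ)
        expected = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
        assert aicc == pytest.approx(expected, abs=1e-9)

    def test_zero_raw_score_infinite(self, lq_model):
        aicc, _ = compute_aicc(lq_model, np.array([0.5, 0.0, 0.1]), 1.0)
        assert np.isinf(aicc)


def _result(p, om, aicc, tag="x"):
    return CandidateResult(
        spec=CandidateSpec(("linear",), float(len(tag)), tag),
        mean_auc_ratio=1.5, proc_p=p, omission_rate=om,
        omission_threshold=0.1, aicc=aicc, k_params=3,
    )


class TestSelection:
    def test_single_significant_candidate(self):
        sel = select_models([_result(0.0, 0.0, 100.0)])
        assert len(sel) == 1 and sel[0].delta_aicc == 0.0

    def test_aicc_ties_kept(self):
        sel = select_models([_result(0.0, 0.0, 100.0, "a"), _result(0.0, 0.0, 100.0, "b")])
        assert len(sel) == 2

    def test_three_pass_filter_matches_oracle(self):
        """Randomized candidate tables: selection equals a brute-force filter."""
        rng = np.random.default_rng(17)
        for trial in range(50):
            results = [
                _result(rng.uniform(0, 0.2), rng.uniform(0, 0.15), rng.uniform(90, 110), f"c{i}")
                for i in range(30)
            ]
            sel = select_models([r for r in results], alpha=0.05, omission_max=0.05, delta_max=2.0)
            # oracle: independent three-pass filter
            stage12 = [r for r in results if r.proc_p < 0.05 and r.omission_rate <= 0.05]
            if not stage12:
                assert sel == []
                continue
            amin = min(r.aicc for r in stage12)
            expected = {id(r) for r in stage12 if r.aicc - amin <= 2.0}
            assert {id(r) for r in sel} == expected
            assert all(r.omission_rate <= 0.05 and r.delta_aicc <= 2.0 for r in sel)
            assert min(r.delta_aicc for r in sel) == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        results = [
            _result(rng.uniform(0, 0.2), rng.uniform(0, 0.15), rng.uniform(90, 110), f"c{i}")
            for i in range(20)
        ]
        sel_fwd = select_models(list(results), 0.05, 0.05, 2.0)
        sel_rev = select_models(list(reversed(results)), 0.05, 0.05, 2.0)
        assert {r.spec.varset_id for r in sel_fwd} == {r.spec.varset_id for r in sel_rev}

    def test_empty_selection_reported_not_raised(self):
        sel = select_models([_result(0.9, 0.5, 100.0)])
        assert sel == []
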