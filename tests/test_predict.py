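"""Fold assignment, template lesion load, nested regression, leakage guard."""

import numpy as np
import pytest

from lesionkit.cohort import LesionMask, Template, VolumeGeometry
from lesionkit.predict import (
    assign_folds,
    behavior_residual_control,
    compare_models,
    cross_validated_loads,
    template_lesion_load,
)


class TestAssignFolds:
    def test_128_into_8_folds_of_16(self):
        folds = assign_folds(128, 8, np.random.default_rng(0))
        sizes = [int((folds.fold_of == f).sum()) for f in range(1, 9)]
        assert sizes == [16] * 8

    def test_unbalanced_sizes_differ_by_one(self):
        folds = assign_folds(10, 3, np.random.default_rng(1))
        sizes = sorted((folds.fold_of == f).sum() for f in range(1, 4))
        assert sizes == [3, 3, 4]

    def test_deterministic_given_seed(self):
        f1 = assign_folds(50, 5, np.random.default_rng(3))
        f2 = assign_folds(50, 5, np.random.default_rng(3))
        assert np.array_equal(f1.fold_of, f2.fold_of)

    def test_too_many_folds_fatal(self):
        with pytest.raises(ValueError, match="folds"):
            assign_folds(5, 8, np.random.default_rng(0))


class TestTemplateLesionLoad:
    geo = VolumeGeometry(shape=(6, 6, 6), affine=np.eye(4))

    def _lesion(self, flat_idx):
        d = np.zeros(self.geo.n_voxels, dtype=bool)
        d[list(flat_idx)] = True
        return LesionMask(participant_id="p", data=d.reshape(self.geo.shape))

    def test_exact_fractions(self):
        tpl = Template(geometry=self.geo, voxels=np.arange(200))
        assert template_lesion_load(self._lesion(range(200)), tpl) == 1.0
        assert template_lesion_load(self._lesion(range(50)), tpl) == 0.25
        assert template_lesion_load(self._lesion([210]), tpl) == 0.0

    def test_monotone_under_lesion_growth(self):
        rng = np.random.default_rng(4)
        tpl = Template(
            geometry=self.geo, voxels=rng.choice(216, size=40, replace=False)
        )
        vox = list(rng.choice(216, size=1, replace=False))
        prev = template_lesion_load(self._lesion(vox), tpl)
        for extra in rng.permutation([v for v in range(216) if v not in vox])[:60]:
            vox.append(extra)
            cur = template_lesion_load(self._lesion(vox), tpl)
            assert cur >= prev
            prev = cur

    def test_empty_template_loads_zero(self, caplog):
        tpl = Template(geometry=self.geo, voxels=np.array([], dtype=int))
        with caplog.at_level("WARNING"):
            assert template_lesion_load(self._lesion([0]), tpl) == 0.0
        assert "empty template" in caplog.text


class TestCompareModels:
    def _hand_data(self):
        rng = np.random.default_rng(7)
        size = rng.uniform(1, 10, size=10)
        load = rng.uniform(size=10)
        score = -0.5 * size + 2.0 * load + rng.normal(size=10)
        return score, size, load

    def test_matches_projection_matrix_oracle(self):
        score, size, load = self._hand_data()
        mc = compare_models(score, size, load)
        n = 10

        def r2(pred_cols):
            D = np.column_stack([np.ones(n)] + pred_cols)
            H = D @ np.linalg.pinv(D)  # projection onto the model space
            yhat = H @ score
            return 1 - ((score - yhat) ** 2).sum() / ((score - score.mean()) ** 2).sum()

        r2_size, r2_both = r2([size]), r2([size, load])
        f_oracle = (r2_both - r2_size) / ((1 - r2_both) / (n - 3))
        assert mc.r2_size == pytest.approx(r2_size, abs=1e-10)
        assert mc.r2_both == pytest.approx(r2_both, abs=1e-10)
        assert mc.f_stat == pytest.approx(f_oracle, abs=1e-10)
        # partial r via explicit residual projections
        M = np.eye(n) - np.column_stack([np.ones(n), size]) @ np.linalg.pinv(
            np.column_stack([np.ones(n), size])
        )
        rs, rl = M @ score, M @ load
        partial = rs @ rl / np.sqrt((rs @ rs) * (rl @ rl))
        assert mc.partial_r == pytest.approx(partial, abs=1e-10)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm_api

        score, size, load = self._hand_data()
        mc = compare_models(score, size, load)
        both = sm_api.OLS(score, sm_api.add_constant(np.column_stack([size, load]))).fit()
        only = sm_api.OLS(score, sm_api.add_constant(size)).fit()
        cmp = both.compare_f_test(only)
        assert mc.r2_both == pytest.approx(both.rsquared, abs=1e-10)
        assert mc.f_stat == pytest.approx(cmp[0], abs=1e-8)
        assert mc.p_value == pytest.approx(cmp[1], abs=1e-10)

    def test_collinear_load_adds_nothing(self):
        rng = np.random.default_rng(1)
        size = rng.uniform(1, 5, size=12)
        score = size + rng.normal(size=12)
        mc = compare_models(score, size, 2.0 * size + 1.0)
        assert mc.delta_r2 == pytest.approx(0.0, abs=1e-10)
        assert mc.partial_r == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_perfect_load(self):
        rng = np.random.default_rng(2)
        size = rng.normal(size=20)
        raw = rng.normal(size=20)
        # load orthogonal to size and the intercept
        M = np.eye(20) - np.column_stack([np.ones(20), size]) @ np.linalg.pinv(
            np.column_stack([np.ones(20), size])
        )
        load = M @ raw
        mc = compare_models(load.copy(), size, load)
        assert mc.r2_size == pytest.approx(0.0, abs=1e-10)
        assert mc.delta_r2 == pytest.approx(1.0, abs=1e-10)
        assert mc.partial_r == pytest.approx(1.0, abs=1e-10)

    def test_nesting_property(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            r = np.random.default_rng(seed)
            score, size, load = (r.normal(size=15) for _ in range(3))
            mc = compare_models(score, size, load)
            assert mc.r2_both >= mc.r2_size - 1e-10
            assert mc.r2_both >= mc.r2_load - 1e-10
            assert mc.delta_r2 >= -1e-10

    def test_constant_predictor_degenerates_gracefully(self):
        rng = np.random.default_rng(5)
        score = rng.normal(size=10)
        size = np.full(10, 3.0)
        load = rng.uniform(size=10)
        mc = compare_models(score, size, load)
        assert mc.r2_size == pytest.approx(0.0, abs=1e-10)


class TestBehaviorResidualControl:
    def test_residuals_uncorrelated_with_size(self):
        rng = np.random.default_rng(0)
        size = rng.uniform(1, 10, size=50)
        score = -size + rng.normal(size=50)
        resid = behavior_residual_control(score, size)
        assert abs(resid.mean()) < 1e-10
        assert abs(np.corrcoef(resid, size)[0, 1]) < 1e-10

    def test_orthogonal_score_unchanged_up_to_centering(self):
        rng = np.random.default_rng(1)
        size = np.repeat([1.0, 2.0], 10)
        raw = rng.normal(size=20)
        M = np.eye(20) - np.column_stack([np.ones(20), size]) @ np.linalg.pinv(
            np.column_stack([np.ones(20), size])
        )
        score = M @ raw  # already orthogonal to size and centered
        resid = behavior_residual_control(score, size)
        assert np.allclose(resid, score, atol=1e-10)

    def test_pure_size_score_fully_absorbed(self):
        size = np.linspace(1, 10, 30)
        resid = behavior_residual_control(3.0 - 2.0 * size, size)
        assert np.allclose(resid, 0, atol=1e-10)


class TestCrossValidatedLoads:
    def test_no_leakage_from_held_out_scores(self, small_cohort):
        # corrupting a held-out participant's score must not change the
        # template used for that participant's load
        cohort, _ = small_cohort
        y = cohort.behavior["focal"].to_numpy()
        folds = assign_folds(len(cohort), 4, np.random.default_rng(2))
        params = {"B": 150, "v": 100, "alpha": 0.05}
        t1, _ = cross_validated_loads(
            cohort, {"focal": y}, "vlsm", folds, params, seed=3
        )
        victim = int(folds.test_indices(2)[0])
        y_bad = y.copy()
        y_bad[victim] = 1e6
        t2, _ = cross_validated_loads(
            cohort, {"focal": y_bad}, "vlsm", folds, params, seed=3
        )
        assert t1["load_focal"].iloc[victim] == t2["load_focal"].iloc[victim]

    def test_loads_track_planted_region_damage(self, focal_cohort):
        cohort, truth = focal_cohort
        y = cohort.behavior["focal_deficit"].to_numpy()
        folds = assign_folds(len(cohort), 8, np.random.default_rng(0))
        table, sizes = cross_validated_loads(
            cohort,
            {"focal_deficit": y},
            "vlsm",
            folds,
            {"B": 300, "v": 100, "alpha": 0.05},
            seed=1,
        )
        loads = table["load_focal_deficit"].to_numpy()
        truth_loads = truth.critical_loads["focal_deficit"]
        assert np.corrcoef(loads, truth_loads)[0, 1] >= 0.7
        assert len(sizes["focal_deficit"]) == 8
        assert ((loads >= 0) & (loads <= 1)).all()

    def test_constant_deficit_yields_zero_loads(self, small_cohort):
        cohort, _ = small_cohort
        y = np.zeros(len(cohort))
        folds = assign_folds(len(cohort), 4, np.random.default_rng(1))
        table, _ = cross_validated_loads(
            cohort, {"flat": y}, "vlsm", folds,
            {"B": 150, "v": 100, "alpha": 0.05}, seed=2,
        )
        assert (table["load_flat"] == 0).all()
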