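"""Preprocessing chain: median imputation, standardization, residualization."""

import numpy as np
import pandas as pd
import pytest

from dynograph.preprocess import (
    PreprocessState,
    apply_impute,
    apply_preprocess,
    apply_standardize,
    fit_impute,
    fit_preprocess,
    fit_standardize,
    fit_residualize,
    apply_residualize,
    residualize,
)


class TestImpute:
    def test_median_fill(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        state = fit_impute(df, ["a"])
        out = apply_impute(df, state)
        assert out["a"].tolist() == [1.0, 2.0, 3.0]

    def test_identity_when_complete(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.7]})
        out = apply_impute(df, fit_impute(df, ["a", "b"]))
        pd.testing.assert_frame_equal(out, df)

    def test_matches_brute_force_median_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        holes = rng.random(df.shape) < 0.3
        df = df.mask(holes)
        state = fit_impute(df, list("abcde"))
        for col in "abcde":
            observed = sorted(v for v in df[col] if not np.isnan(v))
            k = len(observed)
            mid = observed[k // 2] if k % 2 else (observed[k // 2 - 1] + observed[k // 2]) / 2
            assert state.medians[col] == pytest.approx(mid, abs=1e-12)

    def test_fully_missing_column_raises(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="'a'"):
            fit_impute(df, ["a"])


class TestStandardize:
    def test_population_convention(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        state = fit_standardize(df, fit_impute(df, ["a"]))
        out = apply_standardize(df, state)
        np.testing.assert_allclose(out["a"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            state = fit_standardize(df, fit_impute(df, ["a", "b"]))
        assert state.dropped == ["a"]
        out = apply_standardize(df, state)
        assert "a" not in out.columns

    def test_test_rows_use_train_statistics(self, rng):
        train = pd.DataFrame({"x": rng.normal(3.0, 2.0, size=50)})
        test = pd.DataFrame({"x": rng.normal(-1.0, 0.5, size=30)})
        state = fit_standardize(train, fit_impute(train, ["x"]))
        out = apply_standardize(test, state)
        # recompute from stored state: exact, no re-fit
        np.testing.assert_allclose(
            out["x"], (test["x"] - state.mean["x"]) / state.std["x"], atol=0
        )
        assert abs(out["x"].mean()) > 0.5  # clearly not re-centered on test


class TestResidualize:
    def test_intercept_only_centers_columns(self, rng):
        X = rng.normal(size=(30, 4))
        res = residualize(X, np.empty((30, 0)))
        np.testing.assert_allclose(res, X - X.mean(axis=0), atol=1e-12)

    def test_self_projection_vanishes(self, rng):
        C = rng.normal(size=(40, 3))
        res = residualize(C, C)
        assert np.abs(res).max() < 1e-10

    def test_orthogonality_and_least_squares_oracle(self, rng):
        for _ in range(50):
            X = rng.normal(size=(50, 8))
            C = rng.normal(size=(50, 3))
            res = residualize(X, C)
            Ci = np.column_stack([np.ones(50), C])
            scale = np.abs(X).max()
            assert np.abs(Ci.T @ res).max() < 1e-8 * scale
            # normal-equations oracle, column by column
            for j in range(8):
                beta = np.linalg.solve(Ci.T @ Ci, Ci.T @ X[:, j])
                np.testing.assert_allclose(res[:, j], X[:, j] - Ci @ beta, atol=1e-8)

    def test_idempotence(self, rng):
        X = rng.normal(size=(25, 5))
        C = rng.normal(size=(25, 2))
        once = residualize(X, C)
        twice = residualize(once, C)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rank_deficient_covariates_raise(self, rng):
        c = rng.normal(size=30)
        C = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=(30, 2)), C)


class TestFittedChain:
    def test_out_of_sample_uses_training_projection(self, small_cohort):
        panel, _ = small_cohort
        features = [c for c in panel.columns if "__" in c]
        covs = [c for c in panel.columns if c.startswith("cov_")]
        subjects = sorted(panel["subject_id"].unique())
        train = panel[panel["subject_id"].isin(subjects[:100])]
        test = panel[panel["subject_id"].isin(subjects[100:])]
        state = fit_preprocess(train, features, covs)
        out_test = apply_preprocess(test, state, covs)
        # recompute with the stored coefficient matrix: must agree exactly
        from dynograph.preprocess import build_covariate_matrix

        imputed = apply_standardize(apply_impute(test, state), state)
        C, _, _ = build_covariate_matrix(test, covs, site_levels=state.site_levels)
        expected = imputed[state.retained].to_numpy() - C @ state.residual_coef
        np.testing.assert_allclose(out_test[state.retained].to_numpy(), expected, atol=1e-12)

    def test_train_rows_orthogonal_to_covariates(self, small_cohort):
        panel, _ = small_cohort
        features = [c for c in panel.columns if "__" in c]
        covs = [c for c in panel.columns if c.startswith("cov_")]
        state = fit_preprocess(panel, features, covs)
        out = apply_preprocess(panel, state, covs)
        from dynograph.preprocess import build_covariate_matrix

        C, _, _ = build_covariate_matrix(panel, covs, site_levels=state.site_levels)
        prod = C.T @ out[state.retained].to_numpy()
        assert np.abs(prod).max() < 1e-6

    def test_state_json_round_trip(self, small_cohort, tmp_path):
        panel, _ = small_cohort
        features = [c for c in panel.columns if "__" in c][:5]
        covs = [c for c in panel.columns if c.startswith("cov_")]
        state = fit_preprocess(panel, features, covs)
        state.to_json(tmp_path / "state.json")
        loaded = PreprocessState.from_json(tmp_path / "state.json")
        assert loaded.medians == state.medians
        assert loaded.mean == state.mean
        np.testing.assert_allclose(loaded.residual_coef, state.residual_coef)
        a = apply_preprocess(panel, state, covs)
        b = apply_preprocess(panel, loaded, covs)
        np.testing.assert_allclose(
            a[state.retained].to_numpy(), b[state.retained].to_numpy()
        )


class TestPerTimepointResidualization:
    def test_per_visit_projection_orthogonal_within_visit(self, small_cohort):
        panel, _ = small_cohort
        features = [c for c in panel.columns if "__" in c][:6]
        covs = [c for c in panel.columns if c.startswith("cov_")]
        from dynograph.preprocess import build_covariate_matrix

        state = fit_preprocess(panel, features, covs, per_timepoint=True)
        out = apply_preprocess(panel, state, covs)
        for t, sub in out.groupby("t"):
            C, _, _ = build_covariate_matrix(sub, covs, site_levels=state.site_levels)
            prod = C.T @ sub[state.retained].to_numpy()
            assert np.abs(prod).max() < 1e-6

    def test_per_visit_state_round_trips_json(self, small_cohort, tmp_path):
        panel, _ = small_cohort
        features = [c for c in panel.columns if "__" in c][:4]
        covs = [c for c in panel.columns if c.startswith("cov_")]
        state = fit_preprocess(panel, features, covs, per_timepoint=True)
        state.to_json(tmp_path / "s.json")
        loaded = PreprocessState.from_json(tmp_path / "s.json")
        a = apply_preprocess(panel, state, covs)
        b = apply_preprocess(panel, loaded, covs)
        np.testing.assert_allclose(
            a[state.retained].to_numpy(), b[state.retained].to_numpy()
        )
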