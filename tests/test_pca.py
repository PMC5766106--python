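"""NIPALS PCA: oracle equivalence, missing-value handling, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles
from scipy.stats import pearsonr

from seamspc import NipalsPCA, correlation_loadings, cross_validate, fit_pca


def match_signs(A, B):
    """Flip columns of B to the sign best matching A (sign indeterminacy)."""
    signs = np.sign(np.sum(A * B, axis=0))
    signs[signs == 0] = 1.0
    return B * signs


class TestFit:
    def test_rank_one_matrix_fully_explained_by_one_component(self, rng):
        t = rng.standard_normal(10)
        v = rng.uniform(0.5, 2.0, 4)
        X = np.outer(t, v)
        model = NipalsPCA(n_components=1).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-10)
        assert np.nansum(model.calibration_residuals_**2) == pytest.approx(0.0, abs=1e-16)

    def test_matches_svd_oracle_on_complete_data(self, random_complete):
        X = random_complete(20, 6, seed=42)
        model = NipalsPCA(n_components=6).fit(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        np.testing.assert_allclose(np.abs(model.components_), np.abs(Vt),
                                   atol=1e-8)
        np.testing.assert_allclose(match_signs(model.scores_, U * s),
                                   model.scores_, atol=1e-8)
        np.testing.assert_allclose(model.explained_variance_ratio_,
                                   s**2 / (s**2).sum(), atol=1e-10)
        np.testing.assert_allclose(model.score_variances_, s**2 / (20 - 1),
                                   atol=1e-10)

    def test_orthogonality_and_score_orthogonality(self, random_complete):
        model = NipalsPCA(n_components=4).fit(random_complete(30, 8, seed=1))
        P = model.components_
        np.testing.assert_allclose(P @ P.T, np.eye(4), atol=1e-8)
        TtT = model.scores_.T @ model.scores_
        np.testing.assert_allclose(TtT, np.diag(np.diag(TtT)), atol=1e-8)

    def test_explained_variance_non_increasing(self, random_complete):
        model = NipalsPCA(n_components=5).fit(random_complete(40, 7, seed=2))
        assert (np.diff(model.explained_variance_ratio_) <= 1e-12).all()
        assert (np.diff(model.score_variances_) <= 1e-12).all()

    def test_sign_convention_largest_loading_positive(self, random_complete):
        model = NipalsPCA(n_components=3).fit(random_complete(25, 5, seed=3))
        for row in model.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_deterministic_refit(self, random_complete):
        X = random_complete(25, 5, seed=4)
        a = NipalsPCA(n_components=3).fit(X)
        b = NipalsPCA(n_components=3).fit(X)
        np.testing.assert_array_equal(a.components_, b.components_)
        np.testing.assert_array_equal(a.scores_, b.scores_)

    def test_missing_cells_use_available_statistics(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 3)), columns=["a", "b", "c"])
        X.iloc[3:, 0] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, np.nan]
        model = NipalsPCA(n_components=1).fit(X)
        observed = X["a"].dropna()
        assert model.mean_[0] == pytest.approx(observed.mean())
        assert model.scale_[0] == pytest.approx(observed.std(ddof=1))

    def test_small_masking_barely_moves_loadings(self, rng):
        # <=1% masked cells on well-conditioned data: < 5 degrees principal angle
        n, p = 400, 10
        T = rng.standard_normal((n, 3)) * np.array([4.0, 2.0, 1.0])
        L = rng.standard_normal((3, p))
        X = T @ L + 0.1 * rng.standard_normal((n, p))
        full = NipalsPCA(n_components=3).fit(X)
        Xm = X.copy()
        holes = rng.choice(n * p, size=n * p // 100, replace=False)
        Xm.flat[holes] = np.nan
        masked = NipalsPCA(n_components=3).fit(Xm)
        angle = np.degrees(subspace_angles(full.components_.T,
                                           masked.components_.T)).max()
        assert angle < 5.0

    def test_errors_name_the_culprit(self, random_complete):
        X = random_complete(10, 4, seed=5).copy()
        X["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            NipalsPCA(n_components=2).fit(X)
        with pytest.raises(ValueError, match="n_components"):
            NipalsPCA(n_components=9).fit(random_complete(6, 4, seed=6))
        X2 = random_complete(10, 3, seed=7).copy()
        X2["empty"] = np.nan
        with pytest.raises(ValueError, match="empty"):
            NipalsPCA(n_components=2).fit(X2)


class TestProjection:
    def test_projecting_calibration_rows_reproduces_scores(self, random_complete):
        X = random_complete(30, 6, seed=8)
        model = NipalsPCA(n_components=4).fit(X)
        scores, residuals = model.project(X)
        np.testing.assert_allclose(scores, model.scores_, atol=1e-8)

    def test_energy_conservation_complete_rows(self, random_complete):
        X = random_complete(30, 6, seed=9)
        model = NipalsPCA(n_components=3).fit(X)
        Z, _ = model._preprocess(X)
        scores, residuals = model.project(X)
        lhs = (Z**2).sum(axis=1)
        rhs = (scores**2).sum(axis=1) + np.nansum(residuals**2, axis=1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_masked_cell_scores_equal_restricted_least_squares(self, random_complete):
        X = random_complete(30, 6, seed=10)
        model = NipalsPCA(n_components=3).fit(X)
        row = X.iloc[[5]].copy()
        row.iloc[0, 2] = np.nan
        scores, _ = model.project(row)
        # oracle: normal equations restricted to the observed loading rows
        z = ((row.iloc[0] - model.mean_) / model.scale_).to_numpy()
        o = np.isfinite(z)
        Po = model.components_[:, o]
        expected = np.linalg.solve(Po @ Po.T, Po @ z[o])
        np.testing.assert_allclose(scores[0], expected, atol=1e-10)

    def test_labels_matched_order_insensitively(self, random_complete):
        X = random_complete(20, 5, seed=11)
        model = NipalsPCA(n_components=2).fit(X)
        shuffled = X[list(X.columns[::-1])]
        np.testing.assert_allclose(model.transform(shuffled),
                                   model.scores_[:, :2], atol=1e-8)
        with pytest.raises(ValueError, match="mismatch"):
            model.transform(X.rename(columns={"v0": "intruder"}))

    def test_row_with_too_few_observed_values_is_flagged_not_scored(self, random_complete):
        X = random_complete(20, 5, seed=12)
        model = NipalsPCA(n_components=3).fit(X)
        row = X.iloc[[0]].copy()
        row.iloc[0, :3] = np.nan  # 2 observed < 3 components
        scores, residuals = model.project(row)
        assert np.isnan(scores).all()


class TestCorrelationLoadings:
    def test_variable_equal_to_score_sits_on_outer_circle(self, rng):
        # noiseless rank-1 data: every variable is a multiple of the score,
        # so all correlation loadings lie on the 100% (outer) circle
        t = rng.standard_normal(50)
        Y = pd.DataFrame({"a": t, "b": 2.0 * t, "c": -t})
        m = NipalsPCA(n_components=1).fit(Y)
        cl = correlation_loadings(m, Y)
        np.testing.assert_allclose(np.abs(cl["PC1"]), 1.0, atol=1e-8)

    def test_matches_direct_pearson_oracle(self, random_complete):
        X = random_complete(40, 6, seed=13)
        model = NipalsPCA(n_components=3).fit(X)
        cl = correlation_loadings(model, X)
        for j, var in enumerate(X.columns):
            for a in range(3):
                expected = pearsonr(X[var], model.scores_[:, a]).statistic
                assert cl.iloc[j, a] == pytest.approx(expected, abs=1e-10)

    def test_row_sum_of_squares_bounded_by_one(self, random_complete):
        X = random_complete(40, 6, seed=14)
        model = NipalsPCA(n_components=4).fit(X)
        cl = correlation_loadings(model, X)
        assert ((cl**2).sum(axis=1) <= 1 + 1e-8).all()

    def test_constant_variable_rejected_by_name(self, random_complete):
        X = random_complete(30, 4, seed=15)
        model = NipalsPCA(n_components=2).fit(X)
        Y = X.copy()
        Y["v1"] = Y["v1"].iloc[0]
        with pytest.raises(ValueError, match="v1"):
            correlation_loadings(model, Y)


class TestCrossValidation:
    def test_noiseless_low_rank_validates_fully(self, rng):
        T = rng.standard_normal((40, 1))
        L = rng.uniform(0.5, 1.5, (1, 5))
        X = T @ L
        cv = cross_validate(X, max_components=2, n_segments=5)
        assert cv["validated_variance"][0] == pytest.approx(1.0, abs=1e-6)
        assert cv["suggested_components"] == 1

    def test_white_noise_suggests_at_most_one_component(self):
        # simulation oracle: on iid noise the validated variance cannot
        # systematically beat the explained variance, and no real structure
        # should be suggested (property holds in >= 95% of replicates)
        wins = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((30, 6))
            cv = cross_validate(X, max_components=3, n_segments=5)
            ok = (cv["suggested_components"] <= 1
                  and (cv["validated_variance"]
                       <= cv["explained_variance"] + 1e-9).all())
            wins += ok
        assert wins / reps >= 0.95

    def test_structured_data_suggests_true_dimension(self, rng):
        T = rng.standard_normal((60, 2)) * np.array([3.0, 2.0])
        L = rng.standard_normal((2, 8))
        X = T @ L + 0.05 * rng.standard_normal((60, 8))
        cv = cross_validate(X, max_components=4, n_segments=6)
        assert cv["suggested_components"] == 2

    def test_errors(self, random_complete):
        with pytest.raises(ValueError, match="segments"):
            cross_validate(random_complete(10, 4, seed=16), 2, n_segments=1)
        with pytest.raises(ValueError, match="segments"):
            cross_validate(random_complete(4, 3, seed=17), 2, n_segments=9)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, random_complete):
        X = random_complete(25, 5, seed=18)
        X.iloc[3, 2] = np.nan
        model = fit_pca(X, n_components=3)
        path = tmp_path / "model.json"
        model.save(path)
        back = NipalsPCA.load(path)
        np.testing.assert_array_equal(back.components_, model.components_)
        np.testing.assert_array_equal(back.mean_, model.mean_)
        np.testing.assert_array_equal(back.scale_, model.scale_)
        np.testing.assert_array_equal(back.score_variances_, model.score_variances_)
        assert back.feature_names_in_ == model.feature_names_in_
        back.save(tmp_path / "again.json")
        assert (tmp_path / "again.json").read_bytes() == path.read_bytes()

    def test_loaded_model_projects_identically(self, tmp_path, random_complete):
        X = random_complete(25, 5, seed=19)
        model = fit_pca(X, n_components=2)
        model.save(tmp_path / "m.json")
        back = NipalsPCA.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.transform(X), model.transform(X))
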