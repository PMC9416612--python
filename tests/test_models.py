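import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serumnmr.models import (
    OPLS,
    ColumnScaler,
    PCASpectra,
    backscale_loadings,
    encode_classes,
)

from helpers import nipals_pls1_fitted


def random_two_class(seed, n=16, p=30):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.repeat([1.0, 0.0], n // 2)
    return X, y


class TestColumnScaler:
    @pytest.mark.parametrize("method", ["center", "pareto", "auto", "class_centroid"])
    def test_apply_then_invert_is_identity(self, method):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        labels = np.repeat(["Schizophrenia", "Control"], 6)
        scaler = ColumnScaler(method=method).fit(
            X, labels if method == "class_centroid" else None
        )
        assert np.abs(scaler.inverse_transform(scaler.transform(X)) - X).max() < 1e-12

    def test_autoscaling_standardizes_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 3.0, size=(20, 6))
        Z = ColumnScaler("auto").fit(X).transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_pareto_scale_is_sqrt_of_sd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        scaler = ColumnScaler("pareto").fit(X)
        assert np.allclose(scaler.scales_, np.sqrt(X.std(axis=0, ddof=1)))

    def test_class_centroid_offset_is_mean_of_class_means(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 4.0], [4.0, 4.0]])
        labels = np.array(["A", "A", "B", "B"])
        scaler = ColumnScaler("class_centroid").fit(X, labels)
        # class means (1,0) and (3,4) -> offset (2,2)
        assert np.allclose(scaler.offsets_, [2.0, 2.0])

    def test_class_centroid_scaled_means_are_exact_negatives(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 9))
        labels = np.array(["Schizophrenia"] * 9 + ["Control"] * 5)
        scaler = ColumnScaler("class_centroid").fit(X, labels)
        Z = scaler.transform(X)
        mA = Z[labels == "Schizophrenia"].mean(axis=0)
        mB = Z[labels == "Control"].mean(axis=0)
        assert np.abs(mA + mB).max() < 1e-12

    def test_zero_variance_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(10), np.random.default_rng(0).normal(size=10)])
        with pytest.warns(UserWarning):
            scaler = ColumnScaler("auto").fit(X)
        assert list(scaler.dropped_columns_) == [0]
        assert scaler.transform(X).shape == (10, 1)


class TestPCA:
    def test_rank_one_matrix_explains_everything_on_pc1(self):
        u = np.arange(1.0, 7.0)
        v = np.array([1.0, -2.0, 0.5])
        pca = PCASpectra(n_components=2).fit(np.outer(u, v))
        assert pca.explained_variance_fraction_[0] == pytest.approx(1.0)
        assert 1 in pca.zero_variance_components_

    def test_full_rank_reconstruction(self):
        X = np.array(
            [[1.0, 2, 3], [4, 0, -1], [2, 2, 2], [-3, 1, 5]], dtype=float
        )
        pca = PCASpectra(n_components=3).fit(X)
        recon = pca.scores_ @ pca.loadings_.T
        assert np.abs(recon - X).max() < 1e-10
        assert np.abs(pca.loadings_.T @ pca.loadings_ - np.eye(3)).max() < 1e-10

    def test_variance_fractions_sum_below_one_and_non_increasing(self):
        rng = np.random.default_rng(2)
        pca = PCASpectra(n_components=4).fit(rng.normal(size=(30, 10)))
        frac = pca.explained_variance_fraction_
        assert frac.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(frac) <= 1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.decomposition import PCA as SKPCA

        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 12))
        Xc = X - X.mean(axis=0)
        ours = PCASpectra(n_components=3).fit(Xc)
        ref = SKPCA(n_components=3).fit(Xc)
        # loadings agree up to sign per component
        for k in range(3):
            dot = abs(ours.loadings_[:, k] @ ref.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_class_separation_on_strong_marker_cohort(self, clean_cohort):
        X = clean_cohort.intensities
        Xc = X - X.mean(axis=0)
        pca = PCASpectra(n_components=2).fit(Xc)
        case = clean_cohort.class_labels == "Schizophrenia"
        scores = pca.scores_
        centroid_gap = np.linalg.norm(
            scores[case].mean(axis=0) - scores[~case].mean(axis=0)
        )
        within = np.mean(
            [
                np.linalg.norm(scores[g] - scores[g].mean(axis=0), axis=1).mean()
                for g in (case, ~case)
            ]
        )
        assert centroid_gap > 2 * within


class TestOPLS:
    def test_no_structured_noise_yields_no_orthogonal_component(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, 0.0], 8)
        v = rng.normal(size=20)
        X = np.outer(y - y.mean(), v)  # only the y-correlated direction
        model = OPLS(n_orthogonal=2).fit(X, y)
        assert model.n_orthogonal_effective_ == 0

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_fitted_values_equal_pls1_with_one_more_component(self, k):
        X, y = random_two_class(seed=k + 10)
        model = OPLS(n_orthogonal=k).fit(X, y)
        oracle = nipals_pls1_fitted(X, y, k + 1)
        assert np.abs(model.fitted_values_ - oracle).max() < 1e-8

    def test_orthogonal_scores_uncorrelated_with_response(self):
        for seed in range(5):
            X, y = random_two_class(seed)
            model = OPLS(n_orthogonal=3).fit(X, y)
            if model.T_o_.size:
                assert np.abs(model.T_o_.T @ (y - y.mean())).max() < 1e-8
            assert np.abs(model.W_o_.T @ model.w_).max() < 1e-10

    def test_predicting_training_data_reproduces_fitted_values(self):
        X, y = random_two_class(seed=1)
        model = OPLS(n_orthogonal=2).fit(X, y)
        assert np.abs(model.predict(X) - model.fitted_values_).max() < 1e-10

    def test_orthogonal_loading_perturbation_leaves_prediction_unchanged(self):
        X, y = random_two_class(seed=2)
        model = OPLS(n_orthogonal=1).fit(X, y)
        x = X[0]
        perturbed = x + 3.0 * model.P_o_[:, 0]
        before = model.predict(x[None, :])
        after = model.predict(perturbed[None, :])
        assert abs(after[0] - before[0]) < 1e-8

    def test_held_out_class_means_on_correct_sides(self, clean_cohort):
        case = clean_cohort.class_labels == "Schizophrenia"
        y = case.astype(float)
        X = clean_cohort.intensities
        train = np.arange(X.shape[0]) % 3 != 0  # leave every 3rd sample out
        scaler = ColumnScaler("auto")
        with np.errstate(invalid="ignore"):
            scaler.fit(X[train])
        model = OPLS(n_orthogonal=1).fit(scaler.transform(X[train]), y[train])
        yhat = model.predict(scaler.transform(X[~train]))
        assert yhat[case[~train]].mean() > 0.5
        assert yhat[~case[~train]].mean() < 0.5

    def test_predictive_scores_match_training_scores(self):
        X, y = random_two_class(seed=6)
        model = OPLS(n_orthogonal=2).fit(X, y)
        assert np.abs(model.predictive_scores(X) - model.t_).max() < 1e-8


class TestBackscale:
    def test_center_scaling_returns_raw_loading(self):
        X, y = random_two_class(seed=3)
        scaler = ColumnScaler("center").fit(X)
        Xs = scaler.transform(X)
        model = OPLS(n_orthogonal=1).fit(Xs, y)
        backscaled, _ = backscale_loadings(model, scaler, Xs)
        assert np.allclose(backscaled, model.p_)

    def test_variable_equal_to_score_gets_weight_one(self):
        X, y = random_two_class(seed=4)
        model = OPLS(n_orthogonal=0).fit(X, y)
        X2 = np.column_stack([X, model.t_])
        model2 = OPLS(n_orthogonal=0).fit(X2, y)
        scaler = ColumnScaler("center").fit(X2)
        _, weights = backscale_loadings(model2, scaler, X2)
        assert weights[-1] == pytest.approx(1.0, abs=1e-12)

    def test_weights_equal_percolumn_pearson_oracle(self):
        X, y = random_two_class(seed=5)
        scaler = ColumnScaler("auto").fit(X)
        Xs = scaler.transform(X)
        model = OPLS(n_orthogonal=1).fit(Xs, y)
        _, weights = backscale_loadings(model, scaler, Xs)
        for i in range(Xs.shape[1]):
            r = np.corrcoef(Xs[:, i], model.t_)[0, 1]
            assert weights[i] == pytest.approx(abs(r), abs=1e-10)


class TestEncodeClasses:
    def test_case_class_coded_one(self):
        y, classes = encode_classes(["Control", "Schizophrenia", "Control"])
        assert classes == ("Control", "Schizophrenia")
        assert y.tolist() == [0.0, 1.0, 0.0]

    def test_rejects_non_binary_labels(self):
        with pytest.raises(ValueError):
            encode_classes(["a", "b", "c"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_scaling_invertibility_property(seed):
    """Any fitted scaler satisfies apply-then-invert identity."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 5)) * rng.uniform(0.1, 10.0, size=5)
    for method in ("center", "pareto", "auto"):
        scaler = ColumnScaler(method).fit(X)
        assert np.abs(scaler.inverse_transform(scaler.transform(X)) - X).max() < 1e-10


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        from serumnmr.models import load_model, save_model

        X, y = random_two_class(seed=9)
        labels = np.where(y == 1, "Schizophrenia", "Control")
        scaler = ColumnScaler("class_centroid").fit(X, labels)
        Xs = scaler.transform(X)
        model = OPLS(n_orthogonal=2).fit(Xs, y)
        path = tmp_path / "model.json"
        save_model(path, model, scaler)
        model2, scaler2 = load_model(path)
        Xnew = np.random.default_rng(1).normal(size=(5, X.shape[1]))
        a = model.predict(scaler.transform(Xnew))
        b = model2.predict(scaler2.transform(Xnew))
        assert np.allclose(a, b, atol=1e-12)
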