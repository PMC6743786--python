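"""Model-free decoders, knn and Gaussian-approximation baselines."""

import warnings

import numpy as np
import pytest

from trajinfo import (
    DecodingInfoEstimator,
    DendrogramSVC,
    GaussianDecoder,
    estimate_info,
    exponential_filter,
    gaussian_approximation_info,
    knn_mutual_information,
    make_decoder,
)


@pytest.fixture(scope="module")
def separable_data():
    """Two classes of constant trajectories: all zeros vs all ones."""
    X = np.vstack([np.zeros((30, 10)), np.ones((30, 10))])
    y = np.array(["a"] * 30 + ["b"] * 30)
    return X, y


@pytest.fixture(scope="module")
def gaussian_blobs():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1, (200, 5)), rng.normal(3, 1, (200, 5))])
    y = np.array(["a"] * 200 + ["b"] * 200)
    return X, y


class TestDecoders:
    @pytest.mark.parametrize("method", ["svm-linear", "svm-rbf", "gaussian-decoder"])
    def test_separable_degenerate_data_decoded_perfectly(self, separable_data, method):
        X, y = separable_data
        Xj = X + np.random.default_rng(0).normal(0, 1e-3, X.shape)  # break singularity
        dec = make_decoder(method, random_state=0)
        dec.fit(Xj, y)
        assert np.all(dec.predict(Xj) == y)

    def test_mlp_separates_constant_classes(self, separable_data):
        X, y = separable_data
        dec = make_decoder("mlp", random_state=0, hidden_layer_sizes=(20,),
                           max_iter=200, early_stopping=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec.fit(X, y)
        assert np.mean(dec.predict(X) == y) == 1.0

    def test_gaussian_decoder_chance_on_identical_statistics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (400, 5))
        y = np.array(["a", "b"] * 200)
        dec = GaussianDecoder(random_state=0).fit(X[:300], y[:300])
        acc = np.mean(dec.predict(X[300:]) == y[300:])
        assert abs(acc - 0.5) < 0.15

    def test_gaussian_decoder_regularization_selected(self, gaussian_blobs):
        X, y = gaussian_blobs
        dec = GaussianDecoder(random_state=0).fit(X, y)
        assert dec.reg_lambda_ > 0
        assert set(dec.classes_) == {"a", "b"}

    def test_dendrogram_multiclass(self):
        rng = np.random.default_rng(2)
        centers = [0.0, 4.0, 8.0]
        X = np.vstack([rng.normal(c, 1.0, (60, 4)) for c in centers])
        y = np.repeat(["a", "b", "c"], 60)
        dec = DendrogramSVC(kernel="linear", random_state=0).fit(X, y)
        assert np.mean(dec.predict(X) == y) > 0.9

    def test_linear_svm_fails_on_mean_matched_trajectories(self, ex3_discrete):
        # example 3 has identical conditional means: nothing linearly decodable
        X, y = ex3_discrete
        mean, std, _ = estimate_info(X, y, method="svm-linear", replicates=3,
                                     random_state=0)
        assert mean < 0.1


class TestDecodingInfoEstimator:
    def test_replicated_split_estimates(self, gaussian_blobs):
        X, y = gaussian_blobs
        est = DecodingInfoEstimator("gaussian-decoder", replicates=5,
                                    random_state=0).fit(X, y)
        assert len(est.infos_) == 5
        assert 0.8 < est.info_ <= 1.0  # 3-sigma-separated blobs decode well
        assert est.info_std_ >= 0
        assert est.confusion_.q == 2

    def test_same_seed_same_splits(self, gaussian_blobs):
        X, y = gaussian_blobs
        a = DecodingInfoEstimator("gaussian-decoder", replicates=3, random_state=7).fit(X, y)
        b = DecodingInfoEstimator("gaussian-decoder", replicates=3, random_state=7).fit(X, y)
        assert np.array_equal(a.infos_, b.infos_)

    def test_shuffle_control_near_zero(self, ex3_discrete):
        X, y = ex3_discrete
        est = DecodingInfoEstimator(
            "gaussian-decoder", replicates=5, shuffle_labels=True, random_state=0
        ).fit(X, y)
        assert est.info_ < 0.05

    def test_invalid_train_fraction(self, gaussian_blobs):
        X, y = gaussian_blobs
        with pytest.raises(ValueError):
            DecodingInfoEstimator(train_fraction=1.5).fit(X, y)


class TestKnnMutualInformation:
    def test_shuffled_labels_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (600, 10))
        y = rng.permutation(np.repeat(["a", "b"], 300))
        assert abs(knn_mutual_information(X, y, k=3)) < 0.1

    def test_well_separated_blobs_reach_one_bit(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (300, 3)), rng.normal(20, 1, (300, 3))])
        y = np.repeat(["a", "b"], 300)
        assert knn_mutual_information(X, y, k=1) == pytest.approx(1.0, abs=0.05)

    def test_integer_trajectories_crash_negative_without_jitter(self, ex3_discrete):
        # massive Chebyshev-distance ties on raw molecule counts inflate the
        # neighbor counts and drive the estimate strongly negative
        X, y = ex3_discrete
        raw = knn_mutual_information(X, y, k=1)
        assert raw < -0.5

    def test_jitter_repairs_tie_pathology(self, ex3_discrete):
        X, y = ex3_discrete
        raw = knn_mutual_information(X, y, k=1)
        jit = knn_mutual_information(X, y, k=1, jitter_sd=1e-3, random_state=0)
        assert jit > raw + 0.5  # close to zero instead of strongly negative
        assert -0.5 < jit < 0.3

    def test_duplicate_points_warn(self):
        X = np.zeros((40, 3))
        y = np.repeat(["a", "b"], 20)
        with pytest.warns(UserWarning, match="duplicate"):
            knn_mutual_information(X, y, k=1)

    def test_agrees_with_sklearn_on_scalar_responses(self):
        # sklearn's estimator works feature-wise, so the 1-D case is an
        # independent implementation of the same digamma construction
        from sklearn.feature_selection import mutual_info_classif

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (400, 1)), rng.normal(1.5, 1, (400, 1))])
        y = np.repeat([0, 1], 400)
        ours = knn_mutual_information(X, y, k=3)
        theirs = mutual_info_classif(X, y, n_neighbors=3, random_state=0)[0] / np.log(2)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_k_must_be_below_class_count(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError):
            knn_mutual_information(X, y, k=5)


class TestGaussianApproximation:
    def test_identical_classes_zero_bits(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (800, 3))
        y = np.repeat(["a", "b"], 400)
        val = gaussian_approximation_info(X, y, n_mc=4000, random_state=0)
        assert abs(val) < 0.05

    def test_far_separated_1d_classes_reach_one_bit(self):
        rng = np.random.default_rng(7)
        X = np.concatenate([rng.normal(0, 1, 1000), rng.normal(40, 1, 1000)])[:, None]
        y = np.repeat(["a", "b"], 1000)
        val = gaussian_approximation_info(X, y, n_mc=8000, random_state=0)
        assert val == pytest.approx(1.0, abs=0.05)

    def test_overestimates_on_discrete_count_data(self, ex3_discrete, examples):
        from trajinfo import exact_info

        X, y = ex3_discrete
        _, _, _, model = examples[3]
        approx = gaussian_approximation_info(X, y, n_mc=4000, random_state=0)
        # the Gaussian functional form is wrong for counts: no bound guarantee
        assert approx > 1.0  # exceeds even the q=2 entropy budget

    def test_singular_covariance_raises(self):
        X = np.zeros((40, 3))
        y = np.repeat(["a", "b"], 20)
        with pytest.raises(np.linalg.LinAlgError, match="reg"):
            gaussian_approximation_info(X, y)


class TestExponentialFilter:
    def test_tiny_tau_is_identity(self):
        X = np.random.default_rng(8).normal(size=(5, 20))
        assert np.allclose(exponential_filter(X, tau=1e-9, dt=1.0), X)

    def test_constant_rows_unchanged(self):
        X = np.full((3, 15), 4.0)
        assert np.allclose(exponential_filter(X, tau=50.0), X)

    def test_step_response_closed_form(self):
        X = np.zeros((1, 30))
        X[0, 10:] = 1.0
        out = exponential_filter(X, tau=5.0, dt=1.0)
        i = np.arange(1, 21)
        assert np.allclose(out[0, 10:], 1.0 - np.exp(-i / 5.0))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            exponential_filter(np.ones((2, 4)), tau=0.0)
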