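import numpy as np
import pytest
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import Ridge

from precursorpred import (
    ConfigError,
    DataError,
    FingerprintConfig,
    RidgeOvRModel,
    VarianceFilter,
    fit_pipeline,
    fit_ridge_ovr,
    fit_variance_filter,
    select_model,
    stratified_split,
)
from _oracles import ridge_objective_minimizer


class TestVarianceFilter:
    def test_constant_columns_removed(self):
        X = np.array([[0, 1, 0], [0, 1, 1], [0, 1, 0], [0, 1, 1]])
        f = fit_variance_filter(X, 0.01)
        assert f.kept_indices == (2,)

    def test_half_positive_column_kept_at_default_threshold(self):
        # p = 0.5 gives variance 0.25 > 0.0628
        X = np.array([[1], [0], [1], [0]])
        assert fit_variance_filter(X, 0.0628).kept_indices == (0,)

    def test_one_positive_in_fifteen_removed_at_default_threshold(self):
        # p(1-p) = (1/15)(14/15) ~ 0.0622 < 0.0628; checked by brute force below
        X = np.zeros((15, 1))
        X[0, 0] = 1
        brute = float(np.mean((X[:, 0] - X[:, 0].mean()) ** 2))
        assert brute < 0.0628
        assert fit_variance_filter(X, 0.0628).kept_indices == ()

    def test_kept_indices_strictly_increasing_and_match_sklearn(self, rng):
        X = (rng.random((40, 60)) < rng.random(60)).astype(float)
        f = fit_variance_filter(X, 0.0628)
        assert list(f.kept_indices) == sorted(set(f.kept_indices))
        sk = VarianceThreshold(0.0628).fit(X)
        assert list(f.kept_indices) == list(np.where(sk.get_support())[0])

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            fit_variance_filter(np.ones((1, 3)), 0.1)

    def test_transform_checks_width(self):
        f = fit_variance_filter(np.eye(4), 0.1)
        with pytest.raises(ConfigError):
            f.transform(np.ones((2, 5)))


class TestRidgeClosedForm:
    def test_identity_design_zero_alpha_reproduces_targets(self, rng):
        n = 12
        X = np.eye(n)
        y = rng.choice([0, 1], size=n)
        y[:2] = [0, 1]  # both classes present
        W, b, _ = fit_ridge_ovr(X, y, alpha=0.0, fit_intercept=False)
        t = 2.0 * y - 1.0
        assert np.allclose(W[:, 0], t)
        assert np.all(np.sign(X @ W[:, 0]) == t)

    def test_huge_alpha_shrinks_weights_to_intercept(self, rng):
        X = rng.random((30, 8))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        W1, _, _ = fit_ridge_ovr(X, y, alpha=1.0)
        Wb, bb, _ = fit_ridge_ovr(X, y, alpha=1e6)
        assert np.linalg.norm(Wb) < 1e-3 * np.linalg.norm(W1)
        t = 2.0 * y - 1.0
        scores = X @ Wb[:, 0] + bb[0]
        assert np.allclose(scores, t.mean(), atol=1e-2)

    def test_matches_iterative_minimizer_on_random_fixtures(self, rng):
        """Closed form agrees with a generic quasi-Newton optimizer to 1e-6."""
        for _ in range(20):
            n, d = int(rng.integers(10, 40)), int(rng.integers(2, 10))
            X = rng.normal(size=(n, d))
            y01 = (rng.random(n) < 0.5).astype(int)
            y01[:2] = [0, 1]
            alpha = float(rng.uniform(0.1, 10))
            W, b, _ = fit_ridge_ovr(X, y01, alpha=alpha)
            w_ref, b_ref = ridge_objective_minimizer(X, 2.0 * y01 - 1.0, alpha)
            assert np.allclose(W[:, 0], w_ref, atol=1e-6)
            assert abs(b[0] - b_ref) < 1e-6

    def test_matches_sklearn_ridge(self, rng):
        X = rng.normal(size=(25, 6))
        y01 = (rng.random(25) < 0.5).astype(int)
        y01[:2] = [0, 1]
        W, b, _ = fit_ridge_ovr(X, y01, alpha=2.5)
        sk = Ridge(alpha=2.5).fit(X, 2.0 * y01 - 1.0)
        assert np.allclose(W[:, 0], sk.coef_, atol=1e-8)
        assert abs(b[0] - sk.intercept_) < 1e-8

    def test_residual_norm_nondecreasing_in_alpha(self, rng):
        X = rng.normal(size=(30, 10))
        y01 = (rng.random(30) < 0.5).astype(int)
        y01[:2] = [0, 1]
        t = 2.0 * y01 - 1.0
        prev = -1.0
        for alpha in (0.01, 0.1, 1.0, 10.0, 100.0):
            W, b, _ = fit_ridge_ovr(X, y01, alpha=alpha)
            res = float(np.linalg.norm(X @ W[:, 0] + b[0] - t))
            assert res >= prev - 1e-9
            prev = res

    def test_negative_alpha_rejected(self):
        with pytest.raises(ConfigError):
            fit_ridge_ovr(np.eye(3), np.array([0, 1, 1]), alpha=-1.0)

    def test_zero_alpha_rank_deficient_advises_regularization(self):
        X = np.ones((5, 3))  # rank 1
        with pytest.raises(DataError, match="alpha"):
            fit_ridge_ovr(X, np.array([0, 1, 1, 0, 1]), alpha=0.0)

    def test_single_class_label_gets_constant_predictor(self):
        X = np.eye(4)
        Y = np.array([[1, 0], [1, 1], [1, 0], [1, 1]])
        W, b, degenerate = fit_ridge_ovr(X, Y, alpha=1.0)
        assert degenerate == [0]
        assert np.allclose(W[:, 0], 0.0) and b[0] == 1.0


class TestPredict:
    def _tiny_model(self, clean_dataset, **kw):
        sp = stratified_split(clean_dataset, seed=0)
        tr = clean_dataset.subset(sp.train_idx)
        model = fit_pipeline(tr.records, tr.labels, clean_dataset.vocab,
                             FingerprintConfig(n_bits=512), **kw)
        return model, clean_dataset.subset(sp.test_idx)

    def test_zero_score_is_inactive(self, clean_dataset):
        model, test = self._tiny_model(clean_dataset)
        zero = RidgeOvRModel(
            W=np.zeros_like(model.W), b=np.zeros_like(model.b), alpha=model.alpha,
            filter=model.filter, fp_config=model.fp_config, vocab=model.vocab,
        )
        assert not zero.predict_labels(test.records[:5]).any()

    def test_deterministic(self, clean_dataset):
        model, test = self._tiny_model(clean_dataset)
        a = model.predict_labels(test.records)
        b = model.predict_labels(test.records)
        assert np.array_equal(a, b)

    def test_ovr_column_independence(self, clean_dataset):
        model, test = self._tiny_model(clean_dataset)
        before = model.predict_labels(test.records)
        model.W[:, 1] = -model.W[:, 1]
        model.b[1] = -model.b[1]
        after = model.predict_labels(test.records)
        others = [j for j in range(before.shape[1]) if j != 1]
        assert np.array_equal(before[:, others], after[:, others])

    def test_fingerprint_width_mismatch_rejected(self, clean_dataset):
        model, test = self._tiny_model(clean_dataset)
        with pytest.raises(ConfigError):
            model.decision_scores(test.records, X=np.ones((2, 64)))

    def test_json_round_trip_preserves_predictions(self, clean_dataset, tmp_path):
        model, test = self._tiny_model(clean_dataset)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RidgeOvRModel.from_json(path)
        assert np.array_equal(model.predict_labels(test.records), back.predict_labels(test.records))
        assert np.allclose(model.decision_scores(test.records), back.decision_scores(test.records))


class TestRecoveryUnderNoise:
    def test_noisy_labels_still_beat_frequency_matched_random_baseline(self):
        """With 20% label noise the pipeline degrades but stays above the
        analytic random-guess baseline (per label, a frequency-matched random
        guesser has precision = recall = F1 = the observed positive rate)."""
        from precursorpred import DEFAULT_RULES, evaluate, generate_dataset, with_noise

        noise = 0.2
        ds = generate_dataset(400, rules=with_noise(DEFAULT_RULES, noise), seed=31)
        train, test = ds.subset(range(300)), ds.subset(range(300, 400))
        model = fit_pipeline(train.records, train.labels, ds.vocab, FingerprintConfig())
        rep = evaluate(test.labels, model.predict_labels(test.records), list(ds.vocab))
        rates = [r.target_frequency * (1 - noise) + (1 - r.target_frequency) * noise
                 for r in DEFAULT_RULES]
        baseline_mf1 = float(np.mean(rates))
        assert rep["macro"]["m_f1"] > baseline_mf1


class TestSelectModel:
    def _splits(self, clean_dataset):
        sp = stratified_split(clean_dataset, seed=1)
        return clean_dataset.subset(sp.train_idx), clean_dataset.subset(sp.valid_idx)

    def test_single_candidate_grid_returns_it(self, clean_dataset):
        tr, va = self._splits(clean_dataset)
        model, log = select_model(
            tr.records, tr.labels, va.records, va.labels, clean_dataset.vocab,
            alpha_grid=[3.0], tau_grid=[0.05], radius_grid=[1], n_bits=512,
        )
        assert model.alpha == 3.0 and model.filter.threshold == 0.05
        assert len(log) == 1

    def test_winner_attains_max_logged_mf1_and_tie_break(self, clean_dataset):
        tr, va = self._splits(clean_dataset)
        model, log = select_model(
            tr.records, tr.labels, va.records, va.labels, clean_dataset.vocab,
            alpha_grid=[0.5, 1.0], tau_grid=[0.0628], radius_grid=[2], n_bits=512,
        )
        best_row = log.loc[log["valid_mF1"].idxmax()]
        assert log[(log.alpha == model.alpha) & (log.tau == model.filter.threshold)][
            "valid_mF1"
        ].iloc[0] == pytest.approx(log["valid_mF1"].max())
        ties = log[log["valid_mF1"] == log["valid_mF1"].max()]
        assert model.alpha == ties["alpha"].min()

    def test_empty_grid_rejected(self, clean_dataset):
        tr, va = self._splits(clean_dataset)
        with pytest.raises(ConfigError):
            select_model(tr.records, tr.labels, va.records, va.labels,
                         clean_dataset.vocab, alpha_grid=[])
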