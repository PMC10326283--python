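import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from ecogspeech import lindec
from ecogspeech.neurofeat import WindowingConfig
from ecogspeech.tracks import FeatureTrack


class TestZScore:
    def test_train_columns_standardized(self, rng):
        X = rng.standard_normal((200, 5)) * [1, 2, 3, 4, 5] + 7
        st = lindec.fit_zscore(X)
        Z = lindec.apply_zscore(st, X)
        assert np.all(np.abs(Z.mean(0)) < 1e-10)
        assert np.all(np.abs(Z.std(0) - 1) < 1e-10)

    def test_constant_feature_maps_to_zero(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 1] = 4.2
        st = lindec.fit_zscore(X)
        assert st.std[1] == 1.0
        assert np.all(lindec.apply_zscore(st, X)[:, 1] == 0)

    def test_state_depends_only_on_train_data(self, rng):
        X = rng.standard_normal((100, 3))
        st = lindec.fit_zscore(X)
        test = rng.standard_normal((50, 3)) * 100
        Z1 = lindec.apply_zscore(st, test)
        assert np.allclose(Z1, (test - st.mean) / st.std)

    def test_invert_roundtrip(self, rng):
        X = rng.standard_normal((100, 3))
        st = lindec.fit_zscore(X)
        assert np.allclose(lindec.invert_zscore(st, lindec.apply_zscore(st, X)), X)


class TestPCA:
    def test_rank2_data_reconstructs_exactly(self, rng):
        basis = rng.standard_normal((2, 6))
        X = rng.standard_normal((100, 2)) @ basis
        st = lindec.fit_pca(X, 2)
        Z = lindec.apply_pca(st, X)
        recon = Z @ st.components + st.mean
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_components_orthonormal(self, rng):
        st = lindec.fit_pca(rng.standard_normal((80, 10)), 4)
        gram = st.components @ st.components.T
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ValueError):
            lindec.fit_pca(rng.standard_normal((10, 5)), 6)


class TestOLS:
    def test_recovers_noiseless_weights(self, rng):
        X = rng.standard_normal((100, 8))
        W0 = rng.standard_normal((8, 3))
        W, b = lindec.fit_ols(X, X @ W0 + 2.0)
        assert np.max(np.abs(W - W0)) < 1e-8
        assert np.allclose(b, 2.0, atol=1e-8)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((200, 10))
        Y = X @ rng.standard_normal((10, 4)) + 0.1 * rng.standard_normal((200, 4))
        W, _ = lindec.fit_ols(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        Wn = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        assert np.max(np.abs(W - Wn)) < 1e-8

    def test_zero_output_column_gets_zero_weights(self, rng):
        X = rng.standard_normal((100, 5))
        Y = np.column_stack([X @ rng.standard_normal(5), np.zeros(100)])
        W, _ = lindec.fit_ols(X, Y)
        assert np.max(np.abs(W[:, 1])) < 1e-10

    def test_rank_deficient_warns_and_returns_min_norm(self, rng):
        X = rng.standard_normal((10, 20))
        Y = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning):
            W, _ = lindec.fit_ols(X, Y)
        assert np.all(np.isfinite(W))


class TestRidge:
    def test_small_lambda_limit_is_ols(self, rng):
        X = rng.standard_normal((200, 6))
        Y = X @ rng.standard_normal((6, 2))
        W, _, lam = lindec.fit_ridge(X, Y, method="lcurve")
        Wo, _ = lindec.fit_ols(X, Y)
        # noise-free well-posed problem: degenerate L-curve -> smallest grid value
        assert lam == pytest.approx(lindec.DEFAULT_LAMBDA_GRID[0])
        assert np.max(np.abs(W - Wo)) < 1e-4

    def test_weight_norm_shrinks_monotonically(self, rng):
        X = rng.standard_normal((100, 8))
        Y = X @ rng.standard_normal((8, 2)) + rng.standard_normal((100, 2))
        norms = []
        for lam in (1e-2, 1e0, 1e2, 1e4):
            xm, ym, Q, evals, B, _ = lindec._ridge_path_stats(X, Y, np.array([lam]))
            W = lindec._ridge_weights(Q, evals, B, lam)
            norms.append(np.linalg.norm(W))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            lindec.fit_ridge(rng.standard_normal((10, 2)),
                             rng.standard_normal(10), grid=np.array([]))

    def test_per_output_selection_tracks_output_noise(self):
        # the noisier output column should get the stronger penalty
        rng = np.random.default_rng(0)
        W0 = rng.standard_normal((10, 2))
        hits = 0
        for s in range(50):
            X = rng.standard_normal((100, 10))
            Y = np.column_stack([
                X @ W0[:, 0] + 0.1 * rng.standard_normal(100),
                X @ W0[:, 1] + 10.0 * rng.standard_normal(100),
            ])
            _, _, lams = lindec.fit_ridge(X, Y, method="cv_multi", seed=s)
            hits += lams[1] > lams[0]
        assert hits >= 45  # >= 90% of 50 seeded runs

    def test_lcurve_finds_corner_on_illposed_problem(self, rng):
        # strongly collinear design with noise: corner should sit strictly
        # inside the grid
        base = rng.standard_normal((200, 3))
        X = np.hstack([base, base + 1e-4 * rng.standard_normal((200, 3))])
        Y = base @ rng.standard_normal((3, 1)) + 0.5 * rng.standard_normal((200, 1))
        _, _, lam = lindec.fit_ridge(X, Y, method="lcurve")
        grid = lindec.DEFAULT_LAMBDA_GRID
        assert grid[0] < lam < grid[-1]


class TestPLS:
    def test_full_rank_matches_ols_predictions(self, rng):
        X = rng.standard_normal((150, 10))
        Y = X @ rng.standard_normal((10, 3)) + 0.2 * rng.standard_normal((150, 3))
        m = lindec.fit_pls(X, Y, 10)
        W, b = lindec.fit_ols(X, Y)
        pred_pls = X @ m.weights + (m.y_mean - m.x_mean @ m.weights)
        pred_ols = X @ W + b
        assert np.max(np.abs(pred_pls - pred_ols)) < 1e-6

    def test_single_latent_direction_needs_one_component(self, rng):
        # large n so the sample covariance is near-spherical: the first PLS
        # weight then aligns with the generating direction
        X = rng.standard_normal((5000, 8))
        d = rng.standard_normal(8)
        Y = np.outer(X @ d, rng.standard_normal(3))
        m = lindec.fit_pls(X, Y, 1)
        pred = X @ m.weights + (m.y_mean - m.x_mean @ m.weights)
        resid = Y - pred
        assert resid.var() < 0.01 * Y.var()

    def test_matches_sklearn_nipals(self, rng):
        X = rng.standard_normal((120, 9))
        Y = X @ rng.standard_normal((9, 3)) + 0.3 * rng.standard_normal((120, 3))
        m = lindec.fit_pls(X, Y, 4, tol=1e-12)
        sk = PLSRegression(n_components=4, scale=False, tol=1e-12,
                           max_iter=2000).fit(X, Y)
        ours = X @ m.weights + (m.y_mean - m.x_mean @ m.weights)
        assert np.max(np.abs(ours - sk.predict(X))) < 1e-5

    def test_invariant_to_rotation_of_targets(self, rng):
        X = rng.standard_normal((100, 6))
        Y = X @ rng.standard_normal((6, 3)) + 0.1 * rng.standard_normal((100, 3))
        R = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        m1 = lindec.fit_pls(X, Y, 3, tol=1e-12)
        m2 = lindec.fit_pls(X, Y @ R, 3, tol=1e-12)
        p1 = X @ m1.weights + (m1.y_mean - m1.x_mean @ m1.weights)
        p2 = (X @ m2.weights + (m2.y_mean - m2.x_mean @ m2.weights)) @ R.T
        assert np.max(np.abs(p1 - p2)) < 1e-6

    def test_component_bound_enforced(self, rng):
        with pytest.raises(ValueError):
            lindec.fit_pls(rng.standard_normal((10, 4)),
                           rng.standard_normal((10, 2)), 11)


def _tracks(rng, n_sent=4, n_frames=60, n_in=6, n_out=2, w=None):
    w = rng.standard_normal((n_in, n_out)) if w is None else w
    xs, ys = [], []
    for _ in range(n_sent):
        X = rng.standard_normal((n_frames, n_in))
        xs.append(FeatureTrack(X, [f"x{i}" for i in range(n_in)]))
        ys.append(FeatureTrack(X @ w, [f"y{i}" for i in range(n_out)]))
    return xs, ys


class TestLinearDecoderPipeline:
    @pytest.mark.parametrize("kind", lindec.DECODER_KINDS)
    def test_all_decoders_share_fit_predict_contract(self, rng, kind):
        xs, ys = _tracks(rng)
        dec = lindec.LinearDecoder(kind=kind, n_components=6)
        dec.fit(xs[:3], ys[:3])
        pred = dec.predict(xs[3])
        assert pred.n_frames == xs[3].n_frames
        assert pred.n_features == 2

    def test_noiseless_recovery_on_training_data(self, rng):
        xs, ys = _tracks(rng)
        dec = lindec.LinearDecoder(kind="ols").fit(xs, ys)
        pred = dec.predict(xs[0])
        assert np.max(np.abs(pred.data - ys[0].data)) < 1e-6

    def test_zero_input_predicts_training_mean(self, rng):
        xs, ys = _tracks(rng)
        dec = lindec.LinearDecoder(kind="ols").fit(xs, ys)
        zero = FeatureTrack(np.zeros((10, 6)), xs[0].labels)
        pred = dec.predict(zero)
        target_mean = np.vstack([y.data for y in ys]).mean(0)
        # z-scored zero input equals the (negative) feature mean, so the
        # prediction of an all-zero track is constant
        assert np.allclose(pred.data, pred.data[0])
        assert np.allclose(pred.data[0], target_mean, atol=2.0)

    def test_pipeline_order_zscore_delay_pca_context(self, rng):
        """The preprocessing order is observable: PCA fitted on delayed
        (not raw) features changes the basis when the delay is nonzero,
        and context concatenation happens after PCA (dimension check)."""
        xs, ys = _tracks(rng, n_sent=3, n_frames=80)
        dec = lindec.LinearDecoder(
            kind="ols", windowing=WindowingConfig(50.0, -100.0), n_pca=3
        ).fit(xs, ys)
        m = dec.model
        # context applied after PCA: weight rows = n_pca x context frames
        assert m.weights.shape[0] == 3 * 5
        # PCA basis has n_pca orthonormal rows over the raw feature space
        assert m.pca.components.shape == (3, 6)

    def test_delay_shifts_neural_window(self, rng):
        """An impulse in the neural features lands on the decoded frame
        shifted by -delay: negative delay reads from the neural past."""
        n = 50
        X = np.zeros((n, 1))
        X[30, 0] = 1.0
        xs = [FeatureTrack(X, ["x"])]
        Y = np.zeros((n, 1))
        Y[40, 0] = 1.0  # y(40) should see x(30) with delay -100 ms
        ys = [FeatureTrack(Y, ["y"])]
        dec = lindec.LinearDecoder(
            kind="ols", windowing=WindowingConfig(0.0, -100.0)
        ).fit(xs, ys)
        pred = dec.predict(xs[0])
        assert pred.data[40, 0] == pytest.approx(1.0, abs=1e-6)

    def test_save_load_roundtrip(self, rng, tmp_path):
        xs, ys = _tracks(rng)
        dec = lindec.LinearDecoder(kind="ridge_cv", n_pca=4,
                                   windowing=WindowingConfig(50.0, 0.0))
        dec.fit(xs, ys)
        path = tmp_path / "model.npz"
        dec.save(path)
        loaded = lindec.LinearDecoder.load(path)
        p1, p2 = dec.predict(xs[0]), loaded.predict(xs[0])
        assert np.array_equal(p1.data, p2.data)

    def test_dimension_mismatch_rejected(self, rng):
        xs, ys = _tracks(rng)
        dec = lindec.LinearDecoder(kind="ols").fit(xs, ys)
        bad = FeatureTrack(np.zeros((10, 7)), [f"x{i}" for i in range(7)])
        with pytest.raises(ValueError):
            dec.predict(bad)
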