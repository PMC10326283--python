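"""Preprocessing and the five linear decoders.

Decoding pipeline (fitted on training folds only, applied unchanged to the
test fold): per-feature z-scoring -> time delay -> optional PCA of the
neural features -> temporal-context concatenation -> linear weights.  PCA
is computed before context concatenation; PLS performs its reduction after
context concatenation as part of the regression itself.

Decoder kinds:

``ols``
    plain least squares (minimum-norm solution on rank-deficient input)
``ridge_lcurve``
    ridge with the regularization strength at the maximum-curvature corner
    of the log residual-norm vs log solution-norm curve
``ridge_cv``
    ridge with the strength minimizing inner 5-fold validation MSE
``ridge_cv_multi``
    as ``ridge_cv`` but with an independent strength per output feature
``pls``
    PLS2 regression (NIPALS with deflation, shared latent space)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .neurofeat import WindowingConfig, delay_features, window_features
from .tracks import FeatureTrack

DECODER_KINDS = ("ols", "ridge_lcurve", "ridge_cv", "ridge_cv_multi", "pls")
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 25)
FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# z-scoring and PCA

@dataclass
class ZScoreState:
    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray | None = None  # zero-variance feature mask


def fit_zscore(X: np.ndarray) -> ZScoreState:
    """Per-feature mean/sd from the training set; zero-variance features get
    sd = 1 and map to an exact constant 0, keeping dimensions stable."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames to fit z-score statistics")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    constant = std < 1e-12
    std = np.where(constant, 1.0, std)
    return ZScoreState(mean, std, constant)


def apply_zscore(state: ZScoreState, X: np.ndarray) -> np.ndarray:
    Z = (np.asarray(X, dtype=float) - state.mean) / state.std
    if state.constant is not None and state.constant.any():
        Z[:, state.constant] = 0.0
    return Z


def invert_zscore(state: ZScoreState, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) * state.std + state.mean


@dataclass
class PCAState:
    components: np.ndarray  # n_components x n_features, orthonormal rows
    mean: np.ndarray


def fit_pca(X: np.ndarray, n_components: int) -> PCAState:
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(frames, features)")
    p = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    p.fit(X)
    return PCAState(p.components_.copy(), p.mean_.copy())


def apply_pca(state: PCAState, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - state.mean) @ state.components.T


# ---------------------------------------------------------------------------
# decoder fits (weights act on preprocessed inputs; intercept included)

def fit_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares weights and intercept (minimum-norm if rank-deficient)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    W, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient design: returning minimum-norm solution")
    return W, ym - xm @ W


def _ridge_path_stats(X: np.ndarray, Y: np.ndarray, grid: np.ndarray):
    """Eigendecomposition path: weights + norms for every grid value."""
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    gram = Xc.T @ Xc
    evals, Q = np.linalg.eigh(gram)
    evals = np.maximum(evals, 0.0)
    B = Q.T @ (Xc.T @ Yc)  # eigenbasis cross-covariance, d x q
    y_sq = float(np.sum(Yc**2))
    return xm, ym, Q, evals, B, y_sq


def _ridge_weights(Q, evals, B, lam: float | np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 0:
        shrink = 1.0 / (evals + float(lam))
        return Q @ (B * shrink[:, None])
    # per-output lambda
    return Q @ (B / (evals[:, None] + lam[None, :]))


def fit_ridge(
    X: np.ndarray,
    Y: np.ndarray,
    method: str = "cv",
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | float]:
    """Ridge regression with the regularization strength chosen by
    ``method``: 'lcurve', 'cv' (one shared strength) or 'cv_multi' (one per
    output).  Returns (weights, intercept, selected strength(s))."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty regularization grid")
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T

    if method == "lcurve":
        xm, ym, Q, evals, B, y_sq = _ridge_path_stats(X, Y, grid)
        lam = _lcurve_corner(grid, evals, B, y_sq)
        W = _ridge_weights(Q, evals, B, lam)
        return W, ym - xm @ W, lam

    if method not in ("cv", "cv_multi"):
        raise ValueError(f"unknown ridge method {method!r}")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    fold_of = rng.permuted(np.arange(n) % n_folds)
    q = Y.shape[1]
    mse = np.zeros((len(grid), q))
    # inner-fold Gram matrices by subtraction from the full-data sums:
    # avoids recomputing an O(n d^2) product per fold
    gram_full = X.T @ X
    cross_full = X.T @ Y
    xsum_full, ysum_full = X.sum(axis=0), Y.sum(axis=0)
    for f in range(n_folds):
        val = fold_of == f
        Xv, Yv_raw = X[val], Y[val]
        n_tr = n - int(val.sum())
        xm = (xsum_full - Xv.sum(axis=0)) / n_tr
        ym = (ysum_full - Yv_raw.sum(axis=0)) / n_tr
        gram = gram_full - Xv.T @ Xv - n_tr * np.outer(xm, xm)
        cross = cross_full - Xv.T @ Yv_raw - n_tr * np.outer(xm, ym)
        evals, Q = np.linalg.eigh(gram)
        evals = np.maximum(evals, 0.0)
        B = Q.T @ cross
        XvQ = (Xv - xm) @ Q
        Yv = Yv_raw - ym
        for g, lam in enumerate(grid):
            pred = XvQ @ (B / (evals + lam)[:, None])
            mse[g] += np.sum((pred - Yv) ** 2, axis=0)
    xm, ym, Q, evals, B, _ = _ridge_path_stats(X, Y, grid)
    if method == "cv":
        lam = float(grid[int(np.argmin(mse.sum(axis=1)))])
        W = _ridge_weights(Q, evals, B, lam)
    else:
        lam = grid[np.argmin(mse, axis=0)]
        W = _ridge_weights(Q, evals, B, lam)
    return W, ym - xm @ W, lam


def _lcurve_corner(grid: np.ndarray, evals, B, y_sq: float) -> float:
    """Maximum-curvature corner of the (log residual, log solution) curve.

    Degenerate curves (residual norm essentially flat across the grid, as
    on noise-free well-posed problems) fall back to the smallest strength.
    """
    shrink = 1.0 / (evals[:, None] + grid[None, :])  # d x G
    sol_sq = np.einsum("dq,dg->g", B**2, shrink**2)
    fit_part = np.einsum("dq,dg,d->g", B**2, shrink**2, evals)
    cross = np.einsum("dq,dg->g", B**2, shrink)
    res_sq = np.maximum(y_sq - 2.0 * cross + fit_part, 1e-300)
    x = 0.5 * np.log(res_sq)
    y = 0.5 * np.log(np.maximum(sol_sq, 1e-300))
    if x.max() - x.min() < 1e-6:
        return float(grid[0])
    # light smoothing before finite-difference curvature
    k = np.ones(3) / 3.0
    xs = np.convolve(np.pad(x, 1, mode="edge"), k, mode="valid")
    ys = np.convolve(np.pad(y, 1, mode="edge"), k, mode="valid")
    t = np.log(grid)
    x1, y1 = np.gradient(xs, t), np.gradient(ys, t)
    x2, y2 = np.gradient(x1, t), np.gradient(y1, t)
    denom = (x1**2 + y1**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (x1 * y2 - y1 * x2) / denom, -np.inf)
    return float(grid[int(np.argmax(kappa))])


# ---------------------------------------------------------------------------
# PLS2 (NIPALS with deflation)

@dataclass
class PLSModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # equivalent linear map, inputs x outputs
    intercept: np.ndarray
    n_components: int


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PLSModel:
    """PLS2 regression: shared latent space, NIPALS inner loop, X deflation.

    The fitted model is exposed as an equivalent linear weight matrix
    ``B = W (P'W)^-1 C'`` so PLS is interchangeable with the other linear
    decoders.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError("n_components out of range")
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym

    if Xc.shape[0] < Xc.shape[1]:
        # tall-thin in the wrong direction: score-space NIPALS is cheaper
        # than building the d x d Gram
        return _fit_pls_scores(Xc, Yc, xm, ym, n_components, max_iter, tol)

    # NIPALS in covariance space: the inner w/c iteration has the same
    # fixed point as the classic score iteration, and deflating the Gram
    # and cross-covariance matrices is algebraically identical to deflating
    # X and Y themselves — but each component costs O(d^2) instead of
    # O(n d) passes over the data.
    S = Xc.T @ Xc  # d x d
    C = Xc.T @ Yc  # d x q
    G = np.einsum("ij,ij->j", Yc, Yc)  # deflated target variances

    d, q = C.shape
    Wmat = np.zeros((d, n_components))
    Pmat = np.zeros((d, n_components))
    Cmat = np.zeros((q, n_components))
    n_found = 0
    for a in range(n_components):
        if np.max(G) <= 1e-12 or np.linalg.norm(C) <= 1e-12:
            break
        c = np.zeros(q)
        c[int(np.argmax(G))] = 1.0
        w = None
        for _ in range(max_iter):
            w_new = C @ c
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            tt = w_new @ S @ w_new
            if tt <= 0:
                break
            c = C.T @ w_new / tt
            if w is not None and np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        if w is None:
            break
        a_vec = S @ w
        tt = w @ a_vec
        if tt <= 1e-12:
            break
        p = a_vec / tt
        c = C.T @ w / tt
        Wmat[:, a], Pmat[:, a], Cmat[:, a] = w, p, c
        S -= np.outer(a_vec, a_vec) / tt
        C -= np.outer(a_vec, c)
        G = G - tt * c**2
        n_found = a + 1

    Wmat, Pmat, Cmat = Wmat[:, :n_found], Pmat[:, :n_found], Cmat[:, :n_found]
    R = Wmat @ np.linalg.pinv(Pmat.T @ Wmat)
    B = R @ Cmat.T
    return PLSModel(xm, ym, B, ym - xm @ B, n_components)


def _fit_pls_scores(Xc, Yc, xm, ym, n_components, max_iter, tol) -> PLSModel:
    """Classic score-space NIPALS PLS2 (used when n < d)."""
    d, q = Xc.shape[1], Yc.shape[1]
    Wmat = np.zeros((d, n_components))
    Pmat = np.zeros((d, n_components))
    Cmat = np.zeros((q, n_components))
    Xd, Yd = Xc.copy(), Yc.copy()
    n_found = 0
    for a in range(n_components):
        yvar = np.einsum("ij,ij->j", Yd, Yd)
        if yvar.max() <= 1e-12:
            break
        # the score-space u/t iteration visits the same direction sequence
        # as a power iteration on the cross-covariance Xd'Yd; iterating
        # there costs O(dq) per step instead of O(nd)
        cross = Xd.T @ Yd  # d x q
        c = np.zeros(Yd.shape[1])
        c[int(np.argmax(yvar))] = 1.0
        w_old = None
        for _ in range(max_iter):
            w = cross @ c
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            c = cross.T @ w
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-12:
            break
        p = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Wmat[:, a], Pmat[:, a], Cmat[:, a] = w, p, c
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, c)
        n_found = a + 1
    Wmat, Pmat, Cmat = Wmat[:, :n_found], Pmat[:, :n_found], Cmat[:, :n_found]
    R = Wmat @ np.linalg.pinv(Pmat.T @ Wmat)
    B = R @ Cmat.T
    return PLSModel(xm, ym, B, ym - xm @ B, n_components)


# ---------------------------------------------------------------------------
# full decoder pipeline

@dataclass
class DecoderModel:
    """Fitted decoder: preprocessing state + equivalent weight matrix."""

    kind: str
    windowing: WindowingConfig
    x_zscore: ZScoreState
    y_zscore: ZScoreState
    pca: PCAState | None
    weights: np.ndarray
    intercept: np.ndarray
    hyper: object = None
    y_labels: list[str] = field(default_factory=list)


class LinearDecoder:
    """Common fit/predict surface for the five linear decoding methods.

    Operates on lists of per-sentence feature tracks so that delay and
    context windowing never cross sentence boundaries (edge frames use
    replication, keeping the per-sentence frame count intact).
    """

    def __init__(
        self,
        kind: str = "pls",
        windowing: WindowingConfig | None = None,
        n_pca: int | None = None,
        n_components: int = 12,
        lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
        seed: int = 0,
    ):
        if kind not in DECODER_KINDS:
            raise ValueError(f"unknown decoder kind {kind!r}")
        self.kind = kind
        self.windowing = windowing or WindowingConfig()
        self.n_pca = n_pca
        self.n_components = n_components
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)
        self.seed = seed
        self.model: DecoderModel | None = None

    # -- preprocessing used identically at fit and predict time -------------
    def _design_sentence(self, X: FeatureTrack, pca: PCAState | None,
                         xz: ZScoreState) -> np.ndarray:
        Xz = apply_zscore(xz, X.data)
        track = FeatureTrack(Xz, list(X.labels), X.rate)
        track = delay_features(track, self.windowing.delay_frames)
        if pca is not None:
            track = FeatureTrack(apply_pca(pca, track.data),
                                 [f"pc{i}" for i in range(pca.components.shape[0])],
                                 track.rate)
        ctx = WindowingConfig(context_ms=self.windowing.context_ms, delay_ms=0.0)
        return window_features(track, ctx).data

    def fit(self, X_list: list[FeatureTrack], Y_list: list[FeatureTrack]) -> "LinearDecoder":
        if len(X_list) != len(Y_list) or not X_list:
            raise ValueError("need matching, non-empty X and Y sentence lists")
        xz = fit_zscore(np.vstack([x.data for x in X_list]))
        yz = fit_zscore(np.vstack([y.data for y in Y_list]))

        pca = None
        if self.n_pca is not None and self.kind != "pls":
            delayed = [
                delay_features(
                    FeatureTrack(apply_zscore(xz, x.data), list(x.labels), x.rate),
                    self.windowing.delay_frames,
                ).data
                for x in X_list
            ]
            pca = fit_pca(np.vstack(delayed), self.n_pca)

        X = np.vstack([self._design_sentence(x, pca, xz) for x in X_list])
        Y = np.vstack([apply_zscore(yz, y.data) for y in Y_list])

        hyper = None
        if self.kind == "ols":
            W, b = fit_ols(X, Y)
        elif self.kind.startswith("ridge"):
            method = {"ridge_lcurve": "lcurve", "ridge_cv": "cv",
                      "ridge_cv_multi": "cv_multi"}[self.kind]
            W, b, hyper = fit_ridge(X, Y, method=method, grid=self.lambda_grid,
                                    seed=self.seed)
        else:
            m = fit_pls(X, Y, self.n_components)
            W, b, hyper = m.weights, m.y_mean - m.x_mean @ m.weights, self.n_components
        self.model = DecoderModel(
            kind=self.kind, windowing=self.windowing, x_zscore=xz, y_zscore=yz,
            pca=pca, weights=W, intercept=b, hyper=hyper,
            y_labels=list(Y_list[0].labels),
        )
        return self

    def predict(self, X: FeatureTrack) -> FeatureTrack:
        if self.model is None:
            raise RuntimeError("decoder is not fitted")
        m = self.model
        design = self._design_sentence(X, m.pca, m.x_zscore)
        if design.shape[1] != m.weights.shape[0]:
            raise ValueError("input dimension does not match the fitted model")
        pred_z = design @ m.weights + m.intercept
        return FeatureTrack(invert_zscore(m.y_zscore, pred_z), list(m.y_labels))

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        if self.model is None:
            raise RuntimeError("nothing to save: decoder is not fitted")
        m = self.model
        meta = {
            "format_version": FORMAT_VERSION,
            "kind": m.kind,
            "context_ms": m.windowing.context_ms,
            "delay_ms": m.windowing.delay_ms,
            "n_pca": self.n_pca,
            "n_components": self.n_components,
            "seed": self.seed,
            "y_labels": m.y_labels,
        }
        arrays = {
            "x_mean": m.x_zscore.mean, "x_std": m.x_zscore.std,
            "y_mean": m.y_zscore.mean, "y_std": m.y_zscore.std,
            "weights": m.weights, "intercept": m.intercept,
            "lambda_grid": self.lambda_grid,
        }
        if m.pca is not None:
            arrays["pca_components"] = m.pca.components
            arrays["pca_mean"] = m.pca.mean
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "LinearDecoder":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != FORMAT_VERSION:
                raise ValueError("unsupported model format version")
            dec = cls(
                kind=meta["kind"],
                windowing=WindowingConfig(meta["context_ms"], meta["delay_ms"]),
                n_pca=meta["n_pca"], n_components=meta["n_components"],
                lambda_grid=z["lambda_grid"], seed=meta["seed"],
            )
            pca = None
            if "pca_components" in z:
                pca = PCAState(z["pca_components"], z["pca_mean"])
            dec.model = DecoderModel(
                kind=meta["kind"],
                windowing=dec.windowing,
                x_zscore=ZScoreState(z["x_mean"], z["x_std"]),
                y_zscore=ZScoreState(z["y_mean"], z["y_std"]),
                pca=pca, weights=z["weights"], intercept=z["intercept"],
                y_labels=list(meta["y_labels"]),
            )
        return dec
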