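"""Gaussian-kernel partial least squares regression (dual form).

Fitting follows the dual NIPALS scheme: latent score vectors are extracted
iteratively from the double-centered kernel matrix with deflation, and the
regression collapses to a dual coefficient vector so that

    prediction = centered_test_kernel @ dual_coef + mean(y_train).

With a linear kernel the procedure reproduces ordinary linear PLS, which
the test suite uses as an oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import Dataset
from .fda import Standardizer


class KPLSError(ValueError):
    pass


def kernel_matrix(A: np.ndarray, B: np.ndarray, sigma_k: float) -> np.ndarray:
    """Gaussian kernel: entry (i, j) = exp(-||a_i - b_j||^2 / (2 sigma_k^2))."""
    if not sigma_k > 0:
        raise KPLSError("sigma_k must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise KPLSError("dimension mismatch between A and B")
    sq = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma_k**2))


def linear_kernel_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Inner-product kernel; the Taylor/limit cross-check against linear PLS."""
    return np.atleast_2d(A) @ np.atleast_2d(B).T


def median_heuristic(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the rows (positive entries only)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sq = (
        (X**2).sum(axis=1)[:, None]
        + (X**2).sum(axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    np.maximum(sq, 0.0, out=sq)
    d = np.sqrt(sq[np.triu_indices_from(sq, k=1)])
    d = d[d > 0]
    if len(d) == 0:
        raise KPLSError("all training points identical; no kernel scale")
    return float(np.median(d))


@dataclass(frozen=True)
class KPLSModel:
    train_inputs: np.ndarray  # standardized predictor rows
    sigma_k: float | None  # None marks a linear kernel
    n_components: int
    dual_coef: np.ndarray
    y_center: float
    standardizer: Standardizer
    K_train_raw: np.ndarray  # uncentered training kernel (needed to center tests)

    def predict_standardized(self, Z_new: np.ndarray) -> np.ndarray:
        """Predict from rows already passed through the model standardizer."""
        Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
        if Z_new.shape[1] != self.train_inputs.shape[1]:
            raise KPLSError("dimension mismatch with training inputs")
        if self.sigma_k is None:
            Kt = linear_kernel_matrix(Z_new, self.train_inputs)
        else:
            Kt = kernel_matrix(Z_new, self.train_inputs, self.sigma_k)
        n = self.K_train_raw.shape[0]
        ones = np.full((1, n), 1.0 / n)
        Kt_c = Kt - Kt @ np.full((n, n), 1.0 / n)
        Kt_c -= ones @ self.K_train_raw - ones @ self.K_train_raw @ np.full((n, n), 1.0 / n)
        return Kt_c @ self.dual_coef + self.y_center


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a training kernel (feature-space mean removal)."""
    n = K.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return H @ K @ H


def _extract_components(
    Kc: np.ndarray, yc: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dual NIPALS: returns score matrix T (n x c) and weight matrix U."""
    n = len(yc)
    K_res = Kc.copy()
    y_res = yc.copy().astype(float)
    T = np.empty((n, 0))
    U = np.empty((n, 0))
    for _ in range(n_components):
        ny = np.linalg.norm(y_res)
        if ny < 1e-12:
            break
        u = y_res / ny
        t = K_res @ u
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t = t / nt
        P = np.eye(n) - np.outer(t, t)
        K_res = P @ K_res @ P
        y_res = y_res - t * (t @ y_res)
        T = np.hstack([T, t[:, None]])
        U = np.hstack([U, u[:, None]])
    return T, U


def fit_kpls(
    K_train: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    train_inputs: np.ndarray | None = None,
    sigma_k: float | None = None,
    standardizer: Standardizer | None = None,
) -> KPLSModel:
    """Fit the dual regressor on an (uncentered) training kernel.

    Centering of the kernel and the response happens internally so that
    training and prediction stay consistent.
    """
    K_train = np.asarray(K_train, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K_train.shape != (n, n):
        raise KPLSError("kernel/response size mismatch")
    if not 1 <= n_components <= n - 1:
        raise KPLSError(f"n_components must lie in [1, {n - 1}]")
    if np.ptp(y) == 0:
        raise KPLSError("zero-variance response")
    y_center = float(y.mean())
    yc = y - y_center
    Kc = center_kernel(K_train)
    T, U = _extract_components(Kc, yc, n_components)
    if T.shape[1] == 0:
        raise KPLSError("no components could be extracted")
    M = T.T @ Kc @ U
    dual_coef = U @ np.linalg.pinv(M) @ (T.T @ yc)
    if train_inputs is None:
        train_inputs = np.empty((n, 0))
    if standardizer is None:
        p = np.atleast_2d(train_inputs).shape[1]
        standardizer = Standardizer(np.zeros(p), np.ones(p))
    return KPLSModel(
        train_inputs=np.atleast_2d(np.asarray(train_inputs, dtype=float)),
        sigma_k=sigma_k,
        n_components=T.shape[1],
        dual_coef=dual_coef,
        y_center=y_center,
        standardizer=standardizer,
        K_train_raw=K_train,
    )


def predict_kpls(m: KPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for raw (unstandardized) predictor rows."""
    Z = m.standardizer(np.atleast_2d(np.asarray(X_new, dtype=float)))
    return m.predict_standardized(Z)


@dataclass(frozen=True)
class Q2Result:
    ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray  # leave-one-out predictions
    q2: float
    hyperparams: dict


def q_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Q2 = 1 - SS_res / SS_tot with the full-sample mean in the denominator."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise KPLSError("zero-variance response")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


_DEFAULT_COMPONENTS = 4
_SIGMA_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)


def _fit_predict_one(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    sigma_mult: float,
    n_components: int,
) -> np.ndarray:
    std = Standardizer.fit(X_tr)
    Z_tr = std(X_tr)
    sigma_k = sigma_mult * median_heuristic(Z_tr)
    K = kernel_matrix(Z_tr, Z_tr, sigma_k)
    c = min(n_components, len(y_tr) - 1)
    m = fit_kpls(
        K, y_tr, c, train_inputs=Z_tr, sigma_k=sigma_k, standardizer=std
    )
    return m.predict_standardized(std(X_te))


def _loo_predictions(
    X: np.ndarray, y: np.ndarray, sigma_mult: float, n_components: int
) -> np.ndarray:
    n = len(y)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[j] = False
        preds[j] = _fit_predict_one(
            X[mask], y[mask], X[j][None, :], sigma_mult, n_components
        )[0]
        mask[j] = True
    return preds


def loo_q2(
    ds: Dataset,
    variables: Iterable[str],
    hyper_policy: str = "fixed",
    *,
    sigma_multipliers: Sequence[float] = _SIGMA_MULTIPLIERS,
    max_components: int = 10,
) -> Q2Result:
    """Leave-one-out cross-validated Q2 over the responding (Vineland) samples.

    ``hyper_policy="fixed"`` uses the median-heuristic kernel width and a
    fixed component count; ``"nested"`` chooses both inside each training
    fold by an inner leave-one-out grid search.
    """
    variables = tuple(variables)
    resp = ds.vineland_subset()
    if len(resp) < 10:
        raise KPLSError("need at least 10 samples with responses")
    X = resp.matrix(variables)
    y = np.array([s.vineland for s in resp.samples], dtype=float)
    ids = tuple(s.id for s in resp.samples)
    n = len(y)

    if hyper_policy == "fixed":
        preds = _loo_predictions(X, y, 1.0, _DEFAULT_COMPONENTS)
        hyper = {"policy": "fixed", "sigma_mult": 1.0, "n_components": _DEFAULT_COMPONENTS}
    elif hyper_policy == "nested":
        comps = range(1, min(max_components, n - 2) + 1)
        grid = list(itertools.product(sigma_multipliers, comps))
        preds = np.empty(n)
        chosen = []
        mask = np.ones(n, dtype=bool)
        for j in range(n):
            mask[j] = False
            X_tr, y_tr = X[mask], y[mask]
            best = None
            for sm, c in grid:
                inner = _loo_predictions(X_tr, y_tr, sm, c)
                q2 = q_squared(y_tr, inner)
                if best is None or q2 > best[0]:
                    best = (q2, sm, c)
            _, sm, c = best
            chosen.append((sm, c))
            preds[j] = _fit_predict_one(X_tr, y_tr, X[j][None, :], sm, c)[0]
            mask[j] = True
        hyper = {"policy": "nested", "per_fold": chosen}
    else:
        raise KPLSError(f"unknown hyper_policy {hyper_policy!r}")

    return Q2Result(
        ids=ids, y_true=y, y_pred=preds, q2=q_squared(y, preds), hyperparams=hyper
    )


def regression_search(
    ds: Dataset,
    k_max: int = 8,
    hyper_policy: str = "fixed",
    *,
    variables: Sequence[str] | None = None,
) -> dict[int, tuple[tuple[str, ...], float]]:
    """Exhaustive per-size search for the best Q2 combination."""
    pool = tuple(variables) if variables is not None else ds.panel.names
    if k_max > len(pool):
        raise KPLSError("k_max exceeds the number of candidate variables")
    order = {v: i for i, v in enumerate(ds.panel.names)}
    best: dict[int, tuple[tuple[str, ...], float]] = {}
    for k in range(1, k_max + 1):
        top: tuple[tuple[str, ...], float] | None = None
        for combo in itertools.combinations(pool, k):
            combo = tuple(sorted(combo, key=order.__getitem__))
            q2 = loo_q2(ds, combo, hyper_policy).q2
            if top is None or q2 > top[1] or (q2 == top[1] and combo < top[0]):
                top = (combo, q2)
        best[k] = top  # type: ignore[assignment]
    return best
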