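"""Mean-centred multi-response PLS (PLS2) via NIPALS.

Fits ``Y ~ X`` by extracting successive latent variables that maximise the
covariance between X scores and Y scores, deflating both matrices after each
component.  Only mean centring is applied (no unit-variance scaling); the
centring vectors are stored so prediction subtracts the training X mean and
adds the training Y mean back.

Components are nested: the first A components of a larger fit are identical
to an A-component fit, so one fit supports prediction at every truncation
level (used heavily by leave-one-out component selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["PLSModel", "fit_pls"]


@dataclass
class PLSModel:
    """Fitted PLS2 model.

    Attributes
    ----------
    x_mean, y_mean
        Training column means of X (length p) and Y (length q).
    weights
        X weight vectors W, shape (p, A), each of unit norm.
    x_loadings, y_loadings
        Loadings P (p, A) and Q (q, A) of the deflation steps.
    scores
        X score vectors T, shape (n, A); mutually orthogonal.
    coef
        Regression coefficients B (p, q) for centred data using all A
        components: ``Y_hat = (X - x_mean) @ coef + y_mean``.
    n_components
        Number of components actually extracted (may be fewer than requested
        if the remaining covariance degenerated to zero).
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    n_components: int
    _coef_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.x_mean.shape[0]

    @property
    def n_targets(self) -> int:
        return self.y_mean.shape[0]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Coefficient matrix B using the first ``n_components`` components."""
        if n_components is None or n_components == self.n_components:
            return self.coef
        a = int(n_components)
        if not 0 <= a <= self.n_components:
            raise ValueError(
                f"n_components must be in 0..{self.n_components}, got {a}"
            )
        if a not in self._coef_cache:
            self._coef_cache[a] = _coef_from_wpq(
                self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:, :a]
            )
        return self._coef_cache[a]

    def predict(self, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict Y for new samples: ``(X_new - x_mean) @ B + y_mean``."""
        X_new = np.asarray(X_new, dtype=float)
        one_row = X_new.ndim == 1
        X_new = np.atleast_2d(X_new)
        if X_new.shape[1] != self.n_features:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects {self.n_features}"
            )
        B = self.coefficients(n_components)
        out = (X_new - self.x_mean) @ B + self.y_mean
        return out[0] if one_row else out

    @property
    def fitted_values(self) -> np.ndarray:
        """Training-set approximation ``T @ Q.T + y_mean``."""
        return self.scores @ self.y_loadings.T + self.y_mean

    # -- persistence (exact round trip) -----------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            weights=self.weights,
            x_loadings=self.x_loadings,
            y_loadings=self.y_loadings,
            scores=self.scores,
            coef=self.coef,
            n_components=np.array(self.n_components),
        )

    @classmethod
    def load(cls, path) -> "PLSModel":
        with np.load(path) as z:
            return cls(
                x_mean=z["x_mean"],
                y_mean=z["y_mean"],
                weights=z["weights"],
                x_loadings=z["x_loadings"],
                y_loadings=z["y_loadings"],
                scores=z["scores"],
                coef=z["coef"],
                n_components=int(z["n_components"]),
            )


def _coef_from_wpq(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    # B = W (P^T W)^-1 Q^T
    return W @ np.linalg.solve(P.T @ W, Q.T)


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    *,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a mean-centred NIPALS PLS2 model.

    Parameters
    ----------
    X, Y
        Training matrices, shapes (n, p) and (n, q); a 1-D Y is treated as a
        single column.  No missing values allowed.
    n_components
        Requested number of latent variables; must not exceed min(n-1, p).
        If the residual covariance degenerates earlier, the model stops with
        fewer components and logs a notice.
    tol, max_iter
        Inner-loop convergence tolerance on the change of the weight vector,
        and the iteration cap per component.

    Notes
    -----
    Each component's sign is fixed so the largest-magnitude entry of its
    weight vector is positive, making repeated fits bit-identical.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("X and Y must be finite (impute missing values first)")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(
            f"n_components must be in 1..min(n-1, p)={a_max}, got {n_components}"
        )
    q = Y.shape[1]

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xr = X - x_mean
    Yr = Y - y_mean
    x_ss0 = float((Xr**2).sum()) or 1.0
    y_ss0 = float((Yr**2).sum()) or 1.0

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty((q, n_components))
    T = np.empty((n, n_components))

    a = 0
    for a in range(n_components):
        # residual energy exhausted -> nothing left to model
        if (Xr**2).sum() <= 1e-24 * x_ss0 or (Yr**2).sum() <= 1e-24 * y_ss0:
            log.info("stopping at %d components: residual covariance exhausted", a)
            break
        u = Yr[:, int(np.argmax((Yr**2).sum(axis=0)))]
        w_old = None
        degenerate = False
        for _ in range(max_iter):
            w = Xr.T @ u
            wn = np.linalg.norm(w)
            if wn <= 1e-150:
                degenerate = True
                break
            w = w / wn
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 1e-24 * x_ss0:
                degenerate = True
                break
            qv = (Yr.T @ t) / tt
            qq = float(qv @ qv)
            if qq <= 1e-150:
                degenerate = True
                break
            u = (Yr @ qv) / qq
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        if degenerate:
            log.info("stopping at %d components: degenerate direction", a)
            break
        # sign convention: largest-|w| entry positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
            t = -t
            qv = -qv
        tt = float(t @ t)
        pv = (Xr.T @ t) / tt
        Xr = Xr - np.outer(t, pv)
        Yr = Yr - np.outer(t, qv)
        W[:, a] = w
        P[:, a] = pv
        Q[:, a] = qv
        T[:, a] = t
        a += 1

    W, P, Q, T = W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
    coef = _coef_from_wpq(W, P, Q)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coef=coef,
        n_components=a,
    )
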