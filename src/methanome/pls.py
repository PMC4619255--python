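"""Partial least squares regression (univariate response) with VIP scores.

A NIPALS PLS1 implementation operating on predictors and response centred
and scaled to mean 0, SD 1 (the reporting convention used throughout the
package: estimates are on the standardized scale, with back-transformed
coefficients provided secondarily).  The number of latent factors defaults
to the minimiser of the leave-one-out PRESS and can be fixed explicitly.

The Variable Importance for Projection (VIP) statistic summarises each
predictor's contribution to the fitted factors:

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a ),

with SSY_a = q_a^2 (t_a . t_a) the response variance captured by factor a
and w_a the (unit-norm) weight vectors.  The mean of VIP^2 over predictors
is identically 1, so predictors below the conventional 0.8 cutoff
contribute little and are pruned in the selection pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "VIPResult", "pls_fit", "vip", "loo_press"]

_EPS = 1e-12


@dataclass
class PLSModel:
    predictor_names: list[str]
    n_factors: int
    weights: np.ndarray        # p x A, unit-norm columns
    scores: np.ndarray         # n x A, mutually orthogonal
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # A,
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    x_variance_explained: float
    y_variance_explained: float
    press_by_factors: dict[int, float] = field(default_factory=dict)

    @property
    def coef_scaled(self) -> np.ndarray:
        """Regression coefficients on the centred/scaled scale."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    @property
    def coef_original(self) -> np.ndarray:
        """Coefficients mapping raw predictors to raw response."""
        return self.y_std * self.coef_scaled / self.x_std

    @property
    def intercept_original(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef_original)

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_original + self.intercept_original


@dataclass
class VIPResult:
    vip: pd.Series                 # predictor -> VIP score
    retained: pd.Series            # predictor -> VIP >= cutoff
    cutoff: float

    @property
    def retained_predictors(self) -> list[str]:
        return list(self.vip.index[self.retained])


def _standardize(X: np.ndarray, names: Sequence[str]):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    dead = np.where(std < _EPS)[0]
    if dead.size:
        raise ValueError(f"zero-variance predictor column(s): {[names[i] for i in dead]}")
    return (X - mean) / std, mean, std


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """Deflating PLS1; returns W, T, P, q (columns per factor)."""
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    X, y = Xc.copy(), yc.copy()
    for a in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise np.linalg.LinAlgError(
                f"NIPALS exhausted: no covariance left at factor {a + 1}"
            )
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            raise np.linalg.LinAlgError(f"degenerate score vector at factor {a + 1}")
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    return W, T, P, q


def pls_fit(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_factors: int | str = "auto",
    max_factors: int | None = None,
) -> PLSModel:
    """Fit standardized PLS1.

    ``n_factors="auto"`` picks the factor count minimising the leave-one-out
    PRESS (over 1..min(rank, max_factors)); an integer fixes it.  Raises for
    zero-variance columns (named) and for n_factors beyond rank(X).
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(pd.Series(y).to_numpy(), dtype=float).ravel()
    n, p = Xa.shape
    if n != ya.size:
        raise ValueError("X and y have different numbers of rows")
    if n < 3:
        raise ValueError("need at least 3 observations")

    Xc, x_mean, x_std = _standardize(Xa, names)
    y_mean, y_std = float(ya.mean()), float(ya.std(ddof=1))
    if y_std < _EPS:
        raise ValueError("response has zero variance")
    yc = (ya - y_mean) / y_std

    rank = int(np.linalg.matrix_rank(Xc))
    press_by_factors: dict[int, float] = {}
    if n_factors == "auto":
        a_cap = min(rank, n - 2, max_factors or rank)
        if a_cap < 1:
            raise ValueError("not enough data to fit any factor")
        for a in range(1, a_cap + 1):
            press_by_factors[a] = loo_press(Xa, ya, a)
        A = min(press_by_factors, key=lambda a: (press_by_factors[a], a))
    else:
        A = int(n_factors)
        if A < 1:
            raise ValueError("n_factors must be >= 1")
        if A > rank:
            raise ValueError(f"n_factors={A} exceeds rank(X)={rank}")

    W, T, P, q = _nipals(Xc, yc, A)
    ss_x = float((Xc ** 2).sum())
    ss_y = float((yc ** 2).sum())
    tt = (T ** 2).sum(axis=0)
    x_var = float((tt * (P ** 2).sum(axis=0)).sum() / ss_x)
    y_var = float((q ** 2 * tt).sum() / ss_y)
    return PLSModel(
        predictor_names=names,
        n_factors=A,
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        x_variance_explained=x_var,
        y_variance_explained=y_var,
        press_by_factors=press_by_factors,
    )


def loo_press(X: np.ndarray, y: np.ndarray, n_factors: int) -> float:
    """Leave-one-out predicted residual sum of squares at a fixed factor count."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, ytr = X[mask], y[mask]
        mean = Xtr.mean(axis=0)
        std = Xtr.std(axis=0, ddof=1)
        keep = std > _EPS  # a column can go flat in a LOO fold; drop it there
        Xc = (Xtr[:, keep] - mean[keep]) / std[keep]
        ym, ys = ytr.mean(), ytr.std(ddof=1)
        if ys < _EPS:
            press += (y[i] - ym) ** 2
            continue
        yc = (ytr - ym) / ys
        a = min(n_factors, int(np.linalg.matrix_rank(Xc)))
        try:
            W, T, P, q = _nipals(Xc, yc, a)
        except np.linalg.LinAlgError:
            press += (y[i] - ym) ** 2
            continue
        beta = W @ np.linalg.solve(P.T @ W, q)
        xi = (X[i, keep] - mean[keep]) / std[keep]
        press += (y[i] - (ym + ys * (xi @ beta))) ** 2
    return float(press)


def vip(model: PLSModel, cutoff: float = 0.8) -> VIPResult:
    """Per-predictor VIP with the conventional retention cutoff (default 0.8)."""
    W, T, q = model.weights, model.scores, model.y_loadings
    tt = (T ** 2).sum(axis=0)
    ssy = q ** 2 * tt
    total = ssy.sum()
    if total < _EPS:
        raise ValueError("zero explained response variance; VIP undefined")
    p = W.shape[0]
    scores = np.sqrt(p * (W ** 2 @ ssy) / total)
    series = pd.Series(scores, index=model.predictor_names, name="vip")
    return VIPResult(vip=series, retained=series >= cutoff, cutoff=cutoff)
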