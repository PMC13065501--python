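"""One-hidden-layer neural network backend for the measurement-error model.

The network maps (t, X2) -> P(Tobs = 1 | T = t, X2) through a ReLU hidden
layer and a sigmoid output. Training minimizes the weighted binary
cross-entropy plus an L2 weight penalty ("decay") with L-BFGS on the full
batch; the parameter count is tiny (a few dozen), so quasi-Newton training
is both fast and deterministic given the initialization seed.

Hyperparameters (hidden units 1-3, decay over a small grid) are selected by
k-fold cross-validation on the weighted rows, minimizing held-out weighted
cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .models import MEParams, NNConfig

__all__ = ["MLP", "tune_nn", "fit_weighted_me_nn"]

_EPS = 1e-10


@dataclass
class MLP:
    """A fitted one-hidden-layer network with input standardization."""

    W1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    n_hidden: int
    decay: float

    def flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2, [self.b2]])

    def _features(self, t: np.ndarray, X2: np.ndarray) -> np.ndarray:
        Xs = (X2 - self.x_mean) / self.x_sd
        return np.column_stack([np.asarray(t, dtype=float), Xs])

    def predict(self, t: np.ndarray, X2: np.ndarray) -> np.ndarray:
        Z = self._features(t, X2)
        H = np.maximum(Z @ self.W1 + self.b1, 0.0)
        return expit(H @ self.W2 + self.b2)


def _unpack(theta: np.ndarray, d: int, h: int):
    W1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    W2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return W1, b1, W2, b2


def _loss_grad(theta, Z, y, w, d, h, decay):
    W1, b1, W2, b2 = _unpack(theta, d, h)
    pre = Z @ W1 + b1
    H = np.maximum(pre, 0.0)
    logits = H @ W2 + b2
    p = expit(logits)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    wsum = w.sum()
    loss = -(w * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))).sum() / wsum
    loss += decay * ((W1**2).sum() + (W2**2).sum())

    dlogit = (p - y) * w / wsum
    gW2 = H.T @ dlogit + 2.0 * decay * W2
    gb2 = dlogit.sum()
    dH = np.outer(dlogit, W2) * (pre > 0)
    gW1 = Z.T @ dH + 2.0 * decay * W1
    gb1 = dH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
    return loss, grad


def _init_params(d: int, h: int, y_mean: float, rng: np.random.Generator) -> np.ndarray:
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
    b1 = np.full(h, 0.1)  # bias units into the active ReLU region
    W2 = rng.normal(0.0, np.sqrt(1.0 / h), size=h)
    b2 = float(np.log(y_mean / (1.0 - y_mean))) if 0 < y_mean < 1 else 0.0
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _standardizer(X2: np.ndarray, w: np.ndarray):
    """Weighted feature moments, so zero-weight rows have no influence."""
    ws = w / w.sum()
    m = ws @ X2
    s = np.sqrt(ws @ (X2 - m) ** 2)
    s[s < 1e-12] = 1.0
    return m, s


def _train(
    Tobs, T, X2, w, n_hidden, decay, seed, maxiter,
    warm: Optional[MLP] = None,
) -> MLP:
    y = np.asarray(Tobs, dtype=float)
    w = np.asarray(w, dtype=float)
    if warm is not None:
        x_mean, x_sd = warm.x_mean, warm.x_sd
    else:
        x_mean, x_sd = _standardizer(X2, w)
    Z = np.column_stack([np.asarray(T, dtype=float), (X2 - x_mean) / x_sd])
    d = Z.shape[1]
    if warm is not None and warm.n_hidden == n_hidden:
        theta0 = warm.flat()
    else:
        rng = np.random.default_rng(seed)
        ybar = float((w * y).sum() / w.sum())
        theta0 = _init_params(d, n_hidden, ybar, rng)
    res = minimize(
        _loss_grad,
        theta0,
        args=(Z, y, w, d, n_hidden, decay),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    W1, b1, W2, b2 = _unpack(res.x, d, n_hidden)
    return MLP(
        W1=W1, b1=b1, W2=W2, b2=float(b2),
        x_mean=x_mean, x_sd=x_sd, n_hidden=n_hidden, decay=decay,
    )


def _cv_loss(mlp: MLP, Tobs, T, X2, w) -> float:
    p = np.clip(mlp.predict(T, X2), _EPS, 1.0 - _EPS)
    y = np.asarray(Tobs, dtype=float)
    return float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / w.sum())


def tune_nn(Tobs, T, X2, weights, config: NNConfig) -> tuple[int, float]:
    """Grid-search (n_hidden, decay) by k-fold cross-validation.

    Folds are assigned by a seeded shuffle of the rows; the selected grid
    point minimizes mean held-out weighted cross-entropy. Deterministic
    given ``config.seed``. A single-point grid short-circuits the CV.
    """
    grid = [(h, dec) for h in config.hidden_grid for dec in config.decay_grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    n = len(Tobs)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, config.cv_folds)
    w = np.asarray(weights, dtype=float)
    best, best_loss = grid[0], np.inf
    for h, dec in grid:
        losses = []
        for k in range(config.cv_folds):
            val = folds[k]
            trn = np.concatenate([folds[j] for j in range(config.cv_folds) if j != k])
            if w[val].sum() <= 0 or w[trn].sum() <= 0:
                continue
            mlp = _train(
                Tobs[trn], T[trn], X2[trn], w[trn], h, dec,
                seed=config.seed + 13 * k, maxiter=config.maxiter_cv,
            )
            losses.append(_cv_loss(mlp, Tobs[val], T[val], X2[val], w[val]))
        mean_loss = float(np.mean(losses)) if losses else np.inf
        if mean_loss < best_loss - 1e-12:
            best, best_loss = (h, dec), mean_loss
    return best


def fit_weighted_me_nn(
    Tobs, T, X2, weights,
    config: NNConfig,
    hyper: Optional[tuple[int, float]] = None,
    warm_start: Optional[MEParams] = None,
) -> MEParams:
    """Fit (or warm-start refit) the network measurement-error model by
    weighted cross-entropy minimization."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    warm = None
    if warm_start is not None and warm_start.backend == "nn":
        warm = warm_start.nn
    if hyper is None:
        if warm is not None:
            hyper = (warm.n_hidden, warm.decay)
        else:
            hyper = tune_nn(np.asarray(Tobs), np.asarray(T), X2, w, config)
    n_hidden, decay = hyper
    maxiter = config.maxiter_warm if warm is not None else config.maxiter_init
    mlp = _train(
        np.asarray(Tobs), np.asarray(T), X2, w, n_hidden, decay,
        seed=config.seed, maxiter=maxiter, warm=warm,
    )
    return MEParams(backend="nn", nn=mlp)
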