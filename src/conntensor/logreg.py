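"""L1-penalized binary logistic regression via accelerated proximal gradient.

The model is P(y | x) = 1 / (1 + exp(-y (x'w + c))) with y in {-1, +1}; the
fitted objective is the average logistic loss plus a Lasso penalty on the
coefficients (the intercept c is unpenalized):

    min_{w, c}  (1/n) sum_i log(1 + exp(-y_i (x_i'w + c)))  +  lambda ||w||_1

The solver is FISTA (accelerated proximal gradient) with soft-thresholding
and backtracking line search, monitored so the objective is non-increasing
(a monotone restart is applied if an accelerated step would overshoot).
At convergence the KKT conditions hold: |grad_j L| <= lambda wherever
w_j = 0 and grad_j L = -lambda * sign(w_j) elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + exp(z)) without overflow
    return np.logaddexp(0.0, z)


@dataclass
class SparseLogRegModel:
    """Fitted sparse logistic model: coefficients w, intercept c, penalty lambda."""

    w: np.ndarray
    c: float
    lam: float
    objective: float
    n_iter: int = 0
    converged: bool = True
    #: penalized objective after each iteration; non-increasing by construction
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.w))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.size:
            raise ValueError(f"{X.shape[1]} features but model has {self.w.size}")
        return X @ self.w + self.c

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class (+1) for each row of X."""
        return _sigmoid(self.decision_function(X))

    def to_dict(self) -> dict:
        nz = np.nonzero(self.w)[0]
        return {
            "indices": nz.tolist(),
            "values": self.w[nz].tolist(),
            "m": int(self.w.size),
            "intercept": float(self.c),
            "lambda": float(self.lam),
            "objective": float(self.objective),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparseLogRegModel":
        w = np.zeros(d["m"])
        w[np.asarray(d["indices"], dtype=int)] = d["values"]
        return cls(w, d["intercept"], d["lambda"], d["objective"])


def predict_proba(model: SparseLogRegModel, x: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`SparseLogRegModel.predict_proba`."""
    return model.predict_proba(x)


def logistic_loss(w: np.ndarray, c: float, X: np.ndarray, y: np.ndarray) -> float:
    """Average logistic loss (1/n) sum log(1 + exp(-y (x'w + c)))."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    margins = y * (X @ np.asarray(w, dtype=float) + c)
    return float(np.mean(_softplus(-margins)))


def _loss_and_grad(w, c, X, y):
    n = X.shape[0]
    margins = y * (X @ w + c)
    loss = float(np.mean(_softplus(-margins)))
    # d/dz log(1+e^{-z}) = -sigmoid(-z)
    coef = -y * _sigmoid(-margins) / n
    return loss, X.T @ coef, float(np.sum(coef))


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _check_two_classes(y: np.ndarray) -> None:
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both classes (+1 and -1) must be present")


def optimal_intercept(y: np.ndarray) -> float:
    """Intercept of the intercept-only model: log(n_pos / n_neg)."""
    _check_two_classes(y)
    n_pos = int(np.sum(y > 0))
    n_neg = y.size - n_pos
    return float(np.log(n_pos / n_neg))


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda for which the penalized solution is exactly w = 0.

    By the KKT conditions at the intercept-only optimum c* = log(n+/n-),
    w = 0 is optimal iff every coordinate of the loss gradient satisfies
    |(1/n) sum_i y_i x_ij sigma(-y_i c*)| <= lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    c_star = optimal_intercept(y)
    _, grad_w, _ = _loss_and_grad(np.zeros(X.shape[1]), c_star, X, y)
    return float(np.max(np.abs(grad_w)))


def lambda_path(X: np.ndarray, y: np.ndarray, n_values: int = 20) -> np.ndarray:
    """Log-spaced descending grid from lambda_max down to 1e-3 * lambda_max."""
    if n_values < 2:
        raise ValueError("n_values must be >= 2")
    top = lambda_max(X, y)
    return np.geomspace(top, 1e-3 * top, n_values)


def fit_sparse_logreg(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 5000,
    w0: np.ndarray | None = None,
    c0: float | None = None,
    kkt_tol: float | None = None,
) -> SparseLogRegModel:
    """Fit by FISTA with backtracking; intercept unpenalized.

    Convergence: relative change of the penalized objective below ``tol``;
    if ``kkt_tol`` is given, the stationarity violation must additionally
    fall below it (useful when the objective is flat near the optimum and
    coefficient-level agreement matters).  ``w0``/``c0`` allow warm starts
    along a regularization path.  If the iteration budget is exhausted the
    best iterate is returned with ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    _check_two_classes(y)

    m = X.shape[1]
    w = np.zeros(m) if w0 is None else np.asarray(w0, dtype=float).copy()
    c = optimal_intercept(y) if c0 is None else float(c0)

    def objective(wv, cv):
        return logistic_loss(wv, cv, X, y) + lam * float(np.sum(np.abs(wv)))

    # Lipschitz upper bound for the logistic Hessian: ||[X 1]||^2 / (4n)
    aug_norm2 = float(np.linalg.norm(np.column_stack([X, np.ones(X.shape[0])]), 2) ** 2)
    step = 4.0 * X.shape[0] / max(aug_norm2, 1e-12)

    zw, zc = w.copy(), c  # accelerated (momentum) point
    t_momentum = 1.0
    obj_prev = objective(w, c)
    history = [obj_prev]
    n_iter = 0
    converged = False

    for n_iter in range(1, max_iter + 1):
        loss_z, grad_w, grad_c = _loss_and_grad(zw, zc, X, y)
        # backtracking on the smooth part around the momentum point
        s = step
        for _ in range(50):
            w_new = _soft_threshold(zw - s * grad_w, s * lam)
            c_new = zc - s * grad_c
            dw, dc = w_new - zw, c_new - zc
            quad = loss_z + grad_w @ dw + grad_c * dc + (dw @ dw + dc * dc) / (2 * s)
            if logistic_loss(w_new, c_new, X, y) <= quad + 1e-12:
                break
            s *= 0.5
        obj_new = objective(w_new, c_new)
        if obj_new > obj_prev:  # monotone restart: fall back to plain proximal step
            loss_w, grad_w, grad_c = _loss_and_grad(w, c, X, y)
            s = step
            for _ in range(50):
                w_new = _soft_threshold(w - s * grad_w, s * lam)
                c_new = c - s * grad_c
                dw, dc = w_new - w, c_new - c
                quad = loss_w + grad_w @ dw + grad_c * dc + (dw @ dw + dc * dc) / (2 * s)
                if logistic_loss(w_new, c_new, X, y) <= quad + 1e-12:
                    break
                s *= 0.5
            obj_new = objective(w_new, c_new)
            t_momentum = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2))
        zw = w_new + ((t_momentum - 1.0) / t_next) * (w_new - w)
        zc = c_new + ((t_momentum - 1.0) / t_next) * (c_new - c)
        w, c = w_new, c_new
        t_momentum = t_next
        history.append(obj_new)
        if abs(obj_prev - obj_new) <= tol * max(abs(obj_prev), 1.0):
            obj_prev = obj_new
            if kkt_tol is not None:
                probe = SparseLogRegModel(w, float(c), float(lam), obj_new)
                if kkt_violation(probe, X, y) > kkt_tol:
                    continue
            converged = True
            break
        obj_prev = obj_new

    if not converged:
        warnings.warn(f"sparse logistic fit did not converge in {max_iter} iterations")
    return SparseLogRegModel(w, float(c), float(lam), obj_prev, n_iter, converged, history)


def kkt_violation(model: SparseLogRegModel, X: np.ndarray, y: np.ndarray) -> float:
    """Largest violation of the stationarity conditions (0 at an exact optimum)."""
    _, grad_w, grad_c = _loss_and_grad(model.w, model.c, np.asarray(X, float), np.asarray(y, float))
    viol = np.abs(grad_c)
    zero = model.w == 0
    if np.any(zero):
        viol = max(viol, float(np.max(np.maximum(np.abs(grad_w[zero]) - model.lam, 0.0))))
    if np.any(~zero):
        viol = max(viol, float(np.max(np.abs(grad_w[~zero] + model.lam * np.sign(model.w[~zero])))))
    return float(viol)
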