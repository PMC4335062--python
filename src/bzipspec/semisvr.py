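"""Semi-quantitative support vector regression for censored affinities.

The model is linear and additive: the predicted stability of a dimer is
``E = sum_i w_i x_i`` on the log10(Kd/nM) scale, where ``x`` counts interface
pair/triplet features.  Training minimizes

    |w|^2 + C1 * sum_k xi1_k + C2 * sum_k xi2_k

subject to two-sided epsilon-insensitive constraints for measured binders,
``|E_k - y_k| <= eps + xi1_k``, and one-sided constraints for right-censored
non-binders, ``E_k >= E_cutoff - xi2_k``, with all slacks nonnegative.  A
non-binder therefore only pushes its score above the censoring floor; it
carries no target value.

The solver works on the dual: with one multiplier per record (theta in
[-C1, C1] for binders, [0, C2] for non-binders and ``w = X' theta / 2``),
the dual objective

    g(theta) = -theta' X X' theta / 4 + sum_b (theta y - eps |theta|)
               + sum_nb theta * E_cutoff

is maximized by exact coordinate updates (a soft-threshold per binder
coordinate, a clipped Newton step per non-binder).  Iteration stops when the
primal-dual gap certifies the objective to ``tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .features import FeatureKey, FeatureVector

DEFAULT_E_CUTOFF = math.log10(5000.0)

# hyperparameter grids bracketing the interpolation and strong-regularization
# regimes (the selection itself is data-driven, via inner cross-validation)
DEFAULT_C_GRID = tuple(10.0**k for k in range(-2, 4))
DEFAULT_EPS_GRID = (0.0, 0.1, 0.2, 0.4)


def _as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr().astype(float)
    return sp.csr_matrix(np.asarray(X, dtype=float))


class SemiSVR:
    """Scikit-learn style estimator for the censored linear SVR.

    Parameters
    ----------
    C1, C2 : float
        Slack penalties for binders and censored non-binders.
    epsilon : float
        Half-width of the insensitive tube around binder targets.
    e_cutoff : float
        Score floor for non-binders, log10 nM units (default log10(5000)).
    tol : float
        Relative duality-gap stopping tolerance.
    max_iter : int
        Maximum coordinate-descent epochs.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray (n_features,)
    intercept_ : float (always 0; the score is a pure feature sum)
    objective_ : float, certified primal objective value
    dual_gap_ : float
    n_iter_ : int
    """

    def __init__(
        self,
        C1: float = 1.0,
        C2: float = 1.0,
        epsilon: float = 0.1,
        e_cutoff: float = DEFAULT_E_CUTOFF,
        tol: float = 1e-9,
        max_iter: int = 50_000,
        random_state: int = 0,
    ):
        self.C1 = C1
        self.C2 = C2
        self.epsilon = epsilon
        self.e_cutoff = e_cutoff
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- sklearn protocol ------------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "C1": self.C1,
            "C2": self.C2,
            "epsilon": self.epsilon,
            "e_cutoff": self.e_cutoff,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SemiSVR":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _primal(self, Xw, y, censored) -> float:
        b = ~censored
        loss_b = np.maximum(0.0, np.abs(Xw[b] - y[b]) - self.epsilon)
        loss_n = np.maximum(0.0, self.e_cutoff - Xw[censored])
        return float(
            self._w2 + self.C1 * loss_b.sum() + self.C2 * loss_n.sum()
        )

    def fit(self, X, y, censored=None) -> "SemiSVR":
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        X = _as_csr(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if censored is None:
            censored = np.zeros(n, dtype=bool)
        censored = np.asarray(censored, dtype=bool)
        if y.shape != (n,) or censored.shape != (n,):
            raise ValueError("X, y and censored have inconsistent shapes")
        if not (~censored).any():
            raise ValueError("need at least one (uncensored) binder to fit")

        Kdiag = np.asarray(X.multiply(X).sum(axis=1)).ravel()
        theta = np.zeros(n)
        w = np.zeros(p)
        indptr, indices, values = X.indptr, X.indices, X.data
        rng = np.random.default_rng(self.random_state)

        def dual_value() -> float:
            # w = X'theta/2 is maintained, so theta'K theta/4 = w.w
            lin = 0.0
            for k in range(n):
                if censored[k]:
                    lin += theta[k] * self.e_cutoff
                else:
                    lin += theta[k] * y[k] - self.epsilon * abs(theta[k])
            return -float(w @ w) + lin

        gap = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            order = rng.permutation(n)
            max_delta = 0.0
            for k in order:
                lo, hi = indptr[k], indptr[k + 1]
                cols = indices[lo:hi]
                vals = values[lo:hi]
                kk = Kdiag[k]
                if kk == 0.0:
                    # empty feature row: multiplier maximizes its linear term
                    if censored[k]:
                        theta[k] = self.C2 if self.e_cutoff > 0 else 0.0
                    else:
                        theta[k] = (
                            math.copysign(self.C1, y[k]) if abs(y[k]) > self.epsilon else 0.0
                        )
                    continue
                xw = float(vals @ w[cols])
                r = xw - 0.5 * kk * theta[k]
                if censored[k]:
                    t = min(max(2.0 * (self.e_cutoff - r) / kk, 0.0), self.C2)
                else:
                    delta = y[k] - r
                    soft = math.copysign(max(abs(delta) - self.epsilon, 0.0), delta)
                    t = min(max(2.0 * soft / kk, -self.C1), self.C1)
                d = t - theta[k]
                if d != 0.0:
                    theta[k] = t
                    w[cols] += 0.5 * d * vals
                    max_delta = max(max_delta, abs(d))
            if it % 10 == 0 or max_delta == 0.0:
                self._w2 = float(w @ w)
                primal = self._primal(X @ w, y, censored)
                gap = primal - dual_value()
                # a fixed point of the exact coordinate updates is optimal,
                # so stop there even if roundoff leaves a tiny gap estimate
                if gap <= self.tol * max(1.0, abs(primal)) or max_delta == 0.0:
                    break

        self._w2 = float(w @ w)
        self.coef_ = w
        self.intercept_ = 0.0
        self.objective_ = self._primal(X @ w, y, censored)
        self.dual_gap_ = float(self.objective_ - dual_value())
        self.n_iter_ = it
        if not np.isfinite(self.objective_) or (
            self.dual_gap_ > 0.05 * max(1.0, abs(self.objective_))
        ):
            raise RuntimeError(
                f"SemiSVR did not converge: objective {self.objective_:.6g}, "
                f"duality gap {self.dual_gap_:.3g} after {it} epochs "
                f"(n={n}, p={p}, C1={self.C1}, C2={self.C2}); raise max_iter"
            )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("SemiSVR is not fitted")
        return _as_csr(X) @ self.coef_ + self.intercept_

    def score(self, X, y) -> float:
        """Pearson correlation between predictions and y (field metric)."""
        from scipy.stats import pearsonr

        return float(pearsonr(self.predict(X), np.asarray(y, dtype=float))[0])


# -- keyed weight model --------------------------------------------------------


@dataclass
class WeightModel:
    """Learned weights keyed by feature, plus the training hyperparameters."""

    w: dict[FeatureKey, float]
    C1: float = 1.0
    C2: float = 1.0
    epsilon: float = 0.1
    E_cutoff: float = DEFAULT_E_CUTOFF
    intercept: float = 0.0

    def predict(self, fv: FeatureVector) -> float:
        """Predicted log10(Kd/nM); lower = tighter binding."""
        return self.intercept + sum(self.w.get(k, 0.0) * x for k, x in fv.items())


def predict(model: WeightModel, fv: FeatureVector) -> float:
    return model.predict(fv)


def train_weight_model(featurizer, X, y, censored, **params) -> WeightModel:
    """Fit a SemiSVR on an encoded matrix and key the weights by feature."""
    est = SemiSVR(**params).fit(X, y, censored)
    w = {
        key: float(c)
        for key, c in zip(featurizer.feature_keys_, est.coef_)
        if c != 0.0
    }
    return WeightModel(
        w=w,
        C1=est.C1,
        C2=est.C2,
        epsilon=est.epsilon,
        E_cutoff=est.e_cutoff,
        intercept=est.intercept_,
    )


# -- recursive feature elimination --------------------------------------------


def rfe(
    X_train,
    y_train,
    censored_train,
    X_val,
    y_val,
    binder_val,
    C1: float,
    C2: float,
    epsilon: float,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    step_fraction: float = 0.05,
) -> tuple[np.ndarray, list[dict]]:
    """Iteratively drop the lowest-|weight| features and track validation R.

    Each round ranks active features by |w|, removes ceil(step_fraction *
    n_active) of the weakest, and refits, until no features remain.  Returns
    the active-feature index set with the best validation Pearson R on
    binders, and the full curve.
    """
    from scipy.stats import pearsonr

    X_train = _as_csr(X_train)
    X_val = _as_csr(X_val)
    binder_val = np.asarray(binder_val, dtype=bool)
    active = np.arange(X_train.shape[1])
    curve: list[dict] = []
    best_active, best_r = active.copy(), -np.inf
    while active.size:
        est = SemiSVR(C1=C1, C2=C2, epsilon=epsilon, e_cutoff=e_cutoff).fit(
            X_train[:, active], y_train, censored_train
        )
        pred = est.predict(X_val[:, active])
        if binder_val.sum() >= 3 and np.std(pred[binder_val]) > 0:
            r = float(pearsonr(pred[binder_val], np.asarray(y_val)[binder_val])[0])
        else:
            r = float("nan")
        curve.append({"n_features": int(active.size), "r": r, "active": active.copy()})
        if not math.isnan(r) and r > best_r:
            best_r, best_active = r, active.copy()
        n_drop = math.ceil(step_fraction * active.size)
        rank = np.argsort(np.abs(est.coef_), kind="stable")
        active = np.delete(active, rank[:n_drop])
    return best_active, curve


# -- hyperparameter grid search -------------------------------------------------


def grid_search(
    X,
    y,
    censored,
    kd_nM,
    folds: list[np.ndarray],
    C1_grid=DEFAULT_C_GRID,
    C2_grid=DEFAULT_C_GRID,
    eps_grid=DEFAULT_EPS_GRID,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    ceiling: float = 5000.0,
) -> tuple[float, float, float]:
    """Exhaustive grid evaluation by cross-validation over given folds.

    Selection key: pooled Pearson R on binders, ties broken by AUC (strong
    vs weak/non), then by smaller C1 + C2.  Returns (C1, C2, epsilon).
    """
    from .validation import metrics

    X = _as_csr(X)
    y = np.asarray(y, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    kd_nM = np.asarray(kd_nM, dtype=float)
    n = X.shape[0]
    best = None
    for C1 in C1_grid:
        for C2 in C2_grid:
            for eps in eps_grid:
                pred = np.full(n, np.nan)
                ok = True
                for test_idx in folds:
                    train_mask = np.ones(n, dtype=bool)
                    train_mask[test_idx] = False
                    if not (~censored[train_mask]).any():
                        ok = False
                        break
                    est = SemiSVR(C1=C1, C2=C2, epsilon=eps, e_cutoff=e_cutoff).fit(
                        X[train_mask], y[train_mask], censored[train_mask]
                    )
                    pred[test_idx] = est.predict(X[test_idx])
                if not ok:
                    continue
                r, auc = metrics(pred, y, kd_nM, ceiling=ceiling)
                score = (
                    -1.0 if (r is None or math.isnan(r)) else r,
                    -1.0 if (auc is None or math.isnan(auc)) else auc,
                    -(C1 + C2),
                )
                if best is None or score > best[0]:
                    best = (score, (C1, C2, eps))
    if best is None:
        raise RuntimeError("grid search found no feasible hyperparameter point")
    return best[1]
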