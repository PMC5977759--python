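"""Fitting the accelerated failure time (AFT) regression on complete data.

The AFT model is  log(y) = X beta + eps  with independent errors; on
complete (or imputed-complete) data it is a linear regression of log
survival time.  Because p >> n, four dimension-reduction fits are provided:

* PLS   -- v orthogonal latent factors from X and log y, then OLS on the
  factors (v tuned over 1..10 by 10-fold CV);
* SPLS  -- sparse PLS: soft-thresholded direction vectors with shrinkage
  eta in (0,1); eta = 0 recovers PLS exactly;
* lasso / elastic net -- minimisers of
  1/2 ||y - X b||^2 + lambda [ (1-alpha)/2 ||b||^2 + alpha ||b||_1 ],
  alpha = 1 being the lasso (solved by scikit-learn coordinate descent);
* OLS   -- unpenalised least squares, used for the low-dimensional
  clinical-covariates-only model.

All fitters centre log y internally and report coefficients on the scale of
the covariates they were given (which the pipeline standardises first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

__all__ = [
    "AFTModelFit",
    "CVPlan",
    "fit_ols",
    "fit_pls",
    "fit_spls",
    "fit_enet",
    "fit_lasso",
    "predict_time",
    "linear_predictor",
    "cross_validate",
    "cv_enet",
    "lambda_grid",
    "CVFitter",
]


@dataclass
class AFTModelFit:
    """A fitted AFT regression: log yhat = intercept + X_std beta.

    ``scaling`` holds the training (means, sds) when the fit owns its
    standardisation; ``None`` means the caller passes already-standardised
    covariates to :func:`predict_time`.
    """

    method: str
    beta: np.ndarray
    intercept: float
    feature_ids: list[str] | None = None
    tuning: dict = field(default_factory=dict)
    scaling: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict:
        nz = np.nonzero(self.beta)[0]
        return {
            "method": self.method,
            "intercept": self.intercept,
            "tuning": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in self.tuning.items()},
            "beta_index": nz.tolist(),
            "beta_value": self.beta[nz].tolist(),
            "p": int(self.beta.size),
            "feature_ids": self.feature_ids,
        }


@dataclass
class CVPlan:
    """Fold bookkeeping for 10-fold cross-validation over a tuning grid."""

    n_folds: int = 10
    seed: int = 0

    def folds(self, n: int) -> list[np.ndarray]:
        if n < self.n_folds:
            raise ValueError(f"n={n} smaller than n_folds={self.n_folds}")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        out = [np.sort(f) for f in np.array_split(perm, self.n_folds)]
        if min(len(f) for f in out) < 2:
            raise ValueError("a CV fold has fewer than 2 observations")
        return out


def _check_xy(X, logy):
    X = np.asarray(X, dtype=float)
    y = np.asarray(logy, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and logy length n")
    return X, y


def fit_ols(X, logy) -> AFTModelFit:
    """Least squares of log time on the covariates (low-dimensional only)."""
    X, y = _check_xy(X, logy)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    return AFTModelFit("OLS_CLINICAL", beta, intercept)


def _pls1(Xc: np.ndarray, yc: np.ndarray, v: int):
    """NIPALS PLS1 on centred data; returns (beta, scores, n_used)."""
    n, p = Xc.shape
    E, f = Xc.copy(), yc.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(v):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # response residual orthogonal to X: rank exhausted
            break
        w /= nw
        t = E @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pvec = E.T @ t / tt
        q = f @ t / tt  # OLS of the residual response on the (orthogonal) score
        E = E - np.outer(t, pvec)
        f = f - q * t
        W.append(w)
        P.append(pvec)
        Q.append(q)
        T.append(t)
    if not W:
        return np.zeros(p), np.empty((n, 0)), 0
    Wm, Pm, Qm = np.column_stack(W), np.column_stack(P), np.array(Q)
    # back-transform factor regression to the original covariate scale
    beta = Wm @ np.linalg.solve(Pm.T @ Wm, Qm)
    return beta, np.column_stack(T), len(W)


def fit_pls(X, logy, v: int) -> AFTModelFit:
    """Partial least squares AFT fit with ``v`` latent factors.

    Factors are built from both X and log y (NIPALS); the model is then an
    OLS of log y on the factors, reported back on the covariate scale.  A
    ``v`` at or above the rank of X is reduced with a warning.
    """
    X, y = _check_xy(X, logy)
    if not 1 <= v < X.shape[0]:
        raise ValueError(f"need 1 <= v < n, got v={v}, n={X.shape[0]}")
    xm, ym = X.mean(axis=0), y.mean()
    beta, _, used = _pls1(X - xm, y - ym, v)
    if used < v:
        warnings.warn(
            f"PLS rank exhausted: using {used} of {v} requested factors",
            RuntimeWarning,
            stacklevel=2,
        )
    return AFTModelFit(
        "PLS", beta, float(ym - xm @ beta), tuning={"v": v, "v_used": used}
    )


def fit_spls(X, logy, v: int, eta: float) -> AFTModelFit:
    """Sparse partial least squares AFT fit.

    At each of the ``v`` steps the direction z = X^T r (r the current
    response residual) is soft-thresholded at eta * max|z|; variables with
    surviving loadings join the active set, and a plain PLS fit with the
    current number of factors is computed on the active columns.  eta = 0
    keeps every variable active and reproduces :func:`fit_pls`.
    """
    X, y = _check_xy(X, logy)
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"need 0 <= eta < 1, got {eta}")
    if not 1 <= v < X.shape[0]:
        raise ValueError(f"need 1 <= v < n, got v={v}, n={X.shape[0]}")
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    p = Xc.shape[1]

    active = np.zeros(p, dtype=bool)
    beta = np.zeros(p)
    used = 0
    for k in range(1, v + 1):
        r = yc - Xc @ beta
        z = Xc.T @ r
        zmax = np.abs(z).max()
        if zmax < 1e-12:
            break
        w = np.sign(z) * np.maximum(np.abs(z) - eta * zmax, 0.0)
        active |= w != 0.0
        sub_beta, _, used = _pls1(Xc[:, active], yc, k)
        beta = np.zeros(p)
        beta[active] = sub_beta
        if used < k:
            break
    return AFTModelFit(
        "SPLS", beta, float(ym - xm @ beta), tuning={"v": v, "eta": eta, "v_used": used}
    )


def fit_enet(X, logy, lam: float, alpha: float, max_iter: int = 50_000) -> AFTModelFit:
    """Elastic-net AFT fit: minimise
    1/2 ||y - c - X b||^2 + lam [ (1-alpha)/2 ||b||^2 + alpha ||b||_1 ]
    with an unpenalised intercept c.  ``alpha = 1`` is the lasso.

    Solved with scikit-learn coordinate descent (whose objective equals the
    above divided by n, with its ``alpha`` parameter set to lam/n).
    """
    X, y = _check_xy(X, logy)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    n = X.shape[0]
    model = ElasticNet(
        alpha=lam / n, l1_ratio=alpha, fit_intercept=True, max_iter=max_iter, tol=1e-7
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model.fit(X, y)
    for w in caught:
        if "did not converge" in str(w.message).lower() or "convergence" in str(
            w.category.__name__
        ).lower():
            raise RuntimeError(
                f"elastic net failed to converge (lam={lam}, alpha={alpha}, "
                f"n={n}, p={X.shape[1]}): {w.message}"
            )
    method = "LASSO" if alpha == 1.0 else "ELNET"
    return AFTModelFit(
        method,
        np.asarray(model.coef_, dtype=float),
        float(model.intercept_),
        tuning={"lambda": lam, "alpha": alpha},
    )


def fit_lasso(X, logy, lam: float) -> AFTModelFit:
    return fit_enet(X, logy, lam, alpha=1.0)


def linear_predictor(fit: AFTModelFit, X_new) -> np.ndarray:
    X = np.asarray(X_new, dtype=float)
    if X.ndim != 2 or X.shape[1] != fit.beta.size:
        raise ValueError(
            f"X_new has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"fit expects {fit.beta.size}"
        )
    if fit.scaling is not None:
        means, sds = fit.scaling
        X = (X - means) / sds
    return fit.intercept + X @ fit.beta


def predict_time(fit: AFTModelFit, X_new) -> np.ndarray:
    """Predicted survival times yhat = exp(intercept + X beta), in years.

    This is the conditional median under any symmetric error on the log
    scale; no residual-mean correction is applied.
    """
    return np.exp(linear_predictor(fit, X_new))


def lambda_grid(X, logy, alpha: float, num: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda grid from lambda_max (all-zero solution) downward.

    lambda_max = max |X^T (y - ybar)| / max(alpha, 1e-3) on the paper-scale
    objective; the grid spans ``decades`` orders of magnitude below it.
    """
    X, y = _check_xy(X, logy)
    yc = y - y.mean()
    lam_max = float(np.abs(X.T @ yc).max()) / max(alpha, 1e-3)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), num)


def _simplicity_key(params: dict) -> tuple:
    """Tie-break ordering: prefer smaller v, larger eta, larger lambda."""
    return (
        params.get("v", 0),
        -params.get("eta", 0.0),
        -params.get("lambda", 0.0),
        -params.get("alpha", 0.0),
    )


def cross_validate(
    fitter: Callable[..., AFTModelFit],
    X,
    logy,
    grid: Sequence[dict],
    plan: CVPlan | None = None,
) -> tuple[dict, list[dict]]:
    """Mean held-out squared error on log time per grid point; returns the
    argmin and the full CV curve.

    The fold assignment is seeded and shared across the grid so grid points
    are compared on identical splits.  Exact ties are broken toward the
    simpler model (smaller v, larger eta, larger lambda).
    """
    if not grid:
        raise ValueError("empty tuning grid")
    X, y = _check_xy(X, logy)
    plan = plan or CVPlan()
    folds = plan.folds(X.shape[0])
    all_idx = np.arange(X.shape[0])

    curve = []
    for params in grid:
        errs = []
        for hold in folds:
            tr = np.setdiff1d(all_idx, hold, assume_unique=False)
            fit = fitter(X[tr], y[tr], **params)
            resid = y[hold] - linear_predictor(fit, X[hold])
            errs.append(float(np.mean(resid**2)))
        curve.append({**params, "cv_mse": float(np.mean(errs))})

    best = min(curve, key=lambda c: (c["cv_mse"], _simplicity_key(c)))
    best_params = {k: v for k, v in best.items() if k != "cv_mse"}
    return best_params, curve


def cv_enet(
    X,
    logy,
    alphas: Sequence[float],
    lambdas: np.ndarray | None = None,
    plan: CVPlan | None = None,
) -> tuple[dict, list[dict]]:
    """Path-based 10-fold CV for the elastic net (fast warm-started solver).

    Equivalent to :func:`cross_validate` over the (alpha, lambda) grid but
    computed with :func:`sklearn.linear_model.enet_path` per fold.
    """
    X, y = _check_xy(X, logy)
    plan = plan or CVPlan()
    folds = plan.folds(X.shape[0])
    all_idx = np.arange(X.shape[0])
    n = X.shape[0]

    curve = []
    for alpha in alphas:
        lams = lambda_grid(X, y, alpha) if lambdas is None else np.asarray(lambdas)
        sse = np.zeros(lams.size)
        cnt = 0
        for hold in folds:
            tr = np.setdiff1d(all_idx, hold)
            Xt, yt = X[tr], y[tr]
            ym = yt.mean()
            # sklearn path: alphas on its scale are lam / n_train, decreasing
            with warnings.catch_warnings():
                # tuning-path fits at tiny lambdas may stop at max_iter;
                # the selected lambda is refit strictly afterwards
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    Xt - Xt.mean(axis=0),
                    yt - ym,
                    l1_ratio=max(alpha, 1e-3),
                    alphas=lams / Xt.shape[0],
                )
            pred = (X[hold] - Xt.mean(axis=0)) @ coefs + ym
            sse += np.sum((y[hold][:, None] - pred) ** 2, axis=0)
            cnt += hold.size
        for lam, s in zip(lams, sse / cnt):
            curve.append({"lambda": float(lam), "alpha": float(alpha), "cv_mse": float(s)})
    best = min(curve, key=lambda c: (c["cv_mse"], _simplicity_key(c)))
    return {"lambda": best["lambda"], "alpha": best["alpha"]}, curve


class CVFitter:
    """A tuned fitter: cross-validates on first use, optionally freezing the
    chosen tuning for subsequent fits (used inside the imputation loop).

    Parameters
    ----------
    method : one of ``PLS``, ``SPLS``, ``LASSO``, ``ELNET``, ``OLS_CLINICAL``.
    retune : ``"always"`` re-tunes at every call; ``"first"`` freezes the
        tuning after the first call; ``"never"`` requires explicit tuning.
    grid : overrides the default tuning grid (list of parameter dicts for
        PLS/SPLS; for LASSO/ELNET a dict ``{"alphas": [...], "lambdas": ...}``).
    """

    DEFAULT_GRIDS = {
        "PLS": [{"v": v} for v in range(1, 11)],
        "SPLS": [
            {"v": v, "eta": round(eta, 1)}
            for v in range(1, 11)
            for eta in np.arange(0.1, 1.0, 0.1)
        ],
        "ELNET": {"alphas": [round(a, 1) for a in np.arange(0.1, 1.01, 0.1)]},
        "LASSO": {"alphas": [1.0]},
    }

    def __init__(self, method: str, retune: str = "always", grid=None, cv_seed: int = 0,
                 n_folds: int = 10, tuning: dict | None = None):
        if method not in ("PLS", "SPLS", "LASSO", "ELNET", "OLS_CLINICAL"):
            raise ValueError(f"unknown method {method!r}")
        if retune not in ("always", "first", "never"):
            raise ValueError("retune must be 'always', 'first' or 'never'")
        self.method = method
        self.retune = retune
        self.grid = grid if grid is not None else self.DEFAULT_GRIDS.get(method)
        self.plan = CVPlan(n_folds=n_folds, seed=cv_seed)
        self.tuning: dict | None = dict(tuning) if tuning else None
        self.cv_curve: list[dict] | None = None
        self.cv_mse_: float | None = None
        if retune == "never" and self.tuning is None and method != "OLS_CLINICAL":
            raise ValueError("retune='never' requires explicit tuning")

    def _tune(self, X, logy) -> dict:
        if self.method in ("LASSO", "ELNET"):
            lambdas = self.grid.get("lambdas")
            best, curve = cv_enet(X, logy, self.grid["alphas"], lambdas, self.plan)
        else:
            fitter = fit_pls if self.method == "PLS" else fit_spls
            # cap v below the fold-training size
            max_v = max(2, int(np.ceil(X.shape[0] * (1 - 1 / self.plan.n_folds))) - 1)
            grid = [g for g in self.grid if g.get("v", 1) < max_v]
            best, curve = cross_validate(fitter, X, logy, grid, self.plan)
        self.cv_curve = curve
        self.cv_mse_ = min(c["cv_mse"] for c in curve)
        return best

    def fit(self, X, logy) -> AFTModelFit:
        if self.method == "OLS_CLINICAL":
            if self.cv_mse_ is None:  # comparability with tuned methods
                _, curve = cross_validate(lambda Xs, ys: fit_ols(Xs, ys), X, logy, [{}], self.plan)
                self.cv_mse_ = curve[0]["cv_mse"]
            return fit_ols(X, logy)
        if self.tuning is None or self.retune == "always":
            tuning = self._tune(X, logy)
            if self.retune in ("first", "never"):
                self.tuning = tuning
        else:
            tuning = self.tuning
        if self.method == "PLS":
            return fit_pls(X, logy, **tuning)
        if self.method == "SPLS":
            return fit_spls(X, logy, **tuning)
        return fit_enet(X, logy, tuning["lambda"], tuning["alpha"])

    __call__ = fit
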