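"""Sparse Bayesian linear regression (ARD) mapping FC features to WMA.

The normative model is a linear weighted summation of connectivity values,
WMA = w0 + sum_i w_i x_i, with automatic relevance determination: each weight
carries its own Gaussian prior N(0, 1/alpha_i) with a broad Gamma hyperprior
on the precision alpha_i, and a Gamma hyperprior on the noise precision.
Inference is mean-field variational Bayes; irrelevant features have their
precision driven up until they are pruned, yielding automatic connection
selection.  The number of selected connections is data-dependent, never
forced.

Free energy (the evidence lower bound) is tracked every sweep and is
non-decreasing, which the test suite asserts.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

_LOG2PI = float(np.log(2.0 * np.pi))


class SparseBayesianRegression(RegressorMixin, BaseEstimator):
    """ARD linear regression fitted by variational Bayes.

    Features and target are z-scored internally; reported coefficients are on
    the original scale.  Coefficients of pruned features are exactly zero.

    Parameters
    ----------
    alpha_shape, alpha_rate
        Gamma hyperprior on the per-feature weight precisions.  Broad
        defaults (1e-10) make the prior essentially non-informative; raising
        ``alpha_shape`` strengthens the sparsity pressure.
    beta_shape, beta_rate
        Gamma hyperprior on the noise precision.
    prune_precision
        A feature is removed once its posterior mean precision exceeds this
        value; on the standardized scale that bounds the posterior weight SD
        by ``prune_precision**-0.5`` (1e-2 at the default 1e4).
    tol
        Convergence threshold on the relative change of the free energy.
    max_iter
        Maximum number of VB sweeps.
    random_state
        Unused by the deterministic fit; accepted for pipeline compatibility.
    """

    def __init__(
        self,
        alpha_shape: float = 1e-10,
        alpha_rate: float = 1e-10,
        beta_shape: float = 1e-10,
        beta_rate: float = 1e-10,
        prune_precision: float = 1e4,
        tol: float = 1e-8,
        max_iter: int = 5000,
        random_state: int | None = None,
    ) -> None:
        self.alpha_shape = alpha_shape
        self.alpha_rate = alpha_rate
        self.beta_shape = beta_shape
        self.beta_rate = beta_rate
        self.prune_precision = prune_precision
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "SparseBayesianRegression":
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 observations")
        self.n_features_in_ = p

        self.feature_means_ = X.mean(axis=0)
        sx = X.std(axis=0)
        self.dropped_features_ = np.flatnonzero(sx == 0)
        if self.dropped_features_.size:
            warnings.warn(
                f"dropping {self.dropped_features_.size} zero-variance feature(s)",
                stacklevel=2,
            )
        self.feature_sds_ = np.where(sx == 0, 1.0, sx)
        self.target_mean_ = float(y.mean())
        sy = float(y.std())

        if sy == 0.0:
            self.target_sd_ = 1.0
            self.coef_ = np.zeros(p)
            self.support_ = np.array([], dtype=int)
            self.ard_precision_ = np.full(p, np.inf)
            self.intercept_ = self.target_mean_
            self.elbo_trace_ = np.array([])
            self.n_iter_ = 0
            self.converged_ = True
            return self

        self.target_sd_ = sy
        Xs = (X - self.feature_means_) / self.feature_sds_
        ys = (y - self.target_mean_) / sy

        usable = np.setdiff1d(np.arange(p), self.dropped_features_)
        active = usable.copy()
        a0, b0 = self.alpha_shape, self.alpha_rate
        c0, d0 = self.beta_shape, self.beta_rate

        Xa = Xs[:, active]
        XtX = Xa.T @ Xa
        Xty = Xa.T @ ys
        yty = float(ys @ ys)

        E_alpha = np.ones(active.size)
        E_ln_alpha = np.zeros(active.size)
        E_beta, E_ln_beta = 1.0, 0.0
        a_n = a0 + 0.5
        c_n = c0 + n / 2.0

        elbo_trace: list[float] = []
        mu = np.zeros(active.size)
        Sigma = np.eye(active.size)
        converged = False

        for it in range(self.max_iter):
            m = active.size
            # q(w) update
            A = E_beta * XtX + np.diag(E_alpha)
            L = np.linalg.cholesky(A)
            Linv = np.linalg.inv(L)
            Sigma = Linv.T @ Linv
            mu = E_beta * (Sigma @ Xty)
            logdet_Sigma = -2.0 * float(np.log(np.diag(L)).sum())
            E_w2 = mu**2 + np.diag(Sigma)

            # q(alpha) update
            b_n = b0 + 0.5 * E_w2
            E_alpha = a_n / b_n
            E_ln_alpha = digamma(a_n) - np.log(b_n)

            # q(beta) update
            r = ys - Xa @ mu
            resid2 = float(r @ r)
            trace_term = float(np.sum(XtX * Sigma))
            d_n = d0 + 0.5 * (resid2 + trace_term)
            E_beta = c_n / d_n
            E_ln_beta = float(digamma(c_n) - np.log(d_n))

            elbo = self._elbo(
                n, m, E_beta, E_ln_beta, E_alpha, E_ln_alpha, E_w2,
                resid2, trace_term, logdet_Sigma, a_n, b_n, c_n, d_n,
                a0, b0, c0, d0,
            )
            elbo_trace.append(elbo)

            # prune features whose precision diverged
            keep = E_alpha <= self.prune_precision
            pruned_now = not keep.all()
            if pruned_now:
                active = active[keep]
                mu, Sigma = mu[keep], Sigma[np.ix_(keep, keep)]
                E_alpha, E_ln_alpha = E_alpha[keep], E_ln_alpha[keep]
                if active.size == 0:
                    converged = True
                    break
                Xa = Xs[:, active]
                XtX, Xty = Xa.T @ Xa, Xa.T @ ys

            if (
                not pruned_now
                and len(elbo_trace) > 1
                and abs(elbo_trace[-1] - elbo_trace[-2])
                < self.tol * (abs(elbo_trace[-1]) + 1.0)
            ):
                converged = True
                break

        coef_std = np.zeros(p)
        coef_std[active] = mu
        self.coef_ = coef_std * sy / self.feature_sds_
        self.intercept_ = self.target_mean_ - float(self.coef_ @ self.feature_means_)
        self.support_ = np.sort(active)
        precision = np.full(p, np.inf)
        precision[active] = E_alpha
        self.ard_precision_ = precision
        self.noise_precision_ = E_beta / sy**2
        self.posterior_cov_std_ = Sigma
        self.elbo_trace_ = np.asarray(elbo_trace)
        self.n_iter_ = len(elbo_trace)
        self.converged_ = converged
        return self

    @staticmethod
    def _elbo(
        n, m, E_beta, E_ln_beta, E_alpha, E_ln_alpha, E_w2,
        resid2, trace_term, logdet_Sigma, a_n, b_n, c_n, d_n,
        a0, b0, c0, d0,
    ) -> float:
        # E[ln p(y|w,beta)]
        lik = 0.5 * n * (E_ln_beta - _LOG2PI) - 0.5 * E_beta * (resid2 + trace_term)
        # E[ln p(w|alpha)] and E[ln p(alpha)]
        pw = 0.5 * float(np.sum(E_ln_alpha)) - 0.5 * m * _LOG2PI - 0.5 * float(
            np.sum(E_alpha * E_w2)
        )
        palpha = float(
            np.sum(a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * E_ln_alpha - b0 * E_alpha)
        )
        pbeta = c0 * np.log(d0) - gammaln(c0) + (c0 - 1.0) * E_ln_beta - d0 * E_beta
        # entropies
        hw = 0.5 * logdet_Sigma + 0.5 * m * (1.0 + _LOG2PI)
        halpha = float(
            np.sum(a_n - np.log(b_n) + gammaln(a_n) + (1.0 - a_n) * digamma(a_n))
        )
        hbeta = c_n - np.log(d_n) + gammaln(c_n) + (1.0 - c_n) * digamma(c_n)
        return float(lik + pw + palpha + pbeta + hw + halpha + hbeta)

    # ------------------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.coef_.shape[0]}"
            )
        return self.intercept_ + X @ self.coef_


# ----------------------------------------------------------------------
# module-level wrappers


def fit_vbsr(X: np.ndarray, y: np.ndarray, **params) -> SparseBayesianRegression:
    """Fit the ARD model; thin functional wrapper over the estimator."""
    return SparseBayesianRegression(**params).fit(X, y)


def predict(model: SparseBayesianRegression, fc: np.ndarray) -> np.ndarray | float:
    """Predicted WMA for one FC vector or a subjects x features matrix."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim == 1:
        return float(model.predict(fc[None, :])[0])
    return model.predict(fc)


def loocv(X: np.ndarray, y: np.ndarray, **params) -> dict:
    """Leave-one-out cross-validation of the ARD model.

    Every subject is predicted by a model trained on all other subjects;
    returns the held-out predictions and R^2 = 1 - SSE/SST (which may be
    negative when the model predicts worse than the mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = SparseBayesianRegression(**params).fit(X[mask], y[mask])
        preds[i] = est.predict(X[i][None, :])[0]
    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return {"r2": r2, "predictions": preds}


def contribution_ratios(
    model: SparseBayesianRegression,
    X_train: np.ndarray,
    labels: list[str] | None = None,
) -> "pd.DataFrame":
    """Signed percent contribution of each selected connection.

    contribution_i = mean over training subjects of w_i * x_i, divided by the
    sum of those means over the support, times 100.  Percentages are signed
    and sum to 100 up to rounding.
    """
    import pandas as pd

    check_is_fitted(model, "coef_")
    X_train = np.asarray(X_train, dtype=float)
    sup = model.support_
    if sup.size == 0:
        raise ValueError("model has an empty support; no contributions to report")
    mean_wfc = model.coef_[sup] * X_train[:, sup].mean(axis=0)
    denom = float(mean_wfc.sum())
    if denom == 0.0:
        raise ValueError("sum of mean weighted FC is zero; ratios undefined")
    pct = 100.0 * mean_wfc / denom
    if labels is None:
        labels = [f"feature{i}" for i in sup]
    else:
        labels = [labels[i] for i in sup]
    order = np.argsort(-np.abs(pct))
    return pd.DataFrame(
        {
            "feature_index": sup[order],
            "label": [labels[k] for k in order],
            "weight": model.coef_[sup][order],
            "mean_weighted_fc": mean_wfc[order],
            "contribution_pct": pct[order],
        }
    ).reset_index(drop=True)


# ----------------------------------------------------------------------
# serialization


def model_to_dict(model: SparseBayesianRegression, labels: list[str] | None = None) -> dict:
    check_is_fitted(model, "coef_")
    return {
        "schema": "wmconn-model-1",
        "weights": model.coef_.tolist(),
        "intercept": model.intercept_,
        "support": model.support_.tolist(),
        "support_labels": (
            [labels[i] for i in model.support_] if labels is not None else None
        ),
        "feature_means": model.feature_means_.tolist(),
        "feature_sds": model.feature_sds_.tolist(),
        "target_mean": model.target_mean_,
        "target_sd": model.target_sd_,
        "ard_precision": [
            None if not np.isfinite(v) else v for v in model.ard_precision_
        ],
        "diagnostics": {
            "n_iter": int(model.n_iter_),
            "converged": bool(model.converged_),
            "final_elbo": (
                float(model.elbo_trace_[-1]) if model.elbo_trace_.size else None
            ),
        },
        "params": model.get_params(),
    }


def save_model(
    model: SparseBayesianRegression, path: str | Path, labels: list[str] | None = None
) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, labels), indent=1))


def load_model(path: str | Path) -> SparseBayesianRegression:
    d = json.loads(Path(path).read_text())
    est = SparseBayesianRegression(**d["params"])
    est.coef_ = np.asarray(d["weights"], dtype=float)
    est.intercept_ = float(d["intercept"])
    est.support_ = np.asarray(d["support"], dtype=int)
    est.feature_means_ = np.asarray(d["feature_means"], dtype=float)
    est.feature_sds_ = np.asarray(d["feature_sds"], dtype=float)
    est.target_mean_ = float(d["target_mean"])
    est.target_sd_ = float(d["target_sd"])
    est.ard_precision_ = np.asarray(
        [np.inf if v is None else v for v in d["ard_precision"]], dtype=float
    )
    est.n_features_in_ = est.coef_.shape[0]
    est.n_iter_ = d["diagnostics"]["n_iter"]
    est.converged_ = d["diagnostics"]["converged"]
    est.elbo_trace_ = np.array(
        [] if d["diagnostics"]["final_elbo"] is None else [d["diagnostics"]["final_elbo"]]
    )
    return est
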