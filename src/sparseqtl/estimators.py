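"""scikit-learn style estimator facade over the sparse Bayesian sampler.

``SparseBayesianEQTL`` is a fit/predict estimator: fit(X, y) runs the
evolutionary stochastic search over marker-inclusion indicators against a
single- or multi-tissue response and exposes the posterior summaries as
fitted attributes; predict(X) returns fitted values under the best visited
model's posterior-mean effects.  The class composes with sklearn tooling
(get_params/set_params, clone) via BaseEstimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import ExpressionPanel, GenotypePanel, ModelIndicator
from .model import Hyperparameters, ScoreWorkspace
from .postprocess import tau_posterior_given_model
from .sampler import SamplerConfig, run_ess
from .summaries import (
    best_model,
    log10_bayes_factor,
    marginal_inclusion,
    model_size_posterior,
)

__all__ = ["SparseBayesianEQTL"]


class SparseBayesianEQTL(RegressorMixin, BaseEstimator):
    """Sparse Bayesian (multi-)regression for multi-locus eQTL mapping.

    Parameters mirror the model hyperparameters and sampler knobs; see
    Hyperparameters and SamplerConfig.  A 1-D y fits the single-tissue
    model; an (n, q) y fits the joint multi-tissue (matrix-variate) model.

    Fitted attributes
    -----------------
    mppi_ : (p,) marginal posterior inclusion probability per marker
    best_model_ : ModelIndicator of the best visited model
    size_posterior_ : posterior over model sizes
    log10_bf_best_vs_null_ : log10 Bayes factor of best vs null model
    trace_ : VisitedModelTrace of the cold chain
    workspace_ : ScoreWorkspace (cached sufficient statistics)
    coef_ : (p, q) posterior-mean effect matrix (zeros off the best model)
    """

    def __init__(
        self,
        n_chains: int = 4,
        n_sweeps: int = 25_000,
        burn_in: int = 5_000,
        delta: float = 3.0,
        k_scale: float | None = None,
        e_size: float = 2.0,
        v_size: float = 2.0,
        max_model_size: int = 15,
        tau_grid_size: int = 100,
        crossover_prob: float = 0.25,
        random_state: int = 0,
    ):
        self.n_chains = n_chains
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.delta = delta
        self.k_scale = k_scale
        self.e_size = e_size
        self.v_size = v_size
        self.max_model_size = max_model_size
        self.tau_grid_size = tau_grid_size
        self.crossover_prob = crossover_prob
        self.random_state = random_state

    # -- plumbing -------------------------------------------------------------

    def _coerce(self, X, y):
        if isinstance(X, GenotypePanel):
            Xmat = X.codes
        else:
            Xmat = np.asarray(X, dtype=float)
        if isinstance(y, ExpressionPanel):
            Ymat = y.values
        else:
            Ymat = np.asarray(y, dtype=float)
            if Ymat.ndim == 1:
                Ymat = Ymat[:, None]
        if Xmat.ndim != 2:
            raise ValueError("X must be 2-D (strains x markers)")
        if Ymat.shape[0] != Xmat.shape[0]:
            raise ValueError("X and y have different numbers of strains")
        if np.isnan(Xmat).any():
            raise ValueError("X contains missing genotypes; impute first")
        if np.isnan(Ymat).any():
            raise ValueError("y contains missing values")
        return Xmat, Ymat

    def _hyper(self, Ymat, p):
        kw = dict(
            delta=self.delta,
            e_size=self.e_size,
            v_size=self.v_size,
            max_model_size=self.max_model_size,
            tau_grid_size=self.tau_grid_size,
        )
        if self.k_scale is not None:
            kw["k_scale"] = self.k_scale
        return Hyperparameters.from_data(Ymat, p, **kw)

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y):
        Xmat, Ymat = self._coerce(X, y)
        self.n_features_in_ = Xmat.shape[1]
        self._y_mean = Ymat.mean(axis=0)
        hyper = self._hyper(Ymat, Xmat.shape[1])
        config = SamplerConfig(
            n_chains=self.n_chains,
            n_sweeps=self.n_sweeps,
            burn_in=self.burn_in,
            crossover_prob=self.crossover_prob,
            seed=self.random_state,
        )
        ws = ScoreWorkspace(Ymat, Xmat, hyper)
        trace = run_ess(None, None, config, rng=self.random_state, workspace=ws)
        self.workspace_ = ws
        self.trace_ = trace
        self.mppi_ = marginal_inclusion(trace)
        self.size_posterior_ = model_size_posterior(trace)
        self.best_model_ = best_model(trace)
        self.log10_bf_best_vs_null_ = log10_bayes_factor(
            self.best_model_, ModelIndicator.null(ws.p), ws
        )
        self.coef_ = self._posterior_mean_coef()
        return self

    def _posterior_mean_coef(self) -> np.ndarray:
        ws = self.workspace_
        coef = np.zeros((ws.p, ws.q))
        idx = list(self.best_model_.included)
        if idx:
            tau_post = tau_posterior_given_model(ws, tuple(idx))
            c = float(np.sum(tau_post * (ws.tau_grid / (1.0 + ws.tau_grid))))
            Xg = ws.X[:, idx]
            coef[idx] = c * np.linalg.solve(Xg.T @ Xg, Xg.T @ ws.Y)
        return coef

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        Xmat = X.codes if isinstance(X, GenotypePanel) else np.asarray(X, float)
        out = Xmat @ self.coef_ + self._y_mean
        return out.ravel() if out.shape[1] == 1 else out
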