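"""scikit-learn style estimators wrapping the network-inference core.

``NetworkInference`` fits the interaction matrix at fixed regularization;
``NetworkInferenceCV`` selects per-gene (alpha, beta) by leave-one-
observation-out cross-validation. Both accept an :class:`ObservationSet` or
a plain gene-by-sample array (treated as wild-type steady-state samples)
and expose the fitted matrix as ``W_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ObservationSet, PriorNetwork
from .inference import fit_network, insample_ols_error, loo_cv_fit


def as_observation_set(X, mode: str = "steady_state") -> ObservationSet:
    """Coerce a gene-by-sample array into an :class:`ObservationSet`."""
    if isinstance(X, ObservationSet):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D gene-by-sample matrix")
    names = [f"g{i}" for i in range(X.shape[0])]
    return ObservationSet(values=X, mode=mode, gene_names=names)


class NetworkInference(BaseEstimator):
    """Infer a gene interaction matrix at fixed (alpha, beta).

    Parameters
    ----------
    model : {"ode", "markov"}
        Steady-state (zero estimated diagonal) or first-order Markov
        (free diagonal) interpretation of the data.
    alpha : float
        L1 sparsity penalty on every coefficient.
    beta : float
        Extra L1 penalty on coefficients absent from the prior network.
    prior : PriorNetwork, optional
        Penalty-exemption matrix; ``None`` penalizes everything uniformly.
    tol, max_iter
        Coordinate-descent convergence controls.

    Attributes
    ----------
    W_ : ndarray of shape (p, p)
        Fitted interaction matrix, ``W_[i, j]`` = influence of gene j on i.
    network_ : GeneNetwork
    gene_names_ : list of str
    """

    def __init__(self, model="ode", alpha=0.0, beta=0.0, prior=None, tol=1e-5, max_iter=10000):
        self.model = model
        self.alpha = alpha
        self.beta = beta
        self.prior = prior
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        obs = as_observation_set(X, "steady_state" if self.model == "ode" else "time_series")
        self.network_ = fit_network(
            obs,
            prior=self.prior,
            model_kind=self.model,
            alpha=self.alpha,
            beta=self.beta,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.W_ = self.network_.W
        self.gene_names_ = list(self.network_.gene_names)
        return self

    def score(self, X, y=None):
        """Negative in-sample squared error of the unregularized residual."""
        obs = as_observation_set(X, "steady_state" if self.model == "ode" else "time_series")
        from .inference import _blocks  # local import to keep surface small

        Z, Xt, M = _blocks(obs, self.model)
        pred = np.einsum("omp,gp->omg", Z, self.W_)
        resid = (pred - Xt) ** 2
        return -float(np.sum(resid[M]))


class NetworkInferenceCV(BaseEstimator):
    """Network inference with per-gene LOO-CV over an exponential grid.

    Attributes (after fit): ``W_``, ``network_``, ``alpha_`` / ``beta_``
    (per-gene arrays), ``cv_error_`` (summed over genes), ``fit_``
    (:class:`RegularizationFit`), and ``ols_error_`` (unregularized
    in-sample floor, for proportional errors).
    """

    def __init__(self, model="ode", grid_depth=20, prior=None, tol=1e-5, max_iter=10000):
        self.model = model
        self.grid_depth = grid_depth
        self.prior = prior
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        obs = as_observation_set(X, "steady_state" if self.model == "ode" else "time_series")
        self.network_, self.fit_ = loo_cv_fit(
            obs,
            prior=self.prior,
            model_kind=self.model,
            grid_depth=self.grid_depth,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.W_ = self.network_.W
        self.gene_names_ = list(self.network_.gene_names)
        self.alpha_ = self.fit_.alphas
        self.beta_ = self.fit_.betas
        self.cv_errors_ = self.fit_.cv_errors
        self.cv_error_ = self.fit_.total_cv_error
        self.ols_error_ = float(
            np.sum(insample_ols_error(obs, self.model, tol=self.tol, max_iter=self.max_iter))
        )
        return self


__all__ = ["NetworkInference", "NetworkInferenceCV", "as_observation_set", "PriorNetwork"]
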