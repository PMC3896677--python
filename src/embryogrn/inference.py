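"""Unified regularized inference of gene interaction matrices.

Two linear models share one row-separable objective. For steady-state data
each sample ``x`` is assumed to satisfy ``x_i ~ sum_{j != i} W_ij x_j`` (the
self-decay is absorbed, so the estimated diagonal is fixed at zero). For
time-series data consecutive points satisfy the first-order Markov relation
``x^{k+1} ~ W x^k`` with a free diagonal. Either way, row ``i`` of ``W``
minimizes

    w D^i w' - 2 w . U[:, i] + alpha ||w||_1 + beta ||w o W0_i||_1

where ``D^i`` and ``U`` accumulate outer products of the knockout-masked
regressors (knocked-down genes contribute zero as regressors), samples with
gene ``i`` unavailable are dropped from ``D^i``, and ``W0`` exempts known
interactions from the ``beta`` penalty. Regularization strengths are chosen
per gene by leave-one-observation-out cross-validation over a descending
exponential grid anchored at ``max |U_ij|``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    DesignMatrices,
    GeneNetwork,
    ObservationSet,
    PriorNetwork,
    RegularizationFit,
    permute_off_diagonal,
)
from .solver import _cd, _cv_grid

_MODE_FOR_KIND = {"ode": "steady_state", "markov": "time_series"}
_KIND_FOR_MODE = {v: k for k, v in _MODE_FOR_KIND.items()}


def normalize_by_gene_max(raw: np.ndarray, gene_names=None) -> np.ndarray:
    """Scale every gene row by its own maximum so each row peaks at 1.

    Raises
    ------
    ValueError
        If a gene row has no positive entry (its scale is undefined); the
        error names the offending gene.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D gene-by-sample matrix")
    if np.any(raw < 0):
        raise ValueError("expression counts must be nonnegative")
    maxima = raw.max(axis=1)
    bad = np.nonzero(maxima <= 0)[0]
    if bad.size:
        names = (
            [gene_names[i] for i in bad]
            if gene_names is not None
            else [f"row {i}" for i in bad]
        )
        raise ValueError(f"all-zero expression for gene(s): {', '.join(map(str, names))}")
    return raw / maxima[:, None]


def apply_knockout_mask(obs: ObservationSet) -> np.ndarray:
    """Masked matrix ``x_bar``: expression with knocked-down genes zeroed.

    A knocked-down gene cannot drive its targets, so it contributes zero as
    a regressor; all other entries are unchanged.
    """
    return np.where(obs.knockout_mask, 0.0, obs.values)


def _check_mode(obs: ObservationSet, model_kind: str) -> None:
    want = _MODE_FOR_KIND[model_kind]
    if obs.mode != want:
        raise ValueError(
            f"{model_kind} model requires {want} observations, got {obs.mode}"
        )


def _blocks(obs: ObservationSet, model_kind: str):
    """Per-observation regressor/target/mask blocks.

    Returns ``Z, X, M`` with shape ``(n_obs, m, p)`` where ``m`` is 1 for
    steady-state samples and ``k_max`` (transitions per series) for the
    Markov model. ``Z`` rows are the masked regressors (knockouts and
    missing values zeroed), ``X`` the targets with missing values zeroed,
    ``M`` the target-present masks.
    """
    _check_mode(obs, model_kind)
    xbar = apply_knockout_mask(obs)
    xbar = np.where(obs.missing_mask, 0.0, xbar)
    x = np.where(obs.missing_mask, 0.0, obs.values)
    present = ~obs.missing_mask
    if model_kind == "ode":
        Z = xbar.T[:, None, :]
        X = x.T[:, None, :]
        M = present.T[:, None, :]
        return np.ascontiguousarray(Z), np.ascontiguousarray(X), np.ascontiguousarray(M)
    if obs.k_points < 2:
        raise ValueError("Markov design needs at least 2 time points per observation")
    Zs, Xs, Ms = [], [], []
    for o in obs.observation_ids():
        cols = obs.observation_columns(int(o))
        Zs.append(xbar[:, cols[:-1]].T)
        Xs.append(x[:, cols[1:]].T)
        Ms.append(present[:, cols[1:]].T)
    return (
        np.ascontiguousarray(np.stack(Zs)),
        np.ascontiguousarray(np.stack(Xs)),
        np.ascontiguousarray(np.stack(Ms)),
    )


def _per_gene_stacks(Z, X, M, model_kind):
    """Per-gene, per-observation quadratic and linear contributions.

    ``D_stack[g, o]`` accumulates ``z z'`` over the rows of observation ``o``
    where target ``g`` is present; ``u_stack[g, o]`` accumulates ``z * x_g``.
    For the steady-state model the regressor position ``g`` is zeroed
    (``j != i`` restriction), which zeroes row/column ``g`` of ``D`` and
    entry ``g`` of ``u``.
    """
    n_obs, m, p = Z.shape
    D_stack = np.empty((p, n_obs, p, p))
    u_stack = np.empty((p, n_obs, p))
    for o in range(n_obs):
        Zo, Xo, Mo = Z[o], X[o], M[o]
        base = Zo.T @ Zo
        all_present = Mo.all()
        for g in range(p):
            if all_present:
                Dg = base.copy()
            else:
                Dg = (Zo * Mo[:, g : g + 1]).T @ Zo
            ug = Zo.T @ Xo[:, g]
            if model_kind == "ode":
                Dg[g, :] = 0.0
                Dg[:, g] = 0.0
                ug[g] = 0.0
            D_stack[g, o] = Dg
            u_stack[g, o] = ug
    return D_stack, u_stack


def build_design_ode(obs: ObservationSet) -> DesignMatrices:
    """Design matrices for the steady-state model.

    ``D^i`` sums masked outer products over the samples where gene ``i`` is
    available, with the regressor's self-position zeroed; ``U`` sums
    ``x_bar x'`` over all samples.
    """
    Z, X, M = _blocks(obs, "ode")
    D_stack, u_stack = _per_gene_stacks(Z, X, M, "ode")
    U = np.einsum("omp,omq->pq", Z, X)
    return DesignMatrices(D=[D_stack[g].sum(axis=0) for g in range(obs.n_genes)], U=U)


def build_design_markov(obs: ObservationSet) -> DesignMatrices:
    """Design matrices for the first-order Markov model.

    Every transition ``k -> k+1`` of every observation contributes
    ``x_bar^k (x_bar^k)'`` to ``D^i`` (skipped when the target ``x_i^{k+1}``
    is missing) and ``x_bar^k (x^{k+1})'`` to ``U``. The self-position is
    retained: a gene's concentration may drive its own next value.
    """
    Z, X, M = _blocks(obs, "markov")
    D_stack, u_stack = _per_gene_stacks(Z, X, M, "markov")
    U = np.einsum("omp,omq->pq", Z, X)
    return DesignMatrices(D=[D_stack[g].sum(axis=0) for g in range(obs.n_genes)], U=U)


def _resolve_kind(obs: ObservationSet, model_kind: str | None) -> str:
    if model_kind is None:
        return _KIND_FOR_MODE[obs.mode]
    if model_kind not in _MODE_FOR_KIND:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return model_kind


def _check_prior(prior: PriorNetwork | None, gene_names) -> np.ndarray:
    p = len(gene_names)
    if prior is None:
        return np.ones((p, p))
    if list(prior.gene_names) != list(gene_names):
        raise ValueError("prior network gene names do not match the observations")
    return prior.w0.astype(float)


def fit_network(
    obs: ObservationSet,
    prior: PriorNetwork | None = None,
    model_kind: str | None = None,
    alpha: float = 0.0,
    beta: float = 0.0,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> GeneNetwork:
    """Fit the interaction matrix at fixed regularization strengths.

    The objective is row-separable, so each gene's incoming weights are
    solved independently by coordinate descent. Genes whose target values
    are unavailable everywhere get a zero row with a warning.
    """
    model_kind = _resolve_kind(obs, model_kind)
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    w0 = _check_prior(prior, obs.gene_names)
    Z, X, M = _blocks(obs, model_kind)
    D_stack, u_stack = _per_gene_stacks(Z, X, M, model_kind)
    p = obs.n_genes
    W = np.zeros((p, p))
    for g in range(p):
        D_full = D_stack[g].sum(axis=0)
        u_full = u_stack[g].sum(axis=0)
        if not np.any(np.diag(D_full) > 0):
            warnings.warn(
                f"gene {obs.gene_names[g]!r} has no usable samples; returning a zero row",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        lam = alpha + beta * w0[g]
        W[g] = _cd(np.ascontiguousarray(D_full), np.ascontiguousarray(u_full), lam, tol, max_iter)
    if model_kind == "ode":
        np.fill_diagonal(W, 0.0)
    return GeneNetwork(W=W, gene_names=list(obs.gene_names), model_kind=model_kind)


def _grid(lam_max: float, depth: int) -> np.ndarray:
    """Descending exponential ladder from ``lam_max`` plus an exact zero."""
    if lam_max <= 0:
        return np.asarray([0.0])
    ladder = lam_max * 2.0 ** (-np.arange(depth + 1, dtype=float))
    return np.append(ladder, 0.0)


def loo_cv_fit(
    obs: ObservationSet,
    prior: PriorNetwork | None = None,
    model_kind: str | None = None,
    grid_depth: int = 20,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> tuple[GeneNetwork, RegularizationFit]:
    """Select per-gene (alpha, beta) by leave-one-observation-out CV.

    For the Markov model an observation is one complete time series; for the
    steady-state model it is a single sample. For each gene the 2-D grid
    descends exponentially from ``lam_max = max |U_ij|``; the pair with the
    smallest summed held-out squared prediction error wins, ties resolving
    to the sparsest model (largest alpha, then largest beta). The returned
    network is refit on all data at the chosen parameters.
    """
    model_kind = _resolve_kind(obs, model_kind)
    if obs.n_observations < 2:
        raise ValueError("leave-one-out CV needs at least 2 observations")
    w0 = _check_prior(prior, obs.gene_names)
    Z, X, M = _blocks(obs, model_kind)
    D_stack, u_stack = _per_gene_stacks(Z, X, M, model_kind)
    U = np.einsum("omp,omq->pq", Z, X)
    lam_max = float(np.max(np.abs(U))) if U.size else 0.0
    alphas = _grid(lam_max, grid_depth)
    betas = _grid(lam_max, grid_depth)
    no_beta = np.asarray([0.0])

    p = obs.n_genes
    W = np.zeros((p, p))
    best_a = np.zeros(p)
    best_b = np.zeros(p)
    cv_err = np.zeros(p)
    for g in range(p):
        w0_g = np.ascontiguousarray(w0[g])
        beta_grid = betas if np.any(w0_g == 0) else no_beta
        a, b, err = _cv_grid(
            np.ascontiguousarray(D_stack[g]),
            np.ascontiguousarray(u_stack[g]),
            Z,
            np.ascontiguousarray(X[:, :, g]),
            np.ascontiguousarray(M[:, :, g]),
            alphas,
            beta_grid,
            w0_g,
            tol,
            max_iter,
        )
        best_a[g], best_b[g], cv_err[g] = a, b, err
        D_full = np.ascontiguousarray(D_stack[g].sum(axis=0))
        u_full = np.ascontiguousarray(u_stack[g].sum(axis=0))
        lam = a + b * w0_g
        W[g] = _cd(D_full, u_full, lam, tol, max_iter)
    if model_kind == "ode":
        np.fill_diagonal(W, 0.0)
    net = GeneNetwork(W=W, gene_names=list(obs.gene_names), model_kind=model_kind)
    fit = RegularizationFit(
        alphas=best_a,
        betas=best_b,
        cv_errors=cv_err,
        grid_alphas=alphas,
        grid_betas=betas,
        grid_depth=grid_depth,
    )
    return net, fit


def insample_ols_error(
    obs: ObservationSet,
    model_kind: str | None = None,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> np.ndarray:
    """Per-gene in-sample residual of the unregularized fit.

    Solves each row at ``alpha = beta = 0`` (exact normal-equation
    solution) on the full data and evaluates the in-sample squared error;
    this is the least-squares floor that proportional errors are measured
    against.
    """
    model_kind = _resolve_kind(obs, model_kind)
    Z, X, M = _blocks(obs, model_kind)
    D_stack, u_stack = _per_gene_stacks(Z, X, M, model_kind)
    p = obs.n_genes
    errs = np.zeros(p)
    lam = np.zeros(p)
    for g in range(p):
        D_full = np.ascontiguousarray(D_stack[g].sum(axis=0))
        u_full = np.ascontiguousarray(u_stack[g].sum(axis=0))
        w = _cd(D_full, u_full, lam, tol, max_iter)
        pred = np.einsum("omp,p->om", Z, w)
        errs[g] = float(np.sum(((pred - X[:, :, g]) ** 2)[M[:, :, g]]))
    return errs


def threshold_network(net: GeneNetwork, tau: float = 0.0) -> list[tuple[str, str, float]]:
    """Edges with ``|W_ij| >= tau`` as (regulator, target, weight) triples.

    Signs are preserved; at ``tau = 0`` all nonzero entries are returned.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    edges = []
    tgt_idx, reg_idx = np.nonzero((np.abs(net.W) >= tau) & (net.W != 0))
    for i, j in zip(tgt_idx, reg_idx):
        edges.append((net.gene_names[j], net.gene_names[i], float(net.W[i, j])))
    return edges


def prior_overlap(edges, prior: PriorNetwork):
    """Count prior interactions recovered in an edge list (direction-sensitive).

    ``edges`` holds (regulator, target[, weight]) tuples over the prior's
    gene namespace; unknown names raise.
    """
    known = set(prior.edge_list)
    names = set(prior.gene_names)
    matched = []
    for edge in edges:
        reg, tgt = edge[0], edge[1]
        if reg not in names:
            raise KeyError(f"unknown gene {reg!r}")
        if tgt not in names:
            raise KeyError(f"unknown gene {tgt!r}")
        if (reg, tgt) in known:
            matched.append(edge)
    return len(matched), matched


def prior_overlap_pvalue(
    net: GeneNetwork,
    prior: PriorNetwork,
    tau: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the prior-edge overlap of a thresholded network.

    Each null network uniformly shuffles the off-diagonal entries of ``W``
    before thresholding; the p-value uses the add-one estimator
    ``(1 + #{null overlap >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if list(net.gene_names) != list(prior.gene_names):
        raise ValueError("network and prior gene names do not match")
    exempt = (prior.w0 == 0) & ~np.eye(net.n_genes, dtype=bool)

    def overlap(W):
        return int(np.sum((np.abs(W) >= tau) & (W != 0) & exempt))

    observed = overlap(net.W)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if overlap(permute_off_diagonal(net.W, rng)) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
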