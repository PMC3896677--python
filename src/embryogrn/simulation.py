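"""Synthetic benchmark networks, noisy series, and inference-error sweeps.

The generator emulates the benchmark conditions of the inference study:
random sparse directed networks (10 genes, exactly 25 edges, in-degrees
2-3, N(0, 100) weights, verified nonsingular) and 4-time-point series built
by a backward recursion — the last latent state is standard normal, earlier
latent states are ``y^k = W^{-1} y^{k+1}``, and reported values add
intrinsic N(0, 0.1^2)-per-step and extrinsic N(0, 0.3^2) measurement noise.
Drawing edge weights with a large variance keeps ``W^{-1}`` small so the
backward recursion does not blow up.

Sweep runners measure the proportional error: the minimal cross-validation
error divided by the minimal least-squares error of the unregularized fit,
averaged over replicate networks (and prior-edge sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneNetwork, NoiseSpec, ObservationSet, PriorNetwork, SimNetworkSpec
from .inference import insample_ols_error, loo_cv_fit

_RCOND_MIN = 1e-10
_MAX_RESAMPLE = 100


def generate_random_network(
    spec: SimNetworkSpec | None = None, seed: int = 0
) -> GeneNetwork:
    """Draw a random sparse directed network, resampling until nonsingular.

    Every node receives between ``indegree_range[0]`` and ``indegree_range[1]``
    incoming edges from distinct other nodes (no self edges), the total edge
    count is exact, and weights are i.i.d. normal with sd ``weight_sd``.
    Networks whose reciprocal condition number falls below 1e-10 are
    rejected and regenerated with an incremented seed.
    """
    spec = spec or SimNetworkSpec()
    lo, hi = spec.indegree_range
    for attempt in range(_MAX_RESAMPLE):
        rng = np.random.default_rng(seed + attempt)
        indeg = np.full(spec.p, lo)
        extra = spec.total_edges - lo * spec.p
        capacity = np.full(spec.p, hi - lo)
        while extra > 0:
            candidates = np.nonzero(capacity > 0)[0]
            node = rng.choice(candidates)
            indeg[node] += 1
            capacity[node] -= 1
            extra -= 1
        W = np.zeros((spec.p, spec.p))
        for i in range(spec.p):
            others = np.delete(np.arange(spec.p), i)
            regs = rng.choice(others, size=indeg[i], replace=False)
            W[i, regs] = rng.normal(0.0, spec.weight_sd, size=indeg[i])
        sv = np.linalg.svd(W, compute_uv=False)
        if sv[-1] > 0 and sv[-1] / sv[0] >= _RCOND_MIN:
            names = [f"g{i}" for i in range(spec.p)]
            return GeneNetwork(W=W, gene_names=names, model_kind="markov")
    raise RuntimeError("failed to generate a well-conditioned network")


def generate_markov_observation(
    net: GeneNetwork,
    k_points: int = 4,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One noisy time series ``x^1 .. x^{k_points}`` (shape p x k_points).

    The final latent state ``y^{k_points}`` is standard normal; earlier
    latent states follow the backward recursion ``y^k = W^{-1} y^{k+1}`` so
    the clean series satisfies the forward relation ``y^{k+1} = W y^k``
    exactly. Reported values add intrinsic noise (every backward step) and
    extrinsic noise (every time point).
    """
    noise = noise or NoiseSpec()
    if k_points < 2:
        raise ValueError("need at least 2 time points")
    p = net.n_genes
    sv = np.linalg.svd(net.W, compute_uv=False)
    if sv[-1] <= 0 or sv[-1] / sv[0] < _RCOND_MIN:
        raise ValueError("network matrix is singular; backward recursion undefined")
    rng = np.random.default_rng(seed)
    Winv = np.linalg.inv(net.W)
    y = np.empty((p, k_points))
    x = np.empty((p, k_points))
    y[:, -1] = rng.standard_normal(p)
    x[:, -1] = y[:, -1] + rng.normal(0.0, noise.extrinsic_sd, p) if noise.extrinsic_sd > 0 else y[:, -1]
    for k in range(k_points - 2, -1, -1):
        y[:, k] = Winv @ y[:, k + 1]
        xi = np.zeros(p)
        if noise.intrinsic_sd > 0:
            xi = rng.normal(0.0, noise.intrinsic_sd, p)
        xe = np.zeros(p)
        if noise.extrinsic_sd > 0:
            xe = rng.normal(0.0, noise.extrinsic_sd, p)
        x[:, k] = y[:, k] + xi + xe
    return x


def generate_observation_set(
    net: GeneNetwork,
    n_obs: int,
    k_points: int = 4,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> ObservationSet:
    """Bundle ``n_obs`` independent series into a time-series ObservationSet."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_obs)
    series = [
        generate_markov_observation(net, k_points=k_points, noise=noise, seed=int(s))
        for s in sub_seeds
    ]
    values = np.concatenate(series, axis=1)
    obs_ids = np.repeat(np.arange(1, n_obs + 1), k_points)
    time_points = np.tile(np.arange(1, k_points + 1), n_obs)
    return ObservationSet(
        values=values,
        mode="time_series",
        gene_names=list(net.gene_names),
        obs_ids=obs_ids,
        time_points=time_points,
    )


def generate_steady_state_observation(
    net: GeneNetwork,
    n_samples: int,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ObservationSet:
    """Convenience steady-state samples ``x = (I - W)^{-1} eps``.

    A reconstruction of steady-state benchmark data (each sample is the
    equilibrium response to a random perturbation ``eps ~ N(0, noise_sd^2)``);
    the residual of the steady-state regression on such a sample is exactly
    ``eps``. Not part of the time-series benchmark protocol.
    """
    p = net.n_genes
    A = np.eye(p) - net.W
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=(p, n_samples))
    values = np.linalg.solve(A, eps)
    return ObservationSet(
        values=values, mode="steady_state", gene_names=list(net.gene_names)
    )


def make_prior_matrix(
    net: GeneNetwork, n_valid: int, n_invalid: int, seed: int = 0
) -> PriorNetwork:
    """Prior with ``n_valid`` true edges and ``n_invalid`` non-edges exempted.

    Valid edges are sampled uniformly from the network's true (nonzero,
    off-diagonal) edges, invalid ones from the off-diagonal non-edges; the
    two sets are disjoint by construction.
    """
    p = net.n_genes
    offdiag = ~np.eye(p, dtype=bool)
    true_edges = np.argwhere((net.W != 0) & offdiag)
    non_edges = np.argwhere((net.W == 0) & offdiag)
    if not (0 <= n_valid <= len(true_edges)):
        raise ValueError(f"n_valid must be in [0, {len(true_edges)}]")
    if not (0 <= n_invalid <= len(non_edges)):
        raise ValueError(f"n_invalid must be in [0, {len(non_edges)}]")
    rng = np.random.default_rng(seed)
    w0 = np.ones((p, p), dtype=np.int8)
    if n_valid:
        pick = true_edges[rng.choice(len(true_edges), size=n_valid, replace=False)]
        w0[pick[:, 0], pick[:, 1]] = 0
    if n_invalid:
        pick = non_edges[rng.choice(len(non_edges), size=n_invalid, replace=False)]
        w0[pick[:, 0], pick[:, 1]] = 0
    return PriorNetwork(gene_names=list(net.gene_names), w0=w0)


def proportional_error(cv_error: float, ols_error: float) -> float:
    """Minimal CV error divided by the minimal unregularized in-sample error."""
    if ols_error <= 0:
        raise ValueError("least-squares baseline error must be positive")
    return float(cv_error) / float(ols_error)


@dataclass
class SweepResult:
    """Tidy per-replicate table plus condition-level summary of a sweep."""

    table: pd.DataFrame
    summary: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_tsv(self, table_path, summary_path=None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t", index=False)


def run_observation_sweep(
    n_obs_list,
    n_networks: int = 5,
    noise: NoiseSpec | None = None,
    net_spec: SimNetworkSpec | None = None,
    k_points: int = 4,
    grid_depth: int = 12,
    seed: int = 0,
) -> SweepResult:
    """Proportional error as a function of the number of observations.

    For each observation count, ``n_networks`` fresh networks and data sets
    are generated, the model is fit with leave-one-out CV (no prior), and
    the mean proportional error is recorded.
    """
    noise = noise or NoiseSpec()
    net_spec = net_spec or SimNetworkSpec()
    rows = []
    rng = np.random.default_rng(seed)
    for n_obs in n_obs_list:
        if n_obs < 2:
            raise ValueError("each observation count must be >= 2")
        for rep in range(n_networks):
            net_seed = int(rng.integers(0, 2**31 - 1))
            data_seed = int(rng.integers(0, 2**31 - 1))
            net = generate_random_network(net_spec, seed=net_seed)
            obs = generate_observation_set(net, n_obs, k_points, noise, seed=data_seed)
            _, fit = loo_cv_fit(obs, model_kind="markov", grid_depth=grid_depth)
            ols = float(np.sum(insample_ols_error(obs, "markov")))
            rows.append(
                {
                    "n_obs": n_obs,
                    "network": rep,
                    "net_seed": net_seed,
                    "data_seed": data_seed,
                    "cv_error": fit.total_cv_error,
                    "ols_error": ols,
                    "prop_error": proportional_error(fit.total_cv_error, ols),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("n_obs", as_index=False)
        .agg(mean_prop_error=("prop_error", "mean"), n_replicates=("prop_error", "size"))
    )
    return SweepResult(
        table=table,
        summary=summary,
        params={
            "n_obs_list": list(n_obs_list),
            "n_networks": n_networks,
            "k_points": k_points,
            "grid_depth": grid_depth,
            "intrinsic_sd": noise.intrinsic_sd,
            "extrinsic_sd": noise.extrinsic_sd,
            "seed": seed,
        },
    )


def run_prior_edge_sweep(
    valid_counts,
    invalid_counts,
    n_obs: int = 4,
    n_networks: int = 5,
    n_edge_sets: int = 5,
    noise: NoiseSpec | None = None,
    net_spec: SimNetworkSpec | None = None,
    k_points: int = 4,
    grid_depth: int = 12,
    seed: int = 0,
) -> SweepResult:
    """Proportional error over a factorial of valid/invalid prior-edge counts.

    The same ``n_networks`` networks and data sets are reused across the
    factorial; each (valid, invalid) cell draws ``n_edge_sets`` independent
    prior-edge samples per network. Covers the three benchmark designs:
    valid-only, invalid-only, and mixed priors.
    """
    noise = noise or NoiseSpec()
    net_spec = net_spec or SimNetworkSpec()
    rng = np.random.default_rng(seed)
    nets, obs_sets, ols_errors, net_seeds = [], [], [], []
    for rep in range(n_networks):
        net_seed = int(rng.integers(0, 2**31 - 1))
        data_seed = int(rng.integers(0, 2**31 - 1))
        net = generate_random_network(net_spec, seed=net_seed)
        obs = generate_observation_set(net, n_obs, k_points, noise, seed=data_seed)
        nets.append(net)
        obs_sets.append(obs)
        ols_errors.append(float(np.sum(insample_ols_error(obs, "markov"))))
        net_seeds.append(net_seed)
    rows = []
    for n_valid in valid_counts:
        for n_invalid in invalid_counts:
            for rep in range(n_networks):
                for es in range(n_edge_sets):
                    prior_seed = int(rng.integers(0, 2**31 - 1))
                    prior = make_prior_matrix(nets[rep], n_valid, n_invalid, seed=prior_seed)
                    _, fit = loo_cv_fit(
                        obs_sets[rep], prior=prior, model_kind="markov", grid_depth=grid_depth
                    )
                    rows.append(
                        {
                            "n_valid": n_valid,
                            "n_invalid": n_invalid,
                            "network": rep,
                            "edge_set": es,
                            "net_seed": net_seeds[rep],
                            "prior_seed": prior_seed,
                            "cv_error": fit.total_cv_error,
                            "ols_error": ols_errors[rep],
                            "prop_error": proportional_error(
                                fit.total_cv_error, ols_errors[rep]
                            ),
                        }
                    )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["n_valid", "n_invalid"], as_index=False)
        .agg(mean_prop_error=("prop_error", "mean"), n_replicates=("prop_error", "size"))
    )
    return SweepResult(
        table=table,
        summary=summary,
        params={
            "valid_counts": list(valid_counts),
            "invalid_counts": list(invalid_counts),
            "n_obs": n_obs,
            "n_networks": n_networks,
            "n_edge_sets": n_edge_sets,
            "k_points": k_points,
            "grid_depth": grid_depth,
            "intrinsic_sd": noise.intrinsic_sd,
            "extrinsic_sd": noise.extrinsic_sd,
            "seed": seed,
        },
    )
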