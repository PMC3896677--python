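"""Core data containers for network inference from heterogeneous embryo expression data.

The package works on a gene-by-sample expression matrix observed either at
(approximate) steady state or as short time series, a Boolean prior-interaction
matrix whose known edges are exempted from the prior penalty, and a weighted
directed gene interaction matrix ``W`` where ``W[i, j]`` is the signed influence
of gene ``j`` on gene ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODEL_KINDS = ("ode", "markov")
MODES = ("steady_state", "time_series")


def _as_bool_mask(mask, shape, name: str) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"{name} has shape {mask.shape}, expected {shape}")
    return mask


@dataclass
class ObservationSet:
    """Expression observations with knockout and missing-value annotations.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Nonnegative normalized expression, genes by samples. For time-series
        data the columns are individual time points; ``obs_ids`` and
        ``time_points`` assign each column to one observation (a complete
        series) and its time index ``1..k_max+1``.
    mode : {"steady_state", "time_series"}
    gene_names : list of str
        Unique identifiers for the ``p`` rows.
    knockout_mask : ndarray of bool, optional
        True where that gene is knocked down in that sample.
    missing_mask : ndarray of bool, optional
        True where the measurement is unavailable.
    obs_ids, time_points : ndarray of int, optional
        Required for ``time_series`` mode; every observation must contain the
        same number of time points, each time index exactly once.
    require_nonnegative : bool
        Enforce ``values >= 0`` (appropriate for normalized count data;
        simulated series may be signed).
    """

    values: np.ndarray
    mode: str
    gene_names: list[str]
    knockout_mask: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    obs_ids: np.ndarray | None = None
    time_points: np.ndarray | None = None
    require_nonnegative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene-by-sample matrix")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.gene_names = [str(g) for g in self.gene_names]
        p, n = self.values.shape
        if len(self.gene_names) != p:
            raise ValueError(f"{len(self.gene_names)} gene names for {p} rows")
        if len(set(self.gene_names)) != p:
            raise ValueError("gene_names must be unique")
        if self.require_nonnegative and np.any(self.values < 0):
            raise ValueError("negative expression values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        self.knockout_mask = _as_bool_mask(self.knockout_mask, (p, n), "knockout_mask")
        self.missing_mask = _as_bool_mask(self.missing_mask, (p, n), "missing_mask")
        if self.mode == "time_series":
            if self.obs_ids is None or self.time_points is None:
                raise ValueError("time_series mode requires obs_ids and time_points")
            self.obs_ids = np.asarray(self.obs_ids, dtype=int)
            self.time_points = np.asarray(self.time_points, dtype=int)
            if self.obs_ids.shape != (n,) or self.time_points.shape != (n,):
                raise ValueError("obs_ids/time_points must have one entry per column")
            k_sets = {}
            for o in np.unique(self.obs_ids):
                tps = np.sort(self.time_points[self.obs_ids == o])
                k_sets[int(o)] = tuple(tps)
            lengths = {len(t) for t in k_sets.values()}
            if len(lengths) != 1:
                raise ValueError("every observation must have the same number of time points")
            k = lengths.pop()
            if k < 2:
                raise ValueError("time-series observations need at least 2 time points")
            for o, tps in k_sets.items():
                if tps != tuple(range(1, k + 1)):
                    raise ValueError(
                        f"observation {o} has time points {tps}, expected 1..{k}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_observations(self) -> int:
        """Number of leave-out units: samples (steady state) or series."""
        if self.mode == "steady_state":
            return self.n_samples
        return len(np.unique(self.obs_ids))

    @property
    def k_points(self) -> int | None:
        """Time points per observation (``k_max + 1``), time-series only."""
        if self.mode != "time_series":
            return None
        o = np.unique(self.obs_ids)[0]
        return int(np.sum(self.obs_ids == o))

    def observation_columns(self, obs_id: int) -> np.ndarray:
        """Column indices of one observation, ordered by time index."""
        if self.mode == "steady_state":
            return np.asarray([obs_id])
        cols = np.nonzero(self.obs_ids == obs_id)[0]
        return cols[np.argsort(self.time_points[cols])]

    def observation_ids(self) -> np.ndarray:
        if self.mode == "steady_state":
            return np.arange(self.n_samples)
        return np.unique(self.obs_ids)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None


@dataclass
class PriorNetwork:
    """Boolean penalty-exemption matrix.

    ``w0[i, j] == 0`` marks a known directed interaction from gene ``j`` to
    gene ``i`` whose coefficient is exempt from the prior penalty ``beta``;
    all other entries are 1 (penalized).
    """

    gene_names: list[str]
    w0: np.ndarray

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        self.w0 = np.asarray(self.w0)
        p = len(self.gene_names)
        if self.w0.shape != (p, p):
            raise ValueError(f"w0 has shape {self.w0.shape}, expected ({p}, {p})")
        if not np.isin(self.w0, (0, 1)).all():
            raise ValueError("w0 entries must be 0 or 1")
        self.w0 = self.w0.astype(np.int8)

    @classmethod
    def all_penalized(cls, gene_names) -> "PriorNetwork":
        """A prior with no known edges (every coefficient penalized)."""
        p = len(gene_names)
        return cls(list(gene_names), np.ones((p, p), dtype=np.int8))

    @classmethod
    def from_edges(cls, edges, gene_names) -> "PriorNetwork":
        """Build from (regulator, target) name pairs."""
        gene_names = [str(g) for g in gene_names]
        idx = {g: i for i, g in enumerate(gene_names)}
        p = len(gene_names)
        w0 = np.ones((p, p), dtype=np.int8)
        for reg, tgt in edges:
            if reg not in idx:
                raise KeyError(f"unknown regulator {reg!r}")
            if tgt not in idx:
                raise KeyError(f"unknown target {tgt!r}")
            w0[idx[tgt], idx[reg]] = 0
        return cls(gene_names, w0)

    @property
    def edge_list(self) -> list[tuple[str, str]]:
        """(regulator, target) pairs of the exempt (known) interactions."""
        tgt_idx, reg_idx = np.nonzero(self.w0 == 0)
        return [(self.gene_names[j], self.gene_names[i]) for i, j in zip(tgt_idx, reg_idx)]

    @property
    def n_edges(self) -> int:
        return int(np.sum(self.w0 == 0))


@dataclass
class GeneNetwork:
    """Weighted directed interaction matrix with gene labels.

    ``W[i, j]`` is the signed influence of gene ``j`` on gene ``i``. For the
    steady-state ODE convention the self-decay term is absorbed into the model
    and the diagonal is fixed at zero; Markov networks have a free diagonal.
    """

    W: np.ndarray
    gene_names: list[str]
    model_kind: str

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        p = len(self.gene_names)
        if self.W.shape != (p, p):
            raise ValueError(f"W has shape {self.W.shape}, expected ({p}, {p})")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite interaction weights")
        if self.model_kind == "ode" and np.any(np.diag(self.W) != 0):
            raise ValueError("ode networks must have a zero diagonal")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}") from None


@dataclass
class DesignMatrices:
    """Per-gene quadratic forms and the cross matrix of the unified objective.

    ``D[i]`` is the p-by-p PSD matrix of the quadratic term for target gene
    ``i`` and ``U[:, i]`` the linear term, so each row of ``W`` solves
    ``min_w  w D[i] w' - 2 w . U[:, i] + sum_j lambda_j |w_j|``.
    """

    D: list[np.ndarray]
    U: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        p = self.U.shape[0]
        if self.U.shape != (p, p):
            raise ValueError("U must be square")
        if len(self.D) != p:
            raise ValueError("need one D matrix per gene")
        self.D = [np.asarray(d, dtype=float) for d in self.D]
        for i, d in enumerate(self.D):
            if d.shape != (p, p):
                raise ValueError(f"D[{i}] has shape {d.shape}, expected ({p}, {p})")
            if not np.allclose(d, d.T, atol=1e-8):
                raise ValueError(f"D[{i}] is not symmetric")

    @property
    def n_genes(self) -> int:
        return self.U.shape[0]


@dataclass
class RegularizationFit:
    """Per-gene regularization parameters chosen by leave-one-out CV."""

    alphas: np.ndarray
    betas: np.ndarray
    cv_errors: np.ndarray
    grid_alphas: np.ndarray
    grid_betas: np.ndarray
    grid_depth: int

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        self.cv_errors = np.asarray(self.cv_errors, dtype=float)
        if np.any(self.alphas < 0) or np.any(self.betas < 0):
            raise ValueError("regularization parameters must be nonnegative")
        if not np.all(np.isfinite(self.cv_errors)):
            raise ValueError("non-finite CV error")

    @property
    def total_cv_error(self) -> float:
        """Sum over genes of the per-gene held-out squared error."""
        return float(np.sum(self.cv_errors))

    @property
    def mean_cv_error(self) -> float:
        return float(np.mean(self.cv_errors))


@dataclass
class ClassifierConfig:
    """Spatial-pattern classifier levels and threshold.

    ``low``/``medium``/``high`` are the canonical region expression levels for
    the five dorsal-ventral categories; ``th`` is the single threshold of the
    rule cascade.
    """

    th: float = 0.5
    low: float = 0.1
    medium: float = 0.4
    high: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.medium < self.high):
            raise ValueError("need 0 < low < medium < high")
        if not (0 < self.th < 1):
            raise ValueError("th must be in (0, 1)")


@dataclass
class NoiseSpec:
    """Noise magnitudes for the synthetic time-series generator.

    ``intrinsic_sd`` models stochastic fluctuation of the underlying process
    and is added at every backward-recursion step; ``extrinsic_sd`` models
    measurement error and is added to every reported time point.
    """

    intrinsic_sd: float = 0.1
    extrinsic_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.intrinsic_sd < 0 or self.extrinsic_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


@dataclass
class SimNetworkSpec:
    """Shape of a random sparse directed benchmark network."""

    p: int = 10
    total_edges: int = 25
    indegree_range: tuple[int, int] = (2, 3)
    weight_sd: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.indegree_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid indegree_range")
        if hi > self.p - 1:
            raise ValueError("in-degree cannot exceed p - 1 (no self edges)")
        if not (lo * self.p <= self.total_edges <= hi * self.p):
            raise ValueError(
                f"total_edges={self.total_edges} infeasible for p={self.p} "
                f"with in-degrees in {self.indegree_range}"
            )


@dataclass
class KnockoutSpec:
    """Persistent complete knockout for forward simulation."""

    knocked_genes: tuple[str, ...] = ()
    mode: str = "ode"
    t_end: float = 10.0
    dt: float = 0.01
    n_steps: int = 10
    fold_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.mode not in MODEL_KINDS:
            raise ValueError(f"mode must be one of {MODEL_KINDS}")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        self.knocked_genes = tuple(self.knocked_genes)


def permute_off_diagonal(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly shuffle the off-diagonal entries of ``W``, keeping the diagonal."""
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    out = W.copy()
    mask = ~np.eye(p, dtype=bool)
    vals = out[mask]
    out[mask] = rng.permutation(vals)
    return out
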