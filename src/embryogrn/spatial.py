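"""Dorsal-ventral spatial expression pattern prediction and evaluation.

The embryo's dorsal-ventral axis is abstracted as a 1-D interval split into
three regions — left (ventral), middle (vegetal) and right (dorsal). Each
gene's pattern falls into one of five categories (d, v, b, m, u) with
canonical low/medium/high region values. Given an inferred interaction
matrix and patterns for a subset of genes, the remaining genes' region
values are predicted by nonnegative least squares:

* steady state: minimize ``sum_i (x_i - sum_{j != i} W_ij x_j)^2`` per
  region with known genes fixed at their canonical values and free genes
  constrained nonnegative;
* Markov: the time-2 pattern is the nonnegative image ``max(0, W x^1)`` of
  a time-1 pattern whose unknown entries are drawn at random and averaged
  over many runs.

Predicted region triples are mapped back to categories by a fixed rule
cascade on the pairwise region differences, and prediction quality is
scored by leave-one-out or random-subset evaluation, with significance
against networks whose off-diagonal weights are randomly rearranged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import ClassifierConfig, GeneNetwork, permute_off_diagonal

CATEGORIES = ("d", "v", "b", "m", "u")
NO_PATTERN = "none"
REGIONS = ("l", "m", "r")

_DEFAULT_CFG = ClassifierConfig()


def pattern_to_values(category: str, cfg: ClassifierConfig | None = None) -> tuple[float, float, float]:
    """Canonical (left, middle, right) region values for a category.

    d -> (low, medium, high), v -> (high, medium, low), b -> (high, low,
    high), m -> (low, high, low), u -> (medium, medium, medium).
    """
    cfg = cfg or _DEFAULT_CFG
    lo, me, hi = cfg.low, cfg.medium, cfg.high
    table = {
        "d": (lo, me, hi),
        "v": (hi, me, lo),
        "b": (hi, lo, hi),
        "m": (lo, hi, lo),
        "u": (me, me, me),
    }
    try:
        return table[category]
    except KeyError:
        raise ValueError(f"unknown pattern category {category!r}") from None


def classify_pattern(l: float, m: float, r: float, cfg: ClassifierConfig | None = None) -> str:
    """Assign a category to a (left, middle, right) value triple.

    The cascade works on the absolute region differences. With ``mn`` and
    ``mx`` the smallest and largest of |l-m|, |m-r|, |l-r|:

    1. uniform if ``mn/mx >= th`` or ``mx < low``;
    2. both if the middle is the smallest region and |l-r| is at most
       ``th`` of both |m-r| and |l-m| (a zero denominator counts as
       satisfied only when |l-r| is also zero);
    3. vegetal if the middle is strictly largest;
    4. ventral if the left is strictly largest;
    5. dorsal if the right is strictly largest;

    otherwise the sentinel ``"none"`` (not one of the five patterns).
    """
    cfg = cfg or _DEFAULT_CFG
    for name, v in (("l", l), ("m", m), ("r", r)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"region value {name} must be finite and nonnegative")
    dlm, dmr, dlr = abs(l - m), abs(m - r), abs(l - r)
    mx = max(dlm, dmr, dlr)
    mn = min(dlm, dmr, dlr)
    if mx < cfg.low or (mx > 0 and mn / mx >= cfg.th):
        return "u"

    def ratio_ok(num, den):
        if den == 0:
            return num == 0
        return num / den <= cfg.th

    if m < l and m < r and ratio_ok(dlr, dmr) and ratio_ok(dlr, dlm):
        return "b"
    if m > l and m > r:
        return "m"
    if l > m and l > r:
        return "v"
    if r > m and r > l:
        return "d"
    return NO_PATTERN


def _values_frame(values: np.ndarray, gene_names, cfg) -> pd.DataFrame:
    df = pd.DataFrame(values, index=list(gene_names), columns=list(REGIONS))
    df["predicted_category"] = [
        classify_pattern(row[0], row[1], row[2], cfg) for row in values
    ]
    return df


def ode_spatial_predict(
    net: GeneNetwork,
    known: dict[str, str],
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Steady-state spatial prediction with known patterns as constraints.

    Each of the three regions is an independent nonnegative least-squares
    problem ``min ||(I - W) x||^2`` with ``x_k`` fixed to the canonical
    value of gene ``k``'s category for known genes and ``x_i >= 0`` free
    otherwise. Returns a DataFrame of region values and the classified
    category for every gene.
    """
    cfg = cfg or _DEFAULT_CFG
    p = net.n_genes
    idx = {g: i for i, g in enumerate(net.gene_names)}
    for g in known:
        if g not in idx:
            raise KeyError(f"unknown gene {g!r}")
    fixed = np.asarray(sorted(idx[g] for g in known), dtype=int)
    free = np.asarray([i for i in range(p) if i not in set(fixed)], dtype=int)
    A = np.eye(p) - (net.W - np.diag(np.diag(net.W)))
    values = np.zeros((p, 3))
    triples = {g: pattern_to_values(c, cfg) for g, c in known.items()}
    for pos in range(3):
        y_fixed = np.asarray([triples[net.gene_names[i]][pos] for i in fixed])
        values[fixed, pos] = y_fixed
        if free.size:
            b = -A[:, fixed] @ y_fixed if fixed.size else np.zeros(p)
            sol, _ = nnls(A[:, free], b)
            values[free, pos] = sol
    return _values_frame(values, net.gene_names, cfg)


def markov_spatial_predict(
    net: GeneNetwork,
    known_t1: dict[str, str],
    n_runs: int = 1000,
    seed: int = 0,
    cfg: ClassifierConfig | None = None,
    init: str = "uniform",
) -> pd.DataFrame:
    """Time-2 spatial prediction from partial time-1 patterns.

    Per run, time-1 values are the canonical triples for the known genes
    and random values for the rest (``init="uniform"``: i.i.d. uniform(0,1)
    per region; ``init="categorical"``: a random canonical category per
    gene). The time-2 value is the nonnegative minimizer of the Markov
    residual, i.e. elementwise ``max(0, W x^1)``; runs are averaged and the
    mean triple classified.
    """
    cfg = cfg or _DEFAULT_CFG
    if not known_t1:
        raise ValueError("need at least one known time-1 pattern")
    if init not in ("uniform", "categorical"):
        raise ValueError("init must be 'uniform' or 'categorical'")
    p = net.n_genes
    idx = {g: i for i, g in enumerate(net.gene_names)}
    for g in known_t1:
        if g not in idx:
            raise KeyError(f"unknown gene {g!r}")
    fixed = np.asarray(sorted(idx[g] for g in known_t1), dtype=int)
    free = np.asarray([i for i in range(p) if i not in set(fixed)], dtype=int)
    x1 = np.zeros((p, 3))
    for g, c in known_t1.items():
        x1[idx[g]] = pattern_to_values(c, cfg)
    rng = np.random.default_rng(seed)
    total = np.zeros((p, 3))
    runs = n_runs if free.size else 1
    for _ in range(runs):
        if free.size:
            if init == "uniform":
                x1[free] = rng.uniform(0.0, 1.0, size=(free.size, 3))
            else:
                cats = rng.choice(CATEGORIES, size=free.size)
                x1[free] = [pattern_to_values(c, cfg) for c in cats]
        total += np.clip(net.W @ x1, 0.0, None)
    return _values_frame(total / runs, net.gene_names, cfg)


def loo_spatial_eval_ode(
    net: GeneNetwork,
    patterns: dict[str, str],
    cfg: ClassifierConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out evaluation of the steady-state spatial model.

    Each annotated gene in turn is held out, the others constrain the
    prediction, and the held-out gene's classified pattern is compared to
    its annotation. Returns the fraction correct and the per-gene calls
    (the sentinel "none" counts as incorrect).
    """
    cfg = cfg or _DEFAULT_CFG
    genes = sorted(patterns)
    if len(genes) < 2:
        raise ValueError("need at least 2 annotated genes")
    rows = []
    for g in genes:
        constraints = {h: patterns[h] for h in genes if h != g}
        pred = ode_spatial_predict(net, constraints, cfg)
        call = pred.loc[g, "predicted_category"]
        rows.append({"gene": g, "annotated": patterns[g], "predicted": call,
                     "correct": call == patterns[g]})
    calls = pd.DataFrame(rows)
    return float(calls["correct"].mean()), calls


def markov_spatial_eval(
    net: GeneNetwork,
    patterns: dict[str, str],
    t1_genes,
    n_runs: int = 1000,
    seed: int = 0,
    cfg: ClassifierConfig | None = None,
    init: str = "uniform",
) -> tuple[float, pd.DataFrame]:
    """Score time-2 predictions from a few time-1 patterns against annotations.

    ``t1_genes`` are fixed at time 1 to their annotated categories; all
    annotated genes (including the time-1 seeds) are scored at time 2.
    """
    known_t1 = {}
    for g in t1_genes:
        if g not in patterns:
            raise KeyError(f"time-1 gene {g!r} has no annotated pattern")
        known_t1[g] = patterns[g]
    pred = markov_spatial_predict(net, known_t1, n_runs=n_runs, seed=seed, cfg=cfg, init=init)
    rows = []
    for g in sorted(patterns):
        call = pred.loc[g, "predicted_category"]
        rows.append({"gene": g, "annotated": patterns[g], "predicted": call,
                     "correct": call == patterns[g]})
    calls = pd.DataFrame(rows)
    return float(calls["correct"].mean()), calls


def subset_sweep_eval(
    net: GeneNetwork,
    patterns: dict[str, str],
    subset_sizes,
    n_sets: int = 20,
    seed: int = 0,
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Mean percent-correct of the steady-state model vs constraint-set size.

    For each size, ``n_sets`` random subsets of annotated genes constrain
    the prediction and the remaining annotated genes are scored.
    """
    cfg = cfg or _DEFAULT_CFG
    genes = sorted(patterns)
    n = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for size in subset_sizes:
        if not (1 <= size < n):
            raise ValueError(f"subset size {size} must be in [1, {n - 1}]")
        pcts = []
        for _ in range(n_sets):
            chosen = rng.choice(genes, size=size, replace=False)
            constraints = {g: patterns[g] for g in chosen}
            held = [g for g in genes if g not in constraints]
            pred = ode_spatial_predict(net, constraints, cfg)
            correct = sum(pred.loc[g, "predicted_category"] == patterns[g] for g in held)
            pcts.append(100.0 * correct / len(held))
        rows.append({"subset_size": size, "mean_pct_correct": float(np.mean(pcts)),
                     "n_sets": n_sets})
    return pd.DataFrame(rows)


def spatial_permutation_test(
    net: GeneNetwork,
    patterns: dict[str, str],
    model: str = "ode",
    t1_genes=None,
    n_perm: int = 1000,
    n_runs: int = 100,
    seed: int = 0,
    cfg: ClassifierConfig | None = None,
) -> tuple[np.ndarray, float, float]:
    """Significance of spatial prediction vs rearranged-network nulls.

    Each null network shuffles the off-diagonal entries of ``W`` (diagonal
    preserved) and is pushed through the same prediction + classification
    pipeline. Returns (null fractions, observed fraction, p-value) with the
    add-one permutation p-value ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or _DEFAULT_CFG
    rng = np.random.default_rng(seed)

    def evaluate(network, eval_seed):
        if model == "ode":
            frac, _ = loo_spatial_eval_ode(network, patterns, cfg)
        elif model == "markov":
            if not t1_genes:
                raise ValueError("markov permutation test needs t1_genes")
            frac, _ = markov_spatial_eval(
                network, patterns, t1_genes, n_runs=n_runs, seed=eval_seed, cfg=cfg
            )
        else:
            raise ValueError("model must be 'ode' or 'markov'")
        return frac

    observed = evaluate(net, int(rng.integers(0, 2**31 - 1)))
    nulls = np.empty(n_perm)
    for t in range(n_perm):
        Wp = permute_off_diagonal(net.W, rng)
        null_net = GeneNetwork(W=Wp, gene_names=list(net.gene_names), model_kind=net.model_kind)
        nulls[t] = evaluate(null_net, int(rng.integers(0, 2**31 - 1)))
    p_value = (1 + int(np.sum(nulls >= observed))) / (n_perm + 1)
    return nulls, observed, p_value


def random_assignment_accuracy(
    patterns: dict[str, str],
    n_draws: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance-level accuracy of assigning categories uniformly at random.

    Returns (analytic, simulated) expected fraction correct; assigning one
    of the five categories uniformly per gene is correct with probability
    1/5 regardless of the annotation mix.
    """
    genes = sorted(patterns)
    analytic = 1.0 / len(CATEGORIES)
    rng = np.random.default_rng(seed)
    draws = rng.choice(CATEGORIES, size=(n_draws, len(genes)))
    truth = np.asarray([patterns[g] for g in genes])
    simulated = float(np.mean(draws == truth[None, :]))
    return analytic, simulated
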