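"""Readers and writers for the plain-TSV formats, plus a fixture generator.

Formats
-------
Expression TSV
    First column ``gene``, remaining columns sample ids; missing values as
    ``NA``. A companion sample sheet carries columns ``sample_id``,
    ``condition`` (``wt`` or ``<gene>_MO``), ``time_index`` and
    ``observation_id``.
Prior TSV
    Two columns ``regulator``, ``target`` (directed).
Pattern TSV
    Columns ``gene``, ``category`` (d/v/b/m/u, or NA when unannotated).
Network TSV
    Full weight matrix with gene labels on both axes; edge lists as
    ``regulator  target  weight`` TSV or SIF.

All readers reject malformed input with descriptive errors rather than
coercing; all writers round-trip through their readers losslessly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneNetwork, NoiseSpec, ObservationSet, PriorNetwork, SimNetworkSpec
from .spatial import CATEGORIES

SHEET_COLUMNS = ("sample_id", "condition", "time_index", "observation_id")


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kw)


def read_expression(expr_path, sample_sheet_path, mode: str) -> ObservationSet:
    """Load an expression matrix plus sample sheet into an ObservationSet.

    The sheet's ``condition`` column names the knocked-down gene
    (``<gene>_MO``) or ``wt``; ``NA`` expression cells set the missing mask.
    """
    expr = _read_tsv(expr_path, index_col=0)
    try:
        values = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {expr_path}: {exc}") from exc
    sheet = _read_tsv(sample_sheet_path)
    missing_cols = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise ValueError(f"sample sheet lacks column(s): {', '.join(missing_cols)}")
    sheet = sheet.set_index("sample_id")
    expr_samples = list(values.columns)
    if set(expr_samples) != set(map(str, sheet.index.astype(str))):
        raise ValueError("expression columns and sample sheet sample_ids do not match")
    sheet.index = sheet.index.astype(str)
    sheet = sheet.loc[expr_samples]

    gene_names = [str(g) for g in values.index]
    mat = values.to_numpy(dtype=float)
    missing = np.isnan(mat)
    mat = np.nan_to_num(mat, nan=0.0)

    p, n = mat.shape
    ko = np.zeros((p, n), dtype=bool)
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    for col, (sid, row) in enumerate(sheet.iterrows()):
        cond = str(row["condition"])
        if cond == "wt":
            continue
        if not cond.endswith("_MO"):
            raise ValueError(
                f"sample {sid!r}: condition must be 'wt' or '<gene>_MO', got {cond!r}"
            )
        gene = cond[: -len("_MO")]
        if gene not in gene_idx:
            raise ValueError(f"sample {sid!r}: unknown knocked-down gene {gene!r}")
        ko[gene_idx[gene], col] = True

    kwargs = {}
    if mode == "time_series":
        kwargs["obs_ids"] = sheet["observation_id"].to_numpy(dtype=int)
        kwargs["time_points"] = sheet["time_index"].to_numpy(dtype=int)
    return ObservationSet(
        values=mat,
        mode=mode,
        gene_names=gene_names,
        knockout_mask=ko,
        missing_mask=missing,
        require_nonnegative=False,
        **kwargs,
    )


def write_expression(obs: ObservationSet, expr_path, sample_sheet_path) -> None:
    """Write an ObservationSet back to expression TSV + sample sheet."""
    n = obs.n_samples
    if obs.mode == "time_series":
        sample_ids = [
            f"s{int(o)}_{int(t)}" for o, t in zip(obs.obs_ids, obs.time_points)
        ]
        time_index = obs.time_points
        observation_id = obs.obs_ids
    else:
        sample_ids = [f"s{k + 1}" for k in range(n)]
        time_index = np.ones(n, dtype=int)
        observation_id = np.arange(1, n + 1)
    vals = obs.values.astype(object).copy()
    vals[obs.missing_mask] = np.nan
    df = pd.DataFrame(vals, index=obs.gene_names, columns=sample_ids)
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t", na_rep="NA")

    conditions = []
    for col in range(n):
        knocked = np.nonzero(obs.knockout_mask[:, col])[0]
        if knocked.size == 0:
            conditions.append("wt")
        elif knocked.size == 1:
            conditions.append(f"{obs.gene_names[knocked[0]]}_MO")
        else:
            raise ValueError(
                "sample sheet format encodes at most one knocked gene per sample"
            )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": conditions,
            "time_index": time_index,
            "observation_id": observation_id,
        }
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_prior(path, gene_names) -> PriorNetwork:
    """Load a directed (regulator, target) edge list as a PriorNetwork."""
    df = _read_tsv(path)
    for col in ("regulator", "target"):
        if col not in df.columns:
            raise ValueError(f"prior file lacks column {col!r}")
    edges = list(zip(df["regulator"].astype(str), df["target"].astype(str)))
    seen = set()
    unique = []
    for e in edges:
        if e in seen:
            warnings.warn(f"duplicate prior edge {e[0]} -> {e[1]} collapsed", stacklevel=2)
            continue
        seen.add(e)
        unique.append(e)
    return PriorNetwork.from_edges(unique, gene_names)


def write_prior(prior: PriorNetwork, path) -> None:
    pd.DataFrame(prior.edge_list, columns=["regulator", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_patterns(path) -> tuple[dict[str, str], list[str]]:
    """Load gene -> category annotations.

    Returns (annotated patterns, all gene names); ``NA`` categories mark
    unannotated genes and unknown categories are rejected.
    """
    df = _read_tsv(path)
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"pattern file lacks column {col!r}")
    genes = [str(g) for g in df["gene"]]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in pattern file")
    patterns = {}
    for g, c in zip(genes, df["category"]):
        if pd.isna(c):
            continue
        c = str(c)
        if c not in CATEGORIES:
            raise ValueError(f"gene {g!r}: unknown category {c!r}")
        patterns[g] = c
    return patterns, genes


def write_patterns(patterns: dict[str, str], genes, path) -> None:
    rows = [{"gene": g, "category": patterns.get(g, np.nan)} for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_network(net: GeneNetwork, path) -> None:
    """Write the full weight matrix with gene labels."""
    df = pd.DataFrame(net.W, index=net.gene_names, columns=net.gene_names)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_network(path, model_kind: str) -> GeneNetwork:
    df = _read_tsv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("network matrix must have identical row and column labels")
    return GeneNetwork(
        W=df.to_numpy(dtype=float),
        gene_names=[str(g) for g in df.index],
        model_kind=model_kind,
    )


def write_edges(edges, path, fmt: str = "tsv") -> None:
    """Write an edge list as TSV (regulator, target, weight) or SIF."""
    path = Path(path)
    if fmt == "tsv":
        pd.DataFrame(edges, columns=["regulator", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for reg, tgt, w in edges:
                rel = "activates" if w > 0 else "represses"
                fh.write(f"{reg}\t{rel}\t{tgt}\n")
    else:
        raise ValueError("fmt must be 'tsv' or 'sif'")


def read_edges(path) -> list[tuple[str, str, float]]:
    df = _read_tsv(path)
    for col in ("regulator", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"edge file lacks column {col!r}")
    return [
        (str(r), str(t), float(w))
        for r, t, w in zip(df["regulator"], df["target"], df["weight"])
    ]


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Emit a small self-consistent demo world for end-to-end runs.

    An 8-gene random network, 6 low-noise 4-point time series simulated
    from it, a prior exempting 6 of its true edges, random category
    annotations for all genes, and a manifest — sized so the full
    infer -> threshold -> spatial -> permutation pipeline runs in seconds.
    """
    from .simulation import generate_observation_set, generate_random_network, make_prior_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = SimNetworkSpec(p=8, total_edges=18, indegree_range=(2, 3), weight_sd=10.0)
    # backward-recursion series carry weak early-time signal, so the demo
    # world keeps noise well below it to stay recoverable
    noise = NoiseSpec(intrinsic_sd=0.001, extrinsic_sd=0.001)
    net = generate_random_network(spec, seed=int(rng.integers(0, 2**31 - 1)))
    obs = generate_observation_set(
        net, n_obs=6, k_points=4, noise=noise, seed=int(rng.integers(0, 2**31 - 1))
    )
    prior = make_prior_matrix(net, n_valid=6, n_invalid=0, seed=int(rng.integers(0, 2**31 - 1)))
    patterns = {g: str(c) for g, c in zip(net.gene_names, rng.choice(CATEGORIES, size=net.n_genes))}

    paths = {
        "expression": out_dir / "expression.tsv",
        "samples": out_dir / "samples.tsv",
        "truth_network": out_dir / "truth_network.tsv",
        "prior": out_dir / "prior.tsv",
        "patterns": out_dir / "patterns.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_expression(obs, paths["expression"], paths["samples"])
    write_network(net, paths["truth_network"])
    write_prior(prior, paths["prior"])
    write_patterns(patterns, net.gene_names, paths["patterns"])
    manifest = {
        "seed": seed,
        "p": spec.p,
        "total_edges": spec.total_edges,
        "n_obs": 6,
        "k_points": 4,
        "intrinsic_sd": noise.intrinsic_sd,
        "extrinsic_sd": noise.extrinsic_sd,
        "n_valid_prior": 6,
        "normalize": False,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
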