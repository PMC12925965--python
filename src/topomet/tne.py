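"""Topological node enrichment (TNE) and node-level correlation inference.

TNE turns per-sample variables into per-node values on the TCN scaffold:
the arithmetic mean over a node's samples for numeric variables, and the
within-node fraction of samples carrying a label for categorical ones.
Condition metadata (treatment @ timepoint) is expanded to one indicator per
condition before enrichment, so categorical states become [0, 1]-valued
node variables that ordinary rank statistics can handle.

Node-level association is measured with Spearman's rank correlation
(average-rank ties, two-sided p via the t approximation with n = number of
nodes). Because the force of contraction is metadata and never enters the
Mapper construction, the sample-level Spearman of each metabolite with FoC
is an independent ground truth against which the node-level coefficients
can be benchmarked per block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnnotatedDataset
from .mapper import TCNGraph

__all__ = [
    "NodeValueMatrix",
    "CorrelationTable",
    "BenchmarkReport",
    "enrich_numeric",
    "enrich_categorical",
    "build_node_matrix",
    "spearman_nodes",
    "benchmark_against_ground_truth",
]


def enrich_numeric(graph: TCNGraph, variable: pd.Series) -> pd.Series:
    """Mean of a per-sample numeric variable within each node."""
    values = variable.astype(float)
    out = {}
    for n in graph.node_ids:
        samples = graph.samples_of(n)
        missing = [s for s in samples if s not in values.index or pd.isna(values[s])]
        if missing:
            raise ValueError(
                f"numeric enrichment requires complete metadata; "
                f"missing value for samples {missing}"
            )
        out[n] = float(np.mean([values[s] for s in samples]))
    return pd.Series(out, name=variable.name)


def enrich_categorical(
    graph: TCNGraph, labels: pd.Series, target_label: str
) -> pd.Series:
    """Fraction of each node's samples carrying ``target_label``."""
    known = sorted(set(labels.dropna().astype(str)))
    if target_label not in known:
        raise ValueError(
            f"unknown target label {target_label!r}; known labels: {known}"
        )
    out = {}
    for n in graph.node_ids:
        samples = graph.samples_of(n)
        missing = [s for s in samples if s not in labels.index or pd.isna(labels[s])]
        if missing:
            raise ValueError(f"missing label for samples {missing}")
        hits = sum(str(labels[s]) == target_label for s in samples)
        out[n] = hits / len(samples)
    return pd.Series(out, name=target_label)


@dataclass
class NodeValueMatrix:
    """Node x variable matrix: metabolite Z-score means, FoC mean, condition fractions."""

    values: pd.DataFrame  # index node_id, columns variables
    metabolites: list[str]
    targets: list[str]  # foc + condition indicator names


def build_node_matrix(graph: TCNGraph, dataset: AnnotatedDataset) -> NodeValueMatrix:
    """Enrich every metabolite, FoC and condition indicator onto the nodes."""
    Z = dataset.concat_values()
    cols: dict[str, pd.Series] = {}
    for m in Z.columns:
        cols[m] = enrich_numeric(graph, Z[m])
    cols["foc"] = enrich_numeric(graph, dataset.samples.numeric("foc"))
    conditions = dataset.samples.conditions
    for c in conditions:
        cols[c] = enrich_categorical(graph, dataset.samples.condition, c)
    df = pd.DataFrame(cols).loc[graph.node_ids]
    return NodeValueMatrix(
        values=df, metabolites=list(Z.columns), targets=["foc"] + conditions
    )


@dataclass
class CorrelationTable:
    """Metabolites x targets Spearman coefficients with two-sided p-values."""

    rho: pd.DataFrame
    pval: pd.DataFrame
    n_nodes: int
    degenerate: list[tuple[str, str]]  # (row, col) pairs with a zero-variance side

    @property
    def rows(self) -> list[str]:
        return list(self.rho.index)

    @property
    def cols(self) -> list[str]:
        return list(self.rho.columns)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0, 1.0, True
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(rho):
        return 0.0, 1.0, True
    return rho, min(max(p, np.nextafter(0, 1)), 1.0), False


def spearman_nodes(
    matrix: NodeValueMatrix,
    row_vars: Sequence[str] | None = None,
    col_vars: Sequence[str] | None = None,
) -> CorrelationTable:
    """Spearman rank correlation between node-value rows and targets.

    Requires at least 4 nodes; fewer make a rank correlation meaningless.
    Degenerate (zero-variance) pairs yield rho = 0, p = 1 and are flagged.
    """
    rows = list(row_vars) if row_vars is not None else list(matrix.metabolites)
    cols = list(col_vars) if col_vars is not None else list(matrix.targets)
    n = matrix.values.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 nodes for correlation inference, got {n}")
    rho = pd.DataFrame(index=rows, columns=cols, dtype=float)
    pval = pd.DataFrame(index=rows, columns=cols, dtype=float)
    degenerate: list[tuple[str, str]] = []
    for r in rows:
        x = matrix.values[r].to_numpy(dtype=float)
        for c in cols:
            y = matrix.values[c].to_numpy(dtype=float)
            rho.loc[r, c], pval.loc[r, c], bad = _spearman(x, y)
            if bad:
                degenerate.append((r, c))
    return CorrelationTable(rho=rho, pval=pval, n_nodes=n, degenerate=degenerate)


@dataclass
class BenchmarkReport:
    """Per-metabolite node-level vs sample-level Spearman with FoC, per block.

    ``scatter`` has columns metabolite, block, rho_ground_truth (sample
    level), rho_tne (node level); ``agreement`` maps block id to the Pearson
    correlation between the two coefficient vectors.
    """

    scatter: pd.DataFrame
    agreement: dict[str, float]
    target: str

    def write_csv(self, path: str | Path) -> None:
        self.scatter.to_csv(path, index=False)


def benchmark_against_ground_truth(
    graph: TCNGraph, dataset: AnnotatedDataset, numeric_target: str = "foc"
) -> BenchmarkReport:
    """Benchmark TNE-based correlations against the sample-level ground truth.

    For every metabolite, computes (i) the sample-level Spearman between its
    Z scores and the target and (ii) the node-level Spearman via TNE, and
    reports the per-block Pearson agreement between the coefficient vectors.
    """
    target = dataset.samples.numeric(numeric_target)
    target_nodes = enrich_numeric(graph, target)
    rows = []
    for b in dataset.blocks:
        for m in b.metabolite_ids:
            x = b.data[m].to_numpy(dtype=float)
            rho_gt, _, _ = _spearman(x, target.loc[b.sample_ids].to_numpy(dtype=float))
            nodes = enrich_numeric(graph, b.data[m])
            rho_tne, _, _ = _spearman(nodes.to_numpy(), target_nodes.to_numpy())
            rows.append(
                {
                    "metabolite": m,
                    "block": b.block_id,
                    "rho_ground_truth": rho_gt,
                    "rho_tne": rho_tne,
                }
            )
    scatter = pd.DataFrame(rows)
    agreement: dict[str, float] = {}
    for b in dataset.blocks:
        sub = scatter[scatter["block"] == b.block_id]
        gt = sub["rho_ground_truth"].to_numpy()
        tn = sub["rho_tne"].to_numpy()
        if np.array_equal(gt, tn):
            agreement[b.block_id] = 1.0
        elif np.std(gt) == 0.0 or np.std(tn) == 0.0:
            agreement[b.block_id] = float("nan")
        else:
            agreement[b.block_id] = float(stats.pearsonr(gt, tn).statistic)
    return BenchmarkReport(scatter=scatter, agreement=agreement, target=numeric_target)
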