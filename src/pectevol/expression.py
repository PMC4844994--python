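"""Expression normalization, high/tissue-specific calls, and divergence.

Two conventions are supported, matching how the two species' data arrive:
FPKM matrices scored with an absolute threshold (default >10) and
mean-normalized matrices (each gene divided by its row mean) scored against
a relative threshold (default >1). Hierarchical clustering runs on
log2(x+1)-transformed rows with 1 − Pearson correlation distance and
average linkage. Expression divergence between two homologs is the Jaccard
distance between their high-call tissue sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNITS = ("FPKM", "mean-normalized", "log2")
DEFAULT_THRESHOLDS = {"FPKM": 10.0, "mean-normalized": 1.0}


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes × tissues
    unit: str = "FPKM"
    flagged: list[str] = field(default_factory=list)  # all-zero genes

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("tissue names must be unique")
        if self.unit != "log2" and (self.values.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def read_expression(path: str | Path, unit: str = "FPKM") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def mean_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene row by its mean; all-zero rows pass through flagged."""
    values = matrix.values.astype(float)
    means = values.mean(axis=1)
    flagged = list(values.index[means <= 0])
    safe = means.replace(0, 1.0)
    safe[means <= 0] = 1.0
    out = values.div(safe, axis=0)
    return ExpressionMatrix(out, "mean-normalized", flagged)


@dataclass
class HighCalls:
    calls: pd.DataFrame  # boolean genes × tissues
    threshold: float
    unit: str

    def high_anywhere(self) -> pd.Series:
        return self.calls.any(axis=1)

    def specific_tissue(self) -> pd.Series:
        """Tissue name for genes high in exactly one tissue, else None."""
        n_high = self.calls.sum(axis=1)
        out = pd.Series([None] * len(self.calls), index=self.calls.index, dtype=object)
        only = self.calls.index[n_high == 1]
        out[only] = self.calls.loc[only].idxmax(axis=1)
        return out


def call_high_expression(
    matrix: ExpressionMatrix, threshold: float | None = None
) -> HighCalls:
    """Strict-inequality high-expression calls; threshold defaults by unit
    (FPKM > 10, mean-normalized > 1)."""
    if threshold is None:
        if matrix.unit not in DEFAULT_THRESHOLDS:
            raise ValueError(f"no default threshold for unit {matrix.unit!r}")
        threshold = DEFAULT_THRESHOLDS[matrix.unit]
    if matrix.unit == "log2":
        raise ValueError("high-expression calls need linear-scale values")
    return HighCalls(matrix.values > threshold, threshold, matrix.unit)


def cluster_expression(matrix: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering of genes.

    Rows are log2(x+1) transformed; distance is 1 − Pearson correlation
    across tissues. Zero-variance rows get distance 1 to everything
    (correlation undefined). Genes are sorted by id first so the linkage is
    input-order invariant; returns (leaf ordering, scipy linkage matrix).
    """
    if len(matrix.values) < 2:
        raise ValueError("need ≥2 genes to cluster")
    values = matrix.values.sort_index()
    data = np.log2(values.to_numpy(dtype=float) + 1.0)
    n = data.shape[0]
    sd = data.std(axis=1)
    dist = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        sub = data[ok]
        corr = np.corrcoef(sub)
        dist[np.ix_(ok, ok)] = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    link = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(link)
    names = list(values.index)
    return [names[i] for i in order], link


def dendrogram_newick(matrix: ExpressionMatrix) -> str:
    """Newick rendering of the expression dendrogram (merge heights as depths)."""
    values = matrix.values.sort_index()
    _, link = cluster_expression(matrix)
    tree = hierarchy.to_tree(link)
    names = list(values.index)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({render(left)}:{max(node.dist - left.dist, 0.0):.6g},"
            f"{render(right)}:{max(node.dist - right.dist, 0.0):.6g})"
        )

    return render(tree) + ";"


def expression_divergence(
    calls: HighCalls, gene_a: str, gene_b: str
) -> float:
    """Jaccard distance between the two genes' high-call tissue sets.

    Two genes high nowhere are maximally similar (distance 0).
    """
    a = set(calls.calls.columns[calls.calls.loc[gene_a]])
    b = set(calls.calls.columns[calls.calls.loc[gene_b]])
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def write_calls(calls: HighCalls, path: str | Path) -> None:
    out = calls.calls.astype(int)
    out["n_high"] = calls.calls.sum(axis=1)
    out["specific"] = calls.specific_tissue().fillna("-")
    out.to_csv(path, sep="\t")
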