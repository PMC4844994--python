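"""Nucleotide distances and neighbor-joining trees."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .kaks import NUCLEOTIDES, jukes_cantor


def jc69_distance(seq1: str, seq2: str) -> float:
    """Jukes–Cantor distance with pairwise deletion of gap/ambiguous columns.

    Returns NaN at or beyond saturation (p ≥ 0.75); raises when no column is
    comparable.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    compared = mismatches = 0
    for a, b in zip(seq1, seq2):
        if a in NUCLEOTIDES and b in NUCLEOTIDES:
            compared += 1
            if a != b:
                mismatches += 1
    if compared == 0:
        raise ValueError("zero comparable sites")
    return jukes_cantor(mismatches / compared)


def jc69_matrix(sequences: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """All-pairs JC69 distance matrix over a dict of aligned sequences."""
    names = list(sequences)
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jc69_distance(sequences[names[i]], sequences[names[j]])
    return dm, names


def nj_tree(distances: np.ndarray | Sequence[Sequence[float]], ids: Sequence[str]) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    The matrix must be symmetric (to 1e-9) with a zero diagonal and ≥3 taxa;
    negative branch-length estimates are clamped to zero.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("need ≥3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(d))) > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")
    tree = _skbio_nj(DistanceMatrix((d + d.T) / 2.0, ids=list(ids)), neg_as_zero=True)
    return str(tree).strip()


def tree_path_lengths(newick: str) -> dict[frozenset[str], float]:
    """Leaf-to-leaf path lengths of a Newick tree (topology-free comparison aid)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[frozenset[str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out
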