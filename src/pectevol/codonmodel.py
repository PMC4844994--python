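"""Goldman–Yang codon substitution models with branch-wise ω classes.

The instantaneous rate from codon *i* to *j* is zero for multi-nucleotide
changes and otherwise proportional to π_j, multiplied by κ for transitions
and by ω for nonsynonymous changes; each class's matrix is normalized to one
expected substitution per codon per unit branch length. Likelihoods are
computed by Felsenstein pruning over compressed site patterns with per-node
scaling, and κ, the ω of each branch class, and all branch lengths are
maximized jointly by quasi-Newton search on log-transformed parameters.
The one-ratio model gives every branch the same ω; the two-ratio model
gives labeled foreground branches their own ω, and the two are compared by
a χ² likelihood-ratio test with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .kaks import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS

N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

BACKGROUND = "background"
FOREGROUND = "foreground"

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _single_change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61,61) masks: single-nt change, transition, synonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = _is_transition(*diffs[0])
            synonymous[i, j] = CODON_TO_AA[ci] == CODON_TO_AA[cj]
    return single, transition, synonymous

_SINGLE, _TRANSITION, _SYNONYMOUS = _single_change_tables()


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class CodonAlignment:
    """Equal-length in-frame nucleotide sequences with unusable codon columns
    (gaps, ambiguity) already removed."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3 if self.sequences else 0

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def has_stops(self) -> bool:
        return any(
            s[i : i + 3] in STOP_CODONS
            for s in self.sequences.values()
            for i in range(0, len(s), 3)
        )


def make_codon_alignment(
    sequences: Mapping[str, str], mask_stops: bool = False
) -> CodonAlignment:
    """Build a codon alignment, masking codon columns with a gap or ambiguous
    base in any sequence (optionally also columns holding a stop codon)."""
    seqs = {k: v.upper() for k, v in sequences.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    length = lengths.pop()
    if length % 3:
        raise ValueError(f"alignment length {length} not divisible by 3")
    keep = []
    for i in range(0, length, 3):
        codons = [s[i : i + 3] for s in seqs.values()]
        if any(nt not in NUCLEOTIDES for c in codons for nt in c):
            continue
        if mask_stops and any(c in STOP_CODONS for c in codons):
            continue
        keep.append(i)
    return CodonAlignment(
        {k: "".join(s[i : i + 3] for i in keep) for k, s in seqs.items()}
    )


def f3x4_frequencies(alignment: CodonAlignment, floor: float = 1e-4) -> np.ndarray:
    """Codon equilibrium frequencies from positional nucleotide frequencies."""
    counts = np.zeros((3, 4))
    nt_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for seq in alignment.sequences.values():
        for i in range(0, len(seq), 3):
            for pos in range(3):
                counts[pos, nt_index[seq[i + pos]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, floor)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


# ---------------------------------------------------------------------------
# Rate matrix


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Normalized GY-style generator (mean rate one substitution per codon)."""
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be > 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi must be 61 nonnegative frequencies summing to 1")
    q = np.where(_SINGLE, pi[None, :], 0.0)
    q = np.where(_SINGLE & _TRANSITION, q * kappa, q)
    q = np.where(_SINGLE & ~_SYNONYMOUS, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


class _SpectralQ:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self.lam = lam
        self.left = u / sqrt_pi[:, None]   # D^{-1/2} U
        self.right = (u * sqrt_pi[:, None]).T  # U' D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.lam * t)[None, :]) @ self.right
        return np.maximum(p, 0.0)


def transition_matrix(kappa: float, omega: float, pi: np.ndarray, t: float) -> np.ndarray:
    return _SpectralQ(rate_matrix(kappa, omega, pi), np.asarray(pi, float)).transition(t)


# ---------------------------------------------------------------------------
# Trees with branch classes


class TreeNode:
    """Minimal phylogeny node: ``length`` is the branch above the node and
    ``cls`` its branch class (None on the root)."""

    __slots__ = ("name", "children", "length", "cls")

    def __init__(self, name: str | None = None, length: float = 0.0, cls: str | None = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.length = length
        self.cls = cls

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length, self.cls)
        clone.children = [c.copy() for c in self.children]
        return clone

    def to_newick(self) -> str:
        return _newick(self) + ";"


def _newick(node: TreeNode) -> str:
    if node.is_leaf():
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick(c) for c in node.children)
    label = node.name or ""
    return f"({inner}){label}:{node.length:.6g}"


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string (via dendropy) into a TreeNode tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(name, dnode.edge.length or 0.0)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(tree.seed_node)
    if len(root.children) == 2:  # collapse rooted-binary root to a trifurcation
        a, b = root.children
        keep, merge = (a, b) if not a.is_leaf() else (b, a)
        if keep.is_leaf():
            return root  # two-taxon tree stays as-is
        root = TreeNode(None, 0.0)
        merge.length += keep.length
        root.children = list(keep.children) + [merge]
    return root


def label_branch_classes(tree: TreeNode, foreground_leaves: Iterable[str]) -> TreeNode:
    """Label every branch foreground iff all its descendant leaves are in the
    foreground set; mixed or background subtrees stay background."""
    fg = set(foreground_leaves)
    tree = tree.copy()
    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[id(node)] = {node.name}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
        leafset = below[id(node)]
        node.cls = FOREGROUND if leafset and leafset <= fg else BACKGROUND
    tree.cls = None
    return tree


def label_all_background(tree: TreeNode) -> TreeNode:
    tree = tree.copy()
    for node in tree.postorder():
        node.cls = BACKGROUND
    tree.cls = None
    return tree


# ---------------------------------------------------------------------------
# Likelihood


class BranchModelLikelihood:
    """Pruning log-likelihood of a codon alignment on a class-labeled tree."""

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: TreeNode,
        pi: np.ndarray | None = None,
        codon_freq: str = "F3x4",
    ):
        if alignment.has_stops():
            raise ValueError("alignment contains internal stop codons")
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(alignment.names):
            raise ValueError(
                f"tree leaves {sorted(leaf_names)} do not match alignment names"
            )
        self.tree = tree
        if pi is not None:
            self.pi = np.asarray(pi, dtype=float)
        elif codon_freq == "F3x4":
            self.pi = f3x4_frequencies(alignment)
        elif codon_freq == "uniform":
            self.pi = uniform_frequencies()
        else:
            raise ValueError(f"unknown codon_freq {codon_freq!r}")

        # compressed site patterns
        names = alignment.names
        n_codons = alignment.n_codons
        states = np.empty((n_codons, len(names)), dtype=np.int16)
        for k, name in enumerate(names):
            seq = alignment.sequences[name]
            states[:, k] = [CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)]
        patterns, counts = np.unique(states, axis=0, return_counts=True)
        self.patterns = patterns
        self.counts = counts.astype(float)
        self.leaf_col = {name: k for k, name in enumerate(names)}
        self.nodes = tree.postorder()  # root last
        self.edge_nodes = [n for n in self.nodes if n is not tree]
        self.classes = sorted({n.cls for n in self.edge_nodes})

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    def lnl(self, kappa: float, omega_by_class: Mapping[str, float], lengths: Sequence[float]) -> float:
        """Log-likelihood for the given κ, per-class ω and per-edge lengths
        (ordered as ``edge_nodes``)."""
        spectral = {
            cls: _SpectralQ(rate_matrix(kappa, omega_by_class[cls], self.pi), self.pi)
            for cls in self.classes
        }
        tmat = {
            id(node): spectral[node.cls].transition(t)
            for node, t in zip(self.edge_nodes, lengths)
        }
        n_pat = len(self.patterns)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for node in self.nodes:
            if node.is_leaf():
                continue
            lik = np.ones((n_pat, N_CODONS))
            for child in node.children:
                p = tmat[id(child)]
                if child.is_leaf():
                    contrib = p[:, self.patterns[:, self.leaf_col[child.name]]].T
                else:
                    contrib = partial.pop(id(child)) @ p.T
                lik *= contrib
            scale = lik.max(axis=1)
            scale[scale <= 0] = 1.0
            logscale += np.log(scale)
            partial[id(node)] = lik / scale[:, None]
        root_lik = partial[id(self.nodes[-1])] @ self.pi
        root_lik = np.maximum(root_lik, 1e-300)
        return float(np.dot(self.counts, np.log(root_lik) + logscale))


@dataclass
class BranchModelFit:
    model: str
    kappa: float
    omega: dict[str, float]
    pi: np.ndarray
    branch_lengths: list[float]
    lnl: float
    converged: bool
    n_iter: int
    tree: TreeNode = field(repr=False, default=None)

    def fitted_tree(self) -> TreeNode:
        tree = self.tree.copy()
        edges = [n for n in tree.postorder() if n is not tree]
        for node, t in zip(edges, self.branch_lengths):
            node.length = t
        return tree


def fit_branch_model(
    alignment: CodonAlignment,
    tree: TreeNode,
    model: str = "one-ratio",
    pi: np.ndarray | None = None,
    codon_freq: str = "F3x4",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    maxiter: int = 500,
    init: "BranchModelFit | None" = None,
) -> BranchModelFit:
    """Maximum-likelihood fit of the one- or two-ratio branch model.

    ``init`` warm-starts the search (typically a one-ratio fit seeding the
    two-ratio model); multi-start perturbations are drawn from ``seed``.
    """
    if model not in ("one-ratio", "two-ratio"):
        raise ValueError("model must be 'one-ratio' or 'two-ratio'")
    like = BranchModelLikelihood(alignment, tree, pi=pi, codon_freq=codon_freq)
    if model == "two-ratio":
        if FOREGROUND not in {n.cls for n in like.edge_nodes}:
            raise ValueError("two-ratio model requires ≥1 foreground branch")
        classes = [BACKGROUND, FOREGROUND]
    else:
        classes = ["all"]

    def omega_map(values: Sequence[float]) -> dict[str, float]:
        if model == "one-ratio":
            return {cls: values[0] for cls in like.classes}
        return {BACKGROUND: values[0], FOREGROUND: values[1]}

    n_omega = len(classes)
    n_edges = like.n_edges

    def neg_lnl(x: np.ndarray) -> float:
        kappa = math.exp(x[0])
        omegas = omega_map(np.exp(x[1 : 1 + n_omega]))
        lengths = np.exp(x[1 + n_omega :])
        try:
            return -like.lnl(kappa, omegas, lengths)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    t0 = np.array([max(n.length, 1e-3) for n in like.edge_nodes])
    if init is not None:
        omega0 = [init.omega.get(c, np.mean(list(init.omega.values()))) for c in classes]
        base = np.concatenate(
            [
                [math.log(init.kappa)],
                np.log(omega0),
                np.log(np.maximum(init.branch_lengths, 1e-4)),
            ]
        )
    else:
        base = np.concatenate([[math.log(2.0)], np.log([0.3] * n_omega), np.log(t0)])

    bounds = (
        [(math.log(0.01), math.log(100.0))]
        + [(math.log(1e-4), math.log(100.0))] * n_omega
        + [(math.log(1e-6), math.log(50.0))] * n_edges
    )

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        x0 = base if start == 0 else base + rng.normal(0.0, 0.3, size=base.size)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol * 1e-3, "gtol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("branch-model optimization failed to produce a finite likelihood")

    kappa = math.exp(best.x[0])
    omega_values = np.exp(best.x[1 : 1 + n_omega])
    omega = (
        {"all": float(omega_values[0])}
        if model == "one-ratio"
        else {BACKGROUND: float(omega_values[0]), FOREGROUND: float(omega_values[1])}
    )
    return BranchModelFit(
        model=model,
        kappa=float(kappa),
        omega=omega,
        pi=like.pi,
        branch_lengths=list(np.exp(best.x[1 + n_omega :])),
        lnl=float(-best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        tree=tree,
    )


def lrt(null_fit: BranchModelFit, alt_fit: BranchModelFit, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test: 2·(lnL_alt − lnL_null) against χ²(df).

    A higher null than alternative likelihood beyond 1e-6 signals optimizer
    failure and raises.
    """
    delta = alt_fit.lnl - null_fit.lnl
    if delta < -1e-6:
        raise ValueError(
            f"alternative lnL {alt_fit.lnl:.6f} below null {null_fit.lnl:.6f}: refit"
        )
    stat = max(2.0 * delta, 0.0)
    return stat, float(chi2.sf(stat, df))


def lrt_from_lnl(lnl_null: float, lnl_alt: float, df: int = 1) -> tuple[float, float]:
    """LRT directly from two log-likelihood values."""
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    return stat, float(chi2.sf(stat, df))
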