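"""Collinearity chaining, subgenome assignment, and retention analysis.

Homologous anchor pairs are chained into collinear blocks per chromosome
pair and orientation by dynamic programming, scoring
``match_score × anchors + gap_score × intervening genes`` (intervening genes
summed over both genomes between consecutive anchors). Labeled blocks are the
basis of the fractionation analysis: for each reference-genome family gene,
every labeled block spanning it is one candidate syntenic region in the
corresponding subgenome (LF, MF1 or MF2), and the region counts as retained
when the block anchors the gene to a target-genome family member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import GenomeAnnotation

SUBGENOMES = ("LF", "MF1", "MF2")

EVALUE_FLOOR = 1e-250  # floor applied per anchor before the chain product


@dataclass
class ChainParams:
    match_score: int = 50
    min_anchors: int = 5
    gap_score: int = -3
    block_evalue_cutoff: float = 1e-5
    proximal_window: int = 10
    tandem_max_intervening: int = 1

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be ≥ 2")
        if self.gap_score > 0:
            raise ValueError("gap_score must be ≤ 0")
        if self.tandem_max_intervening < 0:
            raise ValueError("tandem_max_intervening must be ≥ 0")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    evalue: float = 1e-180


@dataclass
class SyntenyBlock:
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    score: float
    orientation: str  # same | inverted
    subgenome: str = "unassigned"
    log10_evalue: float = 0.0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def genes_a(self) -> list[str]:
        return [a.gene_a for a in self.anchors]

    def genes_b(self) -> list[str]:
        return [a.gene_b for a in self.anchors]


# ---------------------------------------------------------------------------
# Chaining


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    params: ChainParams | None = None,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks.

    Per chromosome pair and orientation a highest-score chain decomposition is
    taken greedily (descending score, ties to the smaller A-side start); each
    anchor joins at most one block. Chains shorter than ``min_anchors`` or
    whose e-value (product of member-anchor e-values, each floored at 1e-250)
    exceeds the cutoff are discarded.
    """
    params = params or ChainParams()
    for a in anchors:
        if a.gene_a not in annot_a:
            raise KeyError(f"anchor references unknown gene {a.gene_a!r} in {annot_a.species}")
        if a.gene_b not in annot_b:
            raise KeyError(f"anchor references unknown gene {a.gene_b!r} in {annot_b.species}")

    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        key = (annot_a[a.gene_a].chromosome, annot_b[a.gene_b].chromosome)
        by_pair.setdefault(key, []).append(a)

    blocks: list[SyntenyBlock] = []
    log_cutoff = math.log10(params.block_evalue_cutoff)
    for (ca, cb), pair_anchors in sorted(by_pair.items()):
        items = [
            (annot_a[a.gene_a].rank, annot_b[a.gene_b].rank, a) for a in pair_anchors
        ]
        remaining = sorted(items, key=lambda t: (t[0], t[1]))
        while True:
            best = None
            for orientation in ("same", "inverted"):
                chain = _best_chain(remaining, orientation, params)
                if chain and (
                    best is None
                    or (chain[0], -chain[2][0][0]) > (best[0], -best[2][0][0])
                ):
                    best = (*chain, orientation)
            if best is None:
                break
            score, _, members, orientation = best
            if len(members) < params.min_anchors:
                break
            member_set = {id(m[2]) for m in members}
            remaining = [m for m in remaining if id(m[2]) not in member_set]
            log_e = sum(math.log10(max(m[2].evalue, EVALUE_FLOOR)) for m in members)
            if log_e > log_cutoff:
                continue
            blocks.append(
                SyntenyBlock(
                    anchors=[m[2] for m in members],
                    chrom_a=ca,
                    chrom_b=cb,
                    score=score,
                    orientation=orientation,
                    log10_evalue=log_e,
                )
            )
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, annot_a[b.anchors[0].gene_a].rank))
    return blocks


def _best_chain(items, orientation: str, params: ChainParams):
    """O(n²) DP for the best monotone chain; returns (score, end, members)."""
    if not items:
        return None
    n = len(items)
    dp = [float(params.match_score)] * n
    back = [-1] * n
    for j in range(n):
        ra_j, rb_j, _ = items[j]
        for i in range(j):
            ra_i, rb_i, _ = items[i]
            if ra_j <= ra_i:
                continue
            if orientation == "same":
                if rb_j <= rb_i:
                    continue
                gap = (ra_j - ra_i - 1) + (rb_j - rb_i - 1)
            else:
                if rb_j >= rb_i:
                    continue
                gap = (ra_j - ra_i - 1) + (rb_i - rb_j - 1)
            cand = dp[i] + params.match_score + params.gap_score * gap
            if cand > dp[j] or (cand == dp[j] and back[j] == -1):
                dp[j] = cand
                back[j] = i
    # best end: highest score, ties to the chain starting at the smaller A rank
    end = max(range(n), key=lambda j: (dp[j], -_chain_start(back, items, j)))
    members = []
    j = end
    while j != -1:
        members.append(items[j])
        j = back[j]
    members.reverse()
    return dp[end], end, members


def _chain_start(back, items, j):
    while back[j] != -1:
        j = back[j]
    return items[j][0]


# ---------------------------------------------------------------------------
# Subgenome assignment


@dataclass(frozen=True)
class SubgenomeSegment:
    chromosome: str
    start: int
    end: int
    label: str


def read_subgenome_table(path: str | Path) -> list[SubgenomeSegment]:
    """TSV (chromosome, start, end, label) mapping target segments to LF/MF1/MF2."""
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, label = line.split("\t")[:4]
            if label not in SUBGENOMES:
                raise ValueError(f"unknown subgenome label {label!r}")
            segments.append(SubgenomeSegment(chrom, int(start), int(end), label))
    return segments


def assign_subgenomes(
    blocks: Iterable[SyntenyBlock],
    segments: Sequence[SubgenomeSegment],
    annot_b: GenomeAnnotation,
) -> list[SyntenyBlock]:
    """Label each block by the subgenome segment its B-side span overlaps."""
    out = []
    for block in blocks:
        genes = [annot_b[g] for g in block.genes_b()]
        span_lo = min(g.start for g in genes)
        span_hi = max(g.end for g in genes)
        labels = {
            s.label
            for s in segments
            if s.chromosome == block.chrom_b and s.start <= span_hi and s.end >= span_lo
        }
        if len(labels) > 1:
            raise ValueError(
                f"block {block.chrom_a}~{block.chrom_b} [{span_lo},{span_hi}] overlaps "
                f"segments with conflicting labels {sorted(labels)}"
            )
        block.subgenome = labels.pop() if labels else "unassigned"
        out.append(block)
    return out


# ---------------------------------------------------------------------------
# Tandem clusters


def detect_tandem_clusters(
    annotation: GenomeAnnotation,
    family_genes: Iterable[str],
    max_intervening: int = 1,
) -> list[list[str]]:
    """Connected components of family genes linked on the same chromosome with
    at most ``max_intervening`` genes between them; singletons dropped."""
    members = [annotation[g] for g in family_genes]
    graph = nx.Graph()
    graph.add_nodes_from(g.id for g in members)
    by_chrom: dict[str, list] = {}
    for g in members:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.rank)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1 :]:
                if gj.rank - gi.rank <= max_intervening + 1:
                    graph.add_edge(gi.id, gj.id)
                else:
                    break
    clusters = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    clusters.sort(key=lambda c: (annotation[c[0]].chromosome, annotation[c[0]].rank))
    return clusters


def tandem_clusters_by_family(
    annotation: GenomeAnnotation,
    paralog_pairs: Iterable[AnchorPair],
    max_intervening: int = 1,
) -> list[list[str]]:
    """Tandem clusters computed within each homolog family.

    Families are connected components of the paralog-pair graph; the tandem
    rule (same chromosome, ≤ max_intervening genes between members) is then
    applied within each family, so unrelated neighbors never link.
    """
    graph = nx.Graph()
    for p in paralog_pairs:
        if p.gene_a != p.gene_b and p.gene_a in annotation and p.gene_b in annotation:
            graph.add_edge(p.gene_a, p.gene_b)
    clusters: list[list[str]] = []
    for family in nx.connected_components(graph):
        clusters.extend(detect_tandem_clusters(annotation, family, max_intervening))
    clusters.sort(key=lambda c: (annotation[c[0]].chromosome, annotation[c[0]].rank))
    return clusters


# ---------------------------------------------------------------------------
# Duplicate-type classification


def classify_duplicates(
    annotation: GenomeAnnotation,
    paralog_pairs: Iterable[AnchorPair],
    blocks: Iterable[SyntenyBlock],
    clusters: Iterable[Iterable[str]],
    params: ChainParams | None = None,
) -> dict[str, str]:
    """Classify every gene: segmental > tandem > proximal > dispersed > singleton.

    ``paralog_pairs`` are within-genome similarity pairs; ``blocks`` supply the
    segmental anchors; ``clusters`` the tandem groups.
    """
    params = params or ChainParams()
    block_genes: set[str] = set()
    for b in blocks:
        block_genes.update(b.genes_a())
        block_genes.update(b.genes_b())
    tandem_genes = {g for c in clusters for g in c}
    partners: dict[str, set[str]] = {}
    for p in paralog_pairs:
        if p.gene_a == p.gene_b:
            continue
        partners.setdefault(p.gene_a, set()).add(p.gene_b)
        partners.setdefault(p.gene_b, set()).add(p.gene_a)

    types: dict[str, str] = {}
    for g in annotation.genes:
        if g.id in block_genes and g.id in annotation:
            types[g.id] = "segmental"
        elif g.id in tandem_genes:
            types[g.id] = "tandem"
        elif g.id in partners and _has_proximal(g, partners[g.id], annotation, params.proximal_window):
            types[g.id] = "proximal"
        elif g.id in partners:
            types[g.id] = "dispersed"
        else:
            types[g.id] = "singleton"
    return types


def _has_proximal(gene, partner_ids, annotation, window: int) -> bool:
    for pid in partner_ids:
        p = annotation.get(pid)
        if p is not None and p.chromosome == gene.chromosome and abs(p.rank - gene.rank) <= window:
            return True
    return False


def write_duplicate_types(types: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tduplicate_type\n")
        for gene in sorted(types):
            fh.write(f"{gene}\t{types[gene]}\n")


# ---------------------------------------------------------------------------
# Retention


@dataclass
class RetentionSummary:
    """Per-reference-gene copy retention across the three subgenomes."""

    copies: dict[str, int] = field(default_factory=dict)
    flags: dict[str, dict[str, bool]] = field(default_factory=dict)
    candidate_regions: dict[str, int] = field(default_factory=dict)
    syntenic_targets: set[str] = field(default_factory=set)
    nonsyntenic_targets: set[str] = field(default_factory=set)
    n_regions: int = 0
    n_retained: int = 0

    @property
    def retention_fraction(self) -> float:
        return self.n_retained / self.n_regions if self.n_regions else 0.0

    def copy_histogram(self) -> dict[int, int]:
        hist = {k: 0 for k in range(4)}
        for c in self.copies.values():
            hist[min(c, 3)] += 1
        return hist


def retention_summary(
    reference_genes: Iterable[str],
    blocks: Sequence[SyntenyBlock],
    target_family_genes: Iterable[str],
    annot_a: GenomeAnnotation,
) -> RetentionSummary:
    """Count syntenic regions and retained family copies per reference gene.

    A candidate region is one labeled block whose A-side anchor span covers
    the reference gene's rank; it is retained when the block carries an anchor
    from that gene to a target family member. A reference gene in no labeled
    block contributes zero candidate regions. Target family members never
    anchored to a reference gene in a labeled block are non-syntenic.
    """
    target_set = set(target_family_genes)
    summary = RetentionSummary()
    labeled = [b for b in blocks if b.subgenome in SUBGENOMES]

    spans = []
    for b in labeled:
        ranks = [annot_a[g].rank for g in b.genes_a()]
        spans.append((b, min(ranks), max(ranks)))

    for ref in reference_genes:
        gene = annot_a[ref]
        flags = {s: False for s in SUBGENOMES}
        candidates = {s: False for s in SUBGENOMES}
        n_regions = 0
        for block, lo, hi in spans:
            if block.chrom_a != gene.chromosome or not (lo <= gene.rank <= hi):
                continue
            n_regions += 1
            candidates[block.subgenome] = True
            for anchor in block.anchors:
                if anchor.gene_a == ref and anchor.gene_b in target_set:
                    flags[block.subgenome] = True
                    summary.n_retained += 1
                    summary.syntenic_targets.add(anchor.gene_b)
                    break
        summary.n_regions += n_regions
        summary.candidate_regions[ref] = n_regions
        summary.flags[ref] = flags
        summary.copies[ref] = sum(flags.values())
    summary.nonsyntenic_targets = target_set - summary.syntenic_targets
    return summary


def write_retention(summary: RetentionSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#reference_gene\tcopies\tLF\tMF1\tMF2\tregions\n")
        for ref in sorted(summary.copies):
            f = summary.flags[ref]
            fh.write(
                f"{ref}\t{summary.copies[ref]}\t{int(f['LF'])}\t{int(f['MF1'])}"
                f"\t{int(f['MF2'])}\t{summary.candidate_regions[ref]}\n"
            )
        fh.write(
            f"#total_regions={summary.n_regions}\tretained={summary.n_retained}"
            f"\tfraction={100 * summary.retention_fraction:.1f}%\n"
        )


def write_blocks(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#block\tchrA\tchrB\tscore\torientation\tsubgenome\tn_anchors\tanchors\n")
        for i, b in enumerate(blocks, 1):
            pairs = ",".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            fh.write(
                f"{i}\t{b.chrom_a}\t{b.chrom_b}\t{b.score:.1f}\t{b.orientation}"
                f"\t{b.subgenome}\t{b.n_anchors}\t{pairs}\n"
            )
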