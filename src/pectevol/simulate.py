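"""Synthetic whole-genome-triplication (WGT) data generator.

Emulates the statistical structure the pipeline assumes: a diploid ancestral
genome carrying PG/PME family members; a triplication producing three
subgenomes fractionated to increasing degrees (LF least, MF1 moderate, MF2
most, default per-copy loss probabilities 0.3/0.5/0.65), with a designated
family's retention odds scaled by a dose-sensitivity bias; tandem
duplications inserting near-identical adjacent copies; coding sequences
diverged under a Goldman–Yang codon model with specified ω per branch class;
and tissue-structured expression with negative-binomial noise. Every gene's
fate is recorded in a truth table for recovery tests, and all outputs use
exactly the formats the analysis stages read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codonmodel import (
    BACKGROUND,
    CODON_INDEX,
    SENSE_CODONS,
    CodonAlignment,
    TreeNode,
    rate_matrix,
    _SpectralQ,
)
from .expression import ExpressionMatrix
from .io import DomainHit, Gene, GenomeAnnotation
from .kaks import CODON_TO_AA, NUCLEOTIDES
from .synteny import SUBGENOMES, AnchorPair, SubgenomeSegment

GENE_SPACING = 2_000
GENE_LENGTH = 1_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic WGT genome."""

    n_genes: int = 1000
    n_chromosomes: int = 5
    n_pg: int = 30
    n_pme: int = 36
    pme_type1_fraction: float = 0.6
    # per-copy loss probabilities, least → most fractionated subgenome
    p_loss: tuple[float, float, float] = (0.3, 0.5, 0.65)
    retention_bias: dict = field(default_factory=lambda: {"PME": 1.5, "PG": 1.0})
    tandem_rate: float = 0.05
    # codon-model parameters for sequence divergence
    kappa: float = 2.0
    omega: float = 0.2
    copy_branch_length: float = 0.2
    n_codons: int = 300
    # expression design
    tissues: tuple[str, ...] = ("callus", "root", "stem", "leaf", "flower", "silique")
    family_high_tissue: str = "flower"
    high_mean: float = 50.0
    background_mean: float = 2.0
    dispersion: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.p_loss):
            raise ValueError("loss probabilities must lie in [0, 1]")
        if not (self.p_loss[0] <= self.p_loss[1] <= self.p_loss[2]):
            raise ValueError("loss must increase across LF ≤ MF1 ≤ MF2")
        if self.n_pg + self.n_pme > self.n_genes:
            raise ValueError("family sizes exceed the gene count")
        if any(b < 1.0 for b in self.retention_bias.values()):
            raise ValueError("retention bias must be ≥ 1")
        if self.family_high_tissue not in self.tissues:
            raise ValueError("family_high_tissue must be one of the tissues")


@dataclass
class AncestralGenome:
    annotation: GenomeAnnotation
    cds: dict[str, str]
    domain_hits: list[DomainHit]
    family: dict[str, tuple[str, str]]  # gene -> (family, pme_type)


@dataclass
class TruthRecord:
    gene_id: str
    parent: str
    subgenome: str
    fate: str  # retained | lost
    duplicate_type: str
    family: str
    pme_type: str
    omega: float
    block_id: str


@dataclass
class WGTGenome:
    annotation: GenomeAnnotation
    cds: dict[str, str]
    anchors: list[AnchorPair]  # clean truth anchors (ancestor gene, primary copy)
    paralog_pairs: list[AnchorPair]  # within-target homolog pairs
    truth: list[TruthRecord]
    segments: list[SubgenomeSegment]

    def copies_per_parent(self) -> dict[str, int]:
        """Retained primary-copy count (0–3) per ancestral gene."""
        out: dict[str, int] = {}
        for rec in self.truth:
            if rec.duplicate_type == "tandem":
                continue
            out.setdefault(rec.parent, 0)
            if rec.fate == "retained":
                out[rec.parent] += 1
        return out

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {r.gene_id: r for r in self.truth if r.fate == "retained"}


# ---------------------------------------------------------------------------
# Ancestral genome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def simulate_ancestral_genome(config: SimulationConfig) -> AncestralGenome:
    """Ancestral annotated genome with family labels, CDS and domain hits.

    Domain hits are emitted consistent with the labels (e-values drawn below
    the 1e-4 search cutoff) plus decoy hits above the cutoff on random genes.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = []
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    for i in range(config.n_genes):
        chrom = f"chrA{i // per_chrom + 1}"
        pos = i % per_chrom
        start = pos * GENE_SPACING + 1
        genes.append(Gene(f"g{i:04d}", chrom, start, start + GENE_LENGTH - 1,
                          "+" if rng.random() < 0.5 else "-"))
    annotation = GenomeAnnotation("ancestor", genes)

    ids = [g.id for g in annotation.genes]
    chosen = rng.choice(len(ids), size=config.n_pg + config.n_pme, replace=False)
    family: dict[str, tuple[str, str]] = {}
    for k, idx in enumerate(chosen):
        if k < config.n_pg:
            family[ids[idx]] = ("PG", "n/a")
        else:
            is_type1 = (k - config.n_pg) < round(config.n_pme * config.pme_type1_fraction)
            family[ids[idx]] = ("PME", "I" if is_type1 else "II")

    hits: list[DomainHit] = []
    for gid, (fam, ptype) in sorted(family.items()):
        ev = 10.0 ** -rng.uniform(6.0, 40.0)
        if fam == "PG":
            hits.append(DomainHit(gid, "GH28", ev, 30, 330))
        else:
            hits.append(DomainHit(gid, "PME", ev, 120, 400))
            if ptype == "I":
                hits.append(DomainHit(gid, "PMEI", 10.0 ** -rng.uniform(5.0, 20.0), 10, 100))
    # decoy hits that the e-value filter must remove
    n_decoys = max(4, config.n_genes // 50)
    for idx in rng.choice(len(ids), size=n_decoys, replace=False):
        domain = ("GH28", "PME", "PMEI")[int(rng.integers(3))]
        hits.append(DomainHit(ids[idx], domain, 10.0 ** -rng.uniform(0.0, 3.5), 1, 50))

    cds = {gid: _random_cds(rng, config.n_codons) for gid in ids}
    return AncestralGenome(annotation, cds, hits, family)


# ---------------------------------------------------------------------------
# Triplication + fractionation


def _retention_prob(p_loss: float, bias: float) -> float:
    """Odds-scaled retention probability: odds(q)·bias with q = 1 − p_loss."""
    q = 1.0 - p_loss
    if q in (0.0, 1.0) or bias == 1.0:
        return q
    odds = q / (1.0 - q) * bias
    return odds / (1.0 + odds)


def _mutate_synonymous(rng: np.random.Generator, seq: str) -> str:
    """One random synonymous change (tandem-copy signature: Ka/Ks ≈ 0)."""
    positions = list(range(0, len(seq), 3))
    rng.shuffle(positions)
    for i in positions:
        codon = seq[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            continue
        options = [
            codon[:p] + nt + codon[p + 1 :]
            for p in range(3)
            for nt in NUCLEOTIDES
            if nt != codon[p] and CODON_TO_AA.get(codon[:p] + nt + codon[p + 1 :]) == aa
        ]
        if options:
            return seq[:i] + options[int(rng.integers(len(options)))] + seq[i + 3 :]
    return seq


def apply_wgt_fractionation(ancestor: AncestralGenome, config: SimulationConfig) -> WGTGenome:
    """Triplicate the ancestor into three fractionating subgenomes.

    Each ancestral gene gets one copy per subgenome, independently lost with
    the subgenome's loss probability (retention odds multiplied by the family
    bias); surviving copies keep ancestral order on subgenome-tagged
    chromosomes, and tandem events insert an extra adjacent copy carrying one
    synonymous change. Copy sequences diverge from the ancestor under the
    one-ratio codon model at ``copy_branch_length``.
    """
    rng = np.random.default_rng([config.seed, 2])
    pi = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    spectral = _SpectralQ(rate_matrix(config.kappa, config.omega, pi), pi)
    pmat = spectral.transition(config.copy_branch_length)
    pcum = np.cumsum(pmat, axis=1)
    pcum[:, -1] = 1.0

    per_chrom: dict[str, list[tuple[str, str]]] = {}  # chrom -> [(gene id, parent)]
    truth: list[TruthRecord] = []
    anchors: list[AnchorPair] = []
    cds: dict[str, str] = {}
    retained_by_parent: dict[str, list[str]] = {}

    for gene in ancestor.annotation.genes:
        fam, ptype = ancestor.family.get(gene.id, ("none", "n/a"))
        bias = config.retention_bias.get(fam, 1.0)
        for s, p_loss in zip(SUBGENOMES, config.p_loss):
            copy_id = f"{gene.id}_{s}"
            chrom = f"{s}_{gene.chromosome.replace('chrA', 'chrB')}"
            block_id = f"{s}:{gene.chromosome}"
            retained = rng.random() < _retention_prob(p_loss, bias)
            if not retained:
                truth.append(TruthRecord(copy_id, gene.id, s, "lost", "none",
                                         fam, ptype, config.omega, block_id))
                continue
            truth.append(TruthRecord(copy_id, gene.id, s, "retained", "segmental",
                                     fam, ptype, config.omega, block_id))
            per_chrom.setdefault(chrom, []).append((copy_id, gene.id))
            anchors.append(AnchorPair(gene.id, copy_id, 1e-180))
            retained_by_parent.setdefault(gene.id, []).append(copy_id)
            cds[copy_id] = _evolve_from(rng, ancestor.cds[gene.id], pcum)
            if rng.random() < config.tandem_rate:
                tandem_id = f"{copy_id}_t1"
                per_chrom[chrom].append((tandem_id, gene.id))
                truth.append(TruthRecord(tandem_id, gene.id, s, "retained", "tandem",
                                         fam, ptype, config.omega, block_id))
                retained_by_parent[gene.id].append(tandem_id)
                cds[tandem_id] = _mutate_synonymous(rng, cds[copy_id])

    genes = []
    for chrom, members in per_chrom.items():
        for pos, (gid, _) in enumerate(members):
            start = pos * GENE_SPACING + 1
            genes.append(Gene(gid, chrom, start, start + GENE_LENGTH - 1, "+"))
    annotation = GenomeAnnotation("triplicated", genes)

    paralogs = [
        AnchorPair(a, b, 1e-150)
        for copies in retained_by_parent.values()
        for i, a in enumerate(copies)
        for b in copies[i + 1 :]
    ]
    segments = [
        SubgenomeSegment(chrom, 1, 1_000_000_000, chrom.split("_")[0])
        for chrom in sorted(per_chrom)
    ]
    return WGTGenome(annotation, cds, anchors, paralogs, truth, segments)


def _evolve_from(rng: np.random.Generator, seq: str, pcum: np.ndarray) -> str:
    states = np.array([CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)])
    draws = rng.random(states.size)
    new = [SENSE_CODONS[int(np.searchsorted(pcum[s], u, side="right"))]
           for s, u in zip(states, draws)]
    return "".join(new)


def noisy_anchor_table(
    genome: WGTGenome,
    config: SimulationConfig,
    spurious_fraction: float = 0.05,
) -> list[AnchorPair]:
    """Truth anchors plus a configurable fraction of spurious random pairs,
    exercising chaining robustness."""
    rng = np.random.default_rng([config.seed, 3])
    anchors = list(genome.anchors)
    n_spurious = int(len(anchors) * spurious_fraction)
    a_ids = [r.parent for r in genome.truth]
    b_ids = [r.gene_id for r in genome.truth if r.fate == "retained"]
    for _ in range(n_spurious):
        anchors.append(
            AnchorPair(
                a_ids[int(rng.integers(len(a_ids)))],
                b_ids[int(rng.integers(len(b_ids)))],
                10.0 ** -rng.uniform(6.0, 12.0),
            )
        )
    return anchors


# ---------------------------------------------------------------------------
# Codon-sequence evolution on a tree


def evolve_codon_sequences(
    tree: TreeNode,
    kappa: float,
    omega_by_class: dict[str, float],
    pi: np.ndarray,
    n_codons: int,
    seed: int = 0,
) -> CodonAlignment:
    """Evolve codon sequences down a class-labeled tree.

    Root codons are drawn from π; each branch uses the same normalized GY
    generator as the likelihood machinery, exponentiated at its length. No
    indels are introduced.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(SENSE_CODONS),) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("invalid codon frequency vector")
    rng = np.random.default_rng(seed)
    spectral = {
        cls: _SpectralQ(rate_matrix(kappa, om, pi), pi)
        for cls, om in omega_by_class.items()
    }
    pi_cum = np.cumsum(pi)
    pi_cum[-1] = 1.0
    root_states = np.searchsorted(pi_cum, rng.random(n_codons), side="right")

    sequences: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            cls = child.cls if child.cls in spectral else BACKGROUND
            if child.length > 0:
                pcum = np.cumsum(spectral[cls].transition(child.length), axis=1)
                pcum[:, -1] = 1.0
                draws = rng.random(states.size)
                child_states = np.array(
                    [np.searchsorted(pcum[s], u, side="right") for s, u in zip(states, draws)]
                )
            else:
                child_states = states.copy()
            if child.is_leaf():
                sequences[child.name] = child_states
            else:
                descend(child, child_states)

    descend(tree, root_states)
    return CodonAlignment(
        {name: "".join(SENSE_CODONS[s] for s in states) for name, states in sequences.items()}
    )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genes: list[str],
    family: dict[str, tuple[str, str]],
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, bool]]:
    """Tissue-structured FPKM matrix with negative-binomial noise.

    Family members get a mean above the high-call threshold in the designated
    tissue and background means elsewhere; returns the matrix and the design
    truth (gene → should be called high in the family tissue).
    """
    if len(config.tissues) < 2:
        raise ValueError("need ≥2 tissues")
    rng = np.random.default_rng([config.seed, 4])
    means = np.full((len(genes), len(config.tissues)), config.background_mean)
    designed_high: dict[str, bool] = {}
    tissue_idx = config.tissues.index(config.family_high_tissue)
    for i, gid in enumerate(genes):
        fam = family.get(gid, ("none", "n/a"))[0]
        if fam in ("PG", "PME"):
            means[i, tissue_idx] = config.high_mean
            designed_high[gid] = True
        else:
            designed_high[gid] = False
    if config.dispersion:
        r = config.dispersion
        values = rng.negative_binomial(r, r / (r + means)).astype(float)
    else:
        values = means.copy()
    df = pd.DataFrame(values, index=genes, columns=list(config.tissues))
    return ExpressionMatrix(df, "FPKM"), designed_high


# ---------------------------------------------------------------------------
# Truth-table I/O


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tparent\tsubgenome\tfate\tduplicate_type\tfamily\tpme_type\tomega\tblock\n")
        for r in truth:
            fh.write(
                f"{r.gene_id}\t{r.parent}\t{r.subgenome}\t{r.fate}\t{r.duplicate_type}"
                f"\t{r.family}\t{r.pme_type}\t{r.omega:.4g}\t{r.block_id}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(TruthRecord(f[0], f[1], f[2], f[3], f[4], f[5], f[6], float(f[7]), f[8]))
    return out
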