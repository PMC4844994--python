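"""Stage-oriented pipeline runner over the synthetic WGT study.

Stages run in dependency order (simulate → classify → synteny → retention →
kaks → branchmodel → ortho → expression); each writes TSV outputs stamped
with the seed and parameter set, and a summary report collects one section
per executed stage. Deterministic stages are byte-identical across reruns
with the same configuration.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from . import distances, expression as expr, family, kaks, ortho, simulate, synteny
from .codonmodel import (
    BACKGROUND,
    FOREGROUND,
    TreeNode,
    fit_branch_model,
    label_branch_classes,
    lrt,
    uniform_frequencies,
)
from .config import STAGES, PipelineConfig
from .io import BlastHit, write_annotation, write_domain_hits, write_fasta

log = logging.getLogger("pectevol")


class PipelineError(RuntimeError):
    pass


class PipelineState:
    """In-memory objects passed between stages plus their on-disk mirrors."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.data: dict[str, object] = {}
        self.sections: dict[str, list[str]] = {}

    def require(self, stage: str, *keys: str):
        missing = [k for k in keys if k not in self.data]
        if missing:
            raise PipelineError(
                f"stage {stage!r} is missing upstream outputs {missing}; "
                f"run the producing stage first"
            )
        return [self.data[k] for k in keys]


def run_pipeline(config: PipelineConfig) -> PipelineState:
    """Run the requested stages in dependency order; returns the state bundle."""
    state = PipelineState(config)
    state.outdir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in config.stages]
    for stage in requested:
        log.info("[%s] starting", stage)
        _STAGE_FUNCS[stage](state)
        log.info("[%s] done", stage)
    _write_summary(state)
    return state


def _stamp(state: PipelineState, path: Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(state.config.header() + "\n")
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    ancestor = simulate.simulate_ancestral_genome(cfg.simulation)
    genome = simulate.apply_wgt_fractionation(ancestor, cfg.simulation)
    state.data.update(ancestor=ancestor, genome=genome)

    out = state.outdir
    write_annotation(ancestor.annotation, out / "ancestor.gff3")
    write_annotation(genome.annotation, out / "triplicated.gff3")
    write_fasta(ancestor.cds, out / "ancestor_cds.fasta")
    write_fasta(genome.cds, out / "triplicated_cds.fasta")
    write_domain_hits(ancestor.domain_hits, out / "domain_hits.tsv")
    simulate.write_truth_table(genome.truth, out / "truth.tsv")
    with open(out / "subgenomes.tsv", "w") as fh:
        for s in genome.segments:
            fh.write(f"{s.chromosome}\t{s.start}\t{s.end}\t{s.label}\n")
    n_ret = sum(1 for r in genome.truth if r.fate == "retained")
    state.sections["simulate"] = [
        f"ancestral_genes\t{len(ancestor.annotation)}",
        f"triplicated_retained\t{n_ret}",
        f"triplicated_lost\t{sum(1 for r in genome.truth if r.fate == 'lost')}",
    ]


def _stage_classify(state: PipelineState) -> None:
    cfg = state.config
    (ancestor,) = state.require("classify", "ancestor")
    ids = [g.id for g in ancestor.annotation.genes]
    assignments = family.classify_all(ids, ancestor.domain_hits, cfg.domain_evalue_cutoff)
    counts = family.summarize_family_counts(assignments)
    family.write_assignments(assignments, state.outdir / "family_assignments.tsv")
    state.data["assignments"] = assignments
    state.data["counts"] = counts
    state.sections["classify"] = [f"{k}\t{v}" for k, v in counts.items()]


def _stage_synteny(state: PipelineState) -> None:
    cfg = state.config
    ancestor, genome = state.require("synteny", "ancestor", "genome")
    blocks = synteny.chain_collinear_blocks(
        genome.anchors, ancestor.annotation, genome.annotation, cfg.chain
    )
    blocks = synteny.assign_subgenomes(blocks, genome.segments, genome.annotation)
    clusters = synteny.tandem_clusters_by_family(
        genome.annotation, genome.paralog_pairs, cfg.chain.tandem_max_intervening
    )
    dup_types = synteny.classify_duplicates(
        genome.annotation, genome.paralog_pairs, blocks, clusters, cfg.chain
    )
    synteny.write_blocks(blocks, state.outdir / "blocks.tsv")
    synteny.write_duplicate_types(dup_types, state.outdir / "duplicate_types.tsv")
    state.data.update(blocks=blocks, clusters=clusters, dup_types=dup_types)
    state.sections["synteny"] = [
        f"blocks\t{len(blocks)}",
        f"tandem_clusters\t{len(clusters)}",
        f"segmental\t{sum(1 for t in dup_types.values() if t == 'segmental')}",
        f"tandem\t{sum(1 for t in dup_types.values() if t == 'tandem')}",
    ]


def _stage_retention(state: PipelineState) -> None:
    ancestor, genome, blocks = state.require("retention", "ancestor", "genome", "blocks")
    lines = []
    for fam in ("PG", "PME"):
        ref_genes = [g for g, (f, _) in ancestor.family.items() if f == fam]
        targets = {r.gene_id for r in genome.truth if r.fate == "retained" and r.family == fam}
        summary = synteny.retention_summary(ref_genes, blocks, targets, ancestor.annotation)
        synteny.write_retention(summary, state.outdir / f"retention_{fam}.tsv")
        state.data[f"retention_{fam}"] = summary
        lines.append(
            f"{fam}\tregions={summary.n_regions}\tretained={summary.n_retained}"
            f"\tfraction={100 * summary.retention_fraction:.1f}%"
        )
    state.sections["retention"] = lines


def _stage_kaks(state: PipelineState) -> None:
    cfg = state.config
    ancestor, genome = state.require("kaks", "ancestor", "genome")
    rows, ks_values = [], []
    for anchor in genome.anchors:
        res = kaks.ng86_kaks(ancestor.cds[anchor.gene_a], genome.cds[anchor.gene_b])
        t_my = kaks.divergence_time(res.Ks, cfg.substitution_rate) if not math.isnan(res.Ks) else float("nan")
        if not math.isnan(res.Ks):
            ks_values.append(res.Ks)
        rows.append(
            f"{anchor.gene_a}\t{anchor.gene_b}\t{res.S:.2f}\t{res.N:.2f}\t{res.pS:.4f}"
            f"\t{res.pN:.4f}\t{res.Ka:.4f}\t{res.Ks:.4f}\t{res.ratio:.4f}\t{t_my:.1f}"
        )
    mode, _, _ = kaks.ks_mode(ks_values, cfg.ks_bin_width)
    _stamp(state, state.outdir / "kaks.tsv",
           ["#geneA\tgeneB\tS\tN\tpS\tpN\tKa\tKs\tratio\tT_MY"] + rows)
    state.data["ks_values"] = ks_values
    state.sections["kaks"] = [
        f"pairs\t{len(rows)}",
        f"ks_mode_bin_center\t{mode:.2f}",
        f"mode_T_MY\t{kaks.divergence_time(mode, cfg.substitution_rate):.1f}",
    ]


def _stage_branchmodel(state: PipelineState) -> None:
    cfg = state.config
    tree, fg_leaves = _two_clade_tree(cfg.branch_n_taxa)
    labeled = label_branch_classes(tree, fg_leaves)
    pi = uniform_frequencies()
    aln = simulate.evolve_codon_sequences(
        labeled,
        cfg.simulation.kappa,
        {BACKGROUND: cfg.branch_omega_background, FOREGROUND: cfg.branch_omega_foreground},
        pi,
        cfg.branch_n_codons,
        seed=cfg.seed + 101,
    )
    one = fit_branch_model(aln, labeled, "one-ratio", codon_freq="F3x4",
                           n_starts=1, seed=cfg.seed)
    two = fit_branch_model(aln, labeled, "two-ratio", codon_freq="F3x4",
                           n_starts=1, seed=cfg.seed, init=one)
    stat, p = lrt(one, two, df=1)
    _stamp(state, state.outdir / "branch_model.tsv", [
        "#model\tkappa\tomega_background\tomega_foreground\tlnL",
        f"one-ratio\t{one.kappa:.4f}\t{one.omega['all']:.4f}\t{one.omega['all']:.4f}\t{one.lnl:.6f}",
        f"two-ratio\t{two.kappa:.4f}\t{two.omega[BACKGROUND]:.4f}\t{two.omega[FOREGROUND]:.4f}\t{two.lnl:.6f}",
        f"LRT\tdf=1\tstat={stat:.4f}\tp={p:.3g}\t-",
    ])
    state.data["branch_fits"] = (one, two, stat, p)
    state.sections["branchmodel"] = [
        f"one_ratio_lnL\t{one.lnl:.4f}",
        f"two_ratio_lnL\t{two.lnl:.4f}",
        f"lrt_stat\t{stat:.4f}",
        f"lrt_p\t{p:.3g}",
    ]


def _two_clade_tree(n_taxa: int) -> tuple[TreeNode, list[str]]:
    """Balanced two-clade tree; the first clade is the foreground class."""
    half = max(n_taxa // 2, 2)
    fg = [f"fg{i}" for i in range(half)]
    bg = [f"bg{i}" for i in range(n_taxa - half)]

    def ladder(names: list[str]) -> TreeNode:
        node = TreeNode(names[0], 0.2)
        for name in names[1:]:
            parent = TreeNode(None, 0.1)
            parent.children = [node, TreeNode(name, 0.2)]
            node = parent
        return node

    root = TreeNode(None, 0.0)
    if len(bg) >= 2:  # trifurcating root avoids the rooted-binary redundancy
        root.children = [ladder(fg), ladder(bg[:-1]), TreeNode(bg[-1], 0.3)]
    else:
        root.children = [ladder(fg), TreeNode(bg[0], 0.3)]
    return root, fg


def _stage_ortho(state: PipelineState) -> None:
    cfg = state.config
    ancestor, genome = state.require("ortho", "ancestor", "genome")
    fam_ids = {g for g, (f, _) in ancestor.family.items() if f in ("PG", "PME")}
    hits = []
    for a in genome.anchors:
        if a.gene_a in fam_ids:
            hits.append(BlastHit(a.gene_a, a.gene_b, 95.0, 300, 10, 0, 1, 300, 1, 300, a.evalue, 500.0))
            hits.append(BlastHit(a.gene_b, a.gene_a, 95.0, 300, 10, 0, 1, 300, 1, 300, a.evalue, 500.0))
    for p in genome.paralog_pairs:
        truth = genome.truth_by_id()
        if truth.get(p.gene_a) and truth[p.gene_a].family in ("PG", "PME"):
            hits.append(BlastHit(p.gene_a, p.gene_b, 92.0, 300, 15, 0, 1, 300, 1, 300, p.evalue, 450.0))
            hits.append(BlastHit(p.gene_b, p.gene_a, 92.0, 300, 15, 0, 1, 300, 1, 300, p.evalue, 450.0))
    species = {r.gene_id: "triplicated" for r in genome.truth}
    species.update({g.id: "ancestor" for g in ancestor.annotation.genes})
    graph = ortho.build_similarity_graph(hits, species, cfg.ortho_evalue_cutoff)
    clusters = ortho.mcl_cluster(graph, cfg.mcl_inflation, min_size=cfg.min_cluster_size)
    pairs = ortho.classify_pairs(clusters)
    counts = ortho.pair_counts(pairs)
    ortho.write_clusters(clusters, state.outdir / "ortho_clusters.tsv")
    ortho.write_network(graph, pairs, state.outdir / "ortho_network.tsv")
    state.data.update(ortho_clusters=clusters, ortho_pairs=pairs)
    state.sections["ortho"] = [
        f"clusters\t{len(clusters.clusters)}",
        f"reported_clusters\t{len(clusters.reported)}",
        f"ortholog_pairs\t{counts['ortholog']}",
        f"co_ortholog_pairs\t{counts['co-ortholog']}",
    ]


def _stage_expression(state: PipelineState) -> None:
    cfg = state.config
    (genome,) = state.require("expression", "genome")
    truth = genome.truth_by_id()
    genes = [r.gene_id for r in genome.truth if r.fate == "retained"]
    fam = {g: (truth[g].family, truth[g].pme_type) for g in genes}
    matrix, designed = simulate.simulate_expression(genes, fam, cfg.simulation)
    expr.write_expression(matrix, state.outdir / "expression_fpkm.tsv")
    calls = expr.call_high_expression(matrix, cfg.fpkm_threshold)
    expr.write_calls(calls, state.outdir / "expression_calls.tsv")
    fam_genes = sorted(g for g in genes if fam[g][0] in ("PG", "PME"))
    sub = expr.ExpressionMatrix(matrix.values.loc[fam_genes], "FPKM")
    if len(fam_genes) >= 2:
        with open(state.outdir / "expression_dendrogram.nwk", "w") as fh:
            fh.write(expr.dendrogram_newick(sub) + "\n")
    n_designed = sum(designed.values())
    n_called = int(calls.calls.loc[[g for g, d in designed.items() if d],
                                   cfg.simulation.family_high_tissue].sum()) if n_designed else 0
    state.data.update(expression=matrix, calls=calls, designed_high=designed)
    state.sections["expression"] = [
        f"genes\t{len(genes)}",
        f"designed_high\t{n_designed}",
        f"called_high_in_{cfg.simulation.family_high_tissue}\t{n_called}",
    ]


def _write_summary(state: PipelineState) -> None:
    lines = []
    for stage, rows in state.sections.items():
        lines.append(f"[{stage}]")
        lines.extend(rows)
        lines.append("")
    _stamp(state, state.outdir / "summary.tsv", lines)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "synteny": _stage_synteny,
    "retention": _stage_retention,
    "kaks": _stage_kaks,
    "branchmodel": _stage_branchmodel,
    "ortho": _stage_ortho,
    "expression": _stage_expression,
}
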