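"""Domain-based assignment of genes to the PG and PME families.

A polygalacturonase (PG) carries a GH28 glycosyl-hydrolase domain. Pectin
methylesterases come in two architectures: type I (proPME) carries an
N-terminal pro region that profile searches report as a PMEI-family hit in
addition to the catalytic PME domain, while type II carries only the PME
domain. Assignment therefore reduces to domain content after an e-value
filter (default cutoff 1e-4, inclusive).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import DomainHit

DEFAULT_CUTOFF = 1e-4

#: overrides table actions, modelling manual curation of borderline loci
OVERRIDE_ACTIONS = ("add_PG", "add_PME_I", "add_PME_II", "remove")


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str  # PG | PME | none | ambiguous
    pme_type: str  # I | II | n/a
    supporting_hits: list[DomainHit] = field(default_factory=list)


def filter_hits(hits: Iterable[DomainHit], cutoff: float = DEFAULT_CUTOFF) -> list[DomainHit]:
    """Keep hits with e-value ≤ cutoff (boundary inclusive); order preserved."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [h for h in hits if h.evalue <= cutoff]


def classify_family(
    gene_id: str,
    hits: Iterable[DomainHit],
    overrides: Mapping[str, str] | None = None,
) -> FamilyAssignment:
    """Classify one gene from its already-filtered domain hits.

    GH28 → PG; PME + PMEI → PME type I; PME alone → PME type II; neither →
    none. A gene with both GH28 and a PME-domain hit is flagged ambiguous and
    excluded from both family summaries. The overrides table is applied last.
    """
    hits = [h for h in hits if h.gene_id == gene_id]
    domains = {h.domain for h in hits}
    has_gh28 = "GH28" in domains
    has_pme = "PME" in domains
    has_pmei = "PMEI" in domains

    if has_gh28 and has_pme:
        assignment = FamilyAssignment(gene_id, "ambiguous", "n/a", hits)
    elif has_gh28:
        assignment = FamilyAssignment(gene_id, "PG", "n/a", hits)
    elif has_pme and has_pmei:
        assignment = FamilyAssignment(gene_id, "PME", "I", hits)
    elif has_pme:
        assignment = FamilyAssignment(gene_id, "PME", "II", hits)
    else:
        assignment = FamilyAssignment(gene_id, "none", "n/a", hits)

    if overrides and gene_id in overrides:
        action = overrides[gene_id]
        if action not in OVERRIDE_ACTIONS:
            raise ValueError(f"unknown override action {action!r} for {gene_id}")
        if action == "remove":
            assignment = FamilyAssignment(gene_id, "none", "n/a", hits)
        elif action == "add_PG":
            assignment = FamilyAssignment(gene_id, "PG", "n/a", hits)
        elif action == "add_PME_I":
            assignment = FamilyAssignment(gene_id, "PME", "I", hits)
        elif action == "add_PME_II":
            assignment = FamilyAssignment(gene_id, "PME", "II", hits)
    return assignment


def classify_all(
    gene_ids: Iterable[str],
    hits: Iterable[DomainHit],
    cutoff: float = DEFAULT_CUTOFF,
    overrides: Mapping[str, str] | None = None,
) -> list[FamilyAssignment]:
    """Filter hits once, then classify every gene (including hit-less ones)."""
    kept = filter_hits(hits, cutoff)
    by_gene: dict[str, list[DomainHit]] = {}
    for h in kept:
        by_gene.setdefault(h.gene_id, []).append(h)
    ids = list(gene_ids)
    extra = [g for g in by_gene if g not in set(ids)]
    return [classify_family(g, by_gene.get(g, []), overrides) for g in ids + sorted(extra)]


def summarize_family_counts(assignments: Iterable[FamilyAssignment]) -> dict[str, int]:
    """Counts table: n PG, n PME, n PME type I (plus ambiguous, reported aside)."""
    c = Counter()
    for a in assignments:
        if a.family == "PG":
            c["PG"] += 1
        elif a.family == "PME":
            c["PME"] += 1
            if a.pme_type == "I":
                c["PME_I"] += 1
        elif a.family == "ambiguous":
            c["ambiguous"] += 1
    return {"PG": c["PG"], "PME": c["PME"], "PME_I": c["PME_I"], "ambiguous": c["ambiguous"]}


def write_assignments(assignments: Iterable[FamilyAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tfamily\ttype\tn_hits\n")
        for a in assignments:
            fh.write(f"{a.gene_id}\t{a.family}\t{a.pme_type}\t{len(a.supporting_hits)}\n")


def read_overrides(path: str | Path) -> dict[str, str]:
    """Overrides TSV (gene, action); actions validated on read."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, action = line.split("\t")[:2]
            if action not in OVERRIDE_ACTIONS:
                raise ValueError(f"{path}:{lineno}: unknown action {action!r}")
            out[gene] = action
    return out
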