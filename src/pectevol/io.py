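"""Readers and writers for the external formats the pipeline consumes.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends. Gene *rank* is the 0-based index of a gene along its chromosome
after sorting by start coordinate; every positional rule downstream (tandem
clusters, proximal windows, collinearity gaps) is expressed in ranks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_DOMAINS = ("GH28", "PME", "PMEI")


class FormatError(ValueError):
    """Raised for malformed input records; carries the offending line number."""


@dataclass(frozen=True)
class Gene:
    """One gene locus; alternative transcripts are collapsed to the locus span."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    """Ordered gene set for one species.

    Genes are stored sorted by (chromosome, start); ranks are consecutive
    0..n-1 within each chromosome and are recomputed on construction, so
    permuting the input order never changes them.
    """

    species: str
    genes: list[Gene] = field(default_factory=list)
    chromosome_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index_genes()

    def _index_genes(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        if not self.chromosome_order:
            self.chromosome_order = sorted({g.chromosome for g in self.genes})
        chrom_rank = {c: i for i, c in enumerate(self.chromosome_order)}
        self.genes.sort(key=lambda g: (chrom_rank.get(g.chromosome, len(chrom_rank)), g.start, g.id))
        counters: dict[str, int] = {}
        ranked = []
        for g in self.genes:
            r = counters.get(g.chromosome, 0)
            counters[g.chromosome] = r + 1
            ranked.append(dataclasses.replace(g, rank=r))
        self.genes = ranked
        self._by_id = {g.id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> Gene | None:
        return self._by_id.get(gene_id)

    def chromosome_genes(self, chromosome: str) -> list[Gene]:
        return [g for g in self.genes if g.chromosome == chromosome]


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain hit on a protein (positions are 1-based on the protein)."""

    gene_id: str
    domain: str
    evalue: float
    start: int = 1
    end: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"{self.gene_id}: negative e-value {self.evalue}")
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: domain start > end")


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular protein similarity output."""

    query: str
    subject: str
    identity: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(path: str | Path, species: str | None = None) -> GenomeAnnotation:
    """Read gene features from a GFF3 file into a ranked annotation.

    Only ``gene`` features are used; when a file carries no gene lines the
    span of each locus is inferred from its mRNA/CDS children via the
    ``Parent``/``ID`` attributes.
    """
    path = Path(path)
    genes: list[Gene] = []
    child_spans: dict[str, list] = {}
    seen_chroms: list[str] = []
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            n_records += 1
            attr = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("Name")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                genes.append(Gene(gid, chrom, start, end, strand if strand in "+-" else "+"))
                if chrom not in seen_chroms:
                    seen_chroms.append(chrom)
            elif ftype in ("mRNA", "CDS", "exon"):
                parent = attr.get("Parent") or attr.get("ID")
                if parent is None:
                    continue
                parent = parent.split(".")[0]
                rec = child_spans.setdefault(parent, [chrom, start, end, strand])
                rec[1] = min(rec[1], start)
                rec[2] = max(rec[2], end)
    if n_records == 0:
        raise FormatError(f"{path}: empty GFF3 file")
    if not genes:
        for gid, (chrom, start, end, strand) in child_spans.items():
            genes.append(Gene(gid, chrom, start, end, strand if strand in "+-" else "+"))
            if chrom not in seen_chroms:
                seen_chroms.append(chrom)
    return GenomeAnnotation(species or path.stem, genes, sorted(seen_chroms))


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene features back to GFF3; read→write→read is rank-identical."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chromosome}\tpectevol\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tab(path: str | Path, keep_self: bool = False) -> list[BlastHit]:
    """Read 12-column BLAST tabular output; self-hits (query == subject) dropped."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                hit = BlastHit(
                    parts[0], parts[1], float(parts[2]), int(parts[3]), int(parts[4]),
                    int(parts[5]), int(parts[6]), int(parts[7]), int(parts[8]),
                    int(parts[9]), float(parts[10]), float(parts[11]),
                )
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from None
            if hit.query == hit.subject and not keep_self:
                continue
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query, h.subject, f"{h.identity:.2f}", h.length, h.mismatches,
                        h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Domain-hit TSV (gene, domain, evalue, start, end)


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 columns")
            start = int(parts[3]) if len(parts) > 3 else 1
            end = int(parts[4]) if len(parts) > 4 else max(start, 1)
            hits.append(DomainHit(parts[0], parts[1], float(parts[2]), start, end))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tdomain\tevalue\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.domain}\t{h.evalue:.3g}\t{h.start}\t{h.end}\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic TSV helpers


def read_tsv_map(path: str | Path, key_col: int = 0, value_col: int = 1) -> dict[str, str]:
    """Two-column TSV → dict; later keys overwrite earlier ones."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out[parts[key_col]] = parts[value_col]
    return out
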