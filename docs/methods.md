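# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic data can and cannot show.

## Family classification

Genes are assigned from domain content after filtering hits at an e-value
cutoff, default 1e-4 with an *inclusive* boundary (hits at exactly 1e-4
pass; the boundary semantics of such cutoffs are conventionally ambiguous,
so we fix one and test it). GH28 → PG; a PME hit plus a PMEI-family hit on
the same protein → PME type I (the pro region of proPMEs is
PMEI-like, so profile searches report it as a PMEI hit; we do not require
the hit to be N-terminal of the catalytic domain, only co-occurrence); PME
alone → type II. A gene carrying both GH28 and PME hits is biologically
implausible and is flagged ambiguous and excluded from both family counts
rather than silently assigned. Manual curation (removing pseudogenes,
adding fragmented models) is expressed only through an overrides table
applied after the automatic rules, which keeps the automatic path
reproducible. PG classes A/B/C and PME groups are phylogenetic labels and
are consumed as input rather than inferred from sequence.

One gene model per locus: alternative transcripts in the GFF3 are collapsed
to the locus span before any positional logic, since all downstream rules
(ranks, tandem adjacency, windows) are defined per locus.

## Collinearity, subgenomes, retention

Anchors (homologous gene pairs) are chained per chromosome pair and
orientation by an O(n²) dynamic program maximizing
`match_score·anchors + gap_score·gaps`, with MCScanX-style defaults
(match 50, gap −3, minimum 5 anchors, block e-value ≤ 1e-5). Gaps count
intervening genes on both genomes between consecutive anchors. Chains are
extracted greedily by descending score (ties to the smaller A-side start),
each anchor joining at most one block; on instances of ≤ 8 anchors the DP
is tested against exhaustive subset enumeration. The block e-value is the
product of member-anchor e-values, each floored at 1e-250 and accumulated
in log10 space; the chain-level formula is our choice, only the cutoff
value being standard.

Subgenome labels (LF/MF1/MF2) are copied from a user- or
simulator-supplied segment table, as the partition itself comes from
curated resources; a block overlapping segments with conflicting labels is
an error rather than a guess.

Tandem clusters are connected components of family genes on one chromosome
separated by at most one intervening gene (transitive closure, singletons
dropped). For genome-wide duplicate typing the rule is applied within each
homolog family (components of the paralog-pair graph) so unrelated
neighbors never link. Duplicate-type precedence is
segmental > tandem > proximal > dispersed > singleton, mirroring the
standard duplicate classifier; the proximal window is 10 gene ranks (the
upstream tool's default criterion leaves the number unstated).

Retention counts one candidate region per reference gene per labeled block
spanning its rank; the region is retained when the block anchors the gene
to a target-family member, so copies per reference gene are 0–3 (one per
subgenome) and target members never anchored in a labeled block are
non-syntenic. A reference gene covered by no labeled block contributes no
regions. Fractions are reported to 0.1%.

## Molecular evolution

**NG86 Ka/Ks.** Synonymous sites per codon are the fraction of the nine
single-nucleotide changes that preserve the amino acid; changes creating a
stop count as nonsynonymous, so each codon contributes exactly three
sites and N + S = 3 × codons. Differences at multi-substitution codons are
averaged over all orderings of single steps, excluding pathways through
stop codons; the rare pairs whose every pathway is blocked are masked
entirely (sites and differences), a decision the counting method leaves to
implementations. Proportions are Jukes–Cantor corrected; pS ≥ 0.75 flags
saturation and leaves Ks undefined rather than extrapolating. Gap or
ambiguous codon columns are deleted pairwise-complete (whole codons);
JC69 nucleotide distances use pairwise deletion per site.

**Dating.** T = Ks/(2R) with R = 1.5e-8 synonymous substitutions per site
per year (the standard dicot nuclear rate), reported in million years.
Ks histograms use half-open bins [lo, hi) of width 0.1 — modes are
conventionally reported at one-decimal resolution — with ties broken to
the smallest bin center.

**Trees.** Neighbor joining is delegated to scikit-bio with negative
branch estimates clamped to zero; it recovers additive matrices exactly,
which the tests verify on four-taxon instances.

**Codon branch models.** The Goldman–Yang rate matrix over the 61 sense
codons: zero for multi-nucleotide changes, π_j for synonymous
transversions, κπ_j synonymous transitions, ωπ_j and ωκπ_j for
nonsynonymous, each class's matrix normalized to one expected substitution
per codon. Codon frequencies default to F3x4 (positional nucleotide
frequencies, floored at 1e-4 per nucleotide and renormalized to avoid
zero-frequency codons); a uniform-π option exists for controlled tests.
Likelihoods use Felsenstein pruning over compressed site patterns with
per-node max scaling; transition matrices come from eigendecomposition of
the π-symmetrized generator. Branch classes are leaf-set driven: a branch
is foreground iff all its descendant leaves are in the declared foreground
set, mixed subtrees staying background. κ, per-class ω and all branch
lengths are maximized jointly by L-BFGS-B on log-parameters (bounds
ω ∈ [1e-4, 100], κ ∈ [0.01, 100], t ∈ [1e-6, 50]; gradient tolerance
1e-6, ≤ 500 iterations). The fitter supports multi-start perturbation
(default 3 starts, σ = 0.3 on the log scale, seeded); bulk simulation
studies run single-start fits warm-started from the one-ratio optimum,
which converged to the same optima in our checks at a third of the cost.
The LRT uses 2ΔlnL against χ²(df); an alternative likelihood below the
null beyond 1e-6 raises, as that can only be optimizer failure.

## Ortholog clustering

Edges require the e-value cutoff (default 1e-5) in both directions when
reciprocity is on; weights are −log10(e) capped at 200 and averaged over
the two directions. MCL adds self-loops equal to each node's maximum
incident weight (1 for isolated nodes), column-normalizes, and iterates
expansion/inflation (default inflation 1.5) with entries below 1e-8 pruned
per iteration for numerical stability, to a fixed point (tolerance 1e-6,
≤ 200 iterations). Clusters are attractor components; only clusters of
≥ 4 genes enter the orthology report, within which cross-species pairs are
orthologs and same-species pairs co-orthologs.

## Expression

Mean normalization divides each gene by its row mean (all-zero rows pass
through flagged). High-expression calls use strict inequality against
unit-specific thresholds: FPKM > 10, mean-normalized > 1; "specific" means
high in exactly one tissue. Clustering log2(x+1)-transforms (the
pseudocount handles zeros, which the original tooling leaves unspecified),
uses 1 − Pearson distance with average linkage, assigns zero-variance rows
distance 1 to everything, and sorts genes by id first so results are
input-order invariant. Divergence between two homologs is the Jaccard
distance of their high-call tissue sets — a quantitative stand-in for
qualitative heat-map comparison; two genes high nowhere score 0.

## The simulator

The generator emulates exactly the structure the analysis assumes: a
uniformly spaced ancestor (default 1000 genes on 5 chromosomes, 30 PG and
36 PME of which 60% type I — large enough families for stable recovery
statistics at desk scale); triplication into three subgenomes with
independent per-copy Bernoulli loss at 0.3/0.5/0.65 (least → most
fractionated), the designated family's retention odds multiplied by a
dose-sensitivity bias (default 1.5 for PME, 1.0 for PG); tandem insertions
at rate 0.05 carrying one synonymous change (so tandem pairs have Ka/Ks ≈ 0,
a checkable signature); coding sequences diverged from the ancestor under
the same GY generator the likelihood uses (κ = 2, ω = 0.2, branch length
0.2 per copy); domain-hit tables with e-values below the cutoff plus decoy
hits above it; and negative-binomial expression (dispersion 5) with family
members at mean 50 FPKM in the flower tissue against a background mean
of 2. Anchor tables are emitted clean and optionally with 5% spurious
hits. Branch-model studies simulate 6-taxon two-clade trees at 500 codons
with (ω_fg, ω_bg) = (0.28, 0.17), the fitted regime of interest; type-I
error checks use ω = 0.2 on all branches at 200 codons, where the χ²(1)
approximation is already adequate.

What the simulator does **not** model: intron/exon structure, indels,
alignment error, pseudogenes, segmental rearrangement within subgenomes,
expression correlation across tissues, and annotation noise. Passing
recovery tests therefore demonstrates correctness of the analysis logic
under the stated generative assumptions, not robustness to real-data
artifacts such as fragmented gene models or misassembly.

## Problem sizes and determinism

Default study sizes (1000-gene ancestor; 20 recovery and 24 null
replicates for branch models; 25 random chaining instances of ≤ 8 anchors)
keep the full validation suite under a minute while leaving binomial error
bars small relative to the tested margins. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; pipeline reruns
with the same configuration are byte-identical for deterministic stages.

## Known limitations

* The pro-domain rule uses domain co-occurrence, not position, so a
  genuinely separate PMEI gene fused in annotation would be typed I.
* The block e-value formula is heuristic; very short blocks of weak
  anchors near the cutoff may be kept or dropped differently than by other
  chaining tools.
* Two-taxon trees retain the rooted form (branch lengths identifiable only
  as a sum); trees with ≥ 3 taxa are handled unrooted via a trifurcating
  root.
* NG86 is a counting method; at high divergence it underestimates rates
  relative to ML estimators, and saturation is flagged rather than
  corrected.
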