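# pectevol

Tools for studying how cell-wall gene families — polygalacturonases (PG,
GH28 domain) and pectin methylesterases (PME, with type I "proPME" carrying
an extra PMEI-like pro domain) — evolve after a whole-genome triplication
(WGT), as in *Brassica rapa*, where the hexaploidy event left three
homeologous subgenomes (LF, MF1, MF2) fractionating at increasing rates.

The package implements the full analysis chain:

* **Family classification** from profile-domain hits under an e-value
  cutoff (default ≤ 1e-4): GH28 → PG; PME + PMEI → PME type I; PME alone →
  type II; a manual-curation overrides table is applied last.
* **Collinearity and fractionation** — anchor pairs are chained into
  collinear blocks by dynamic programming with score
  `50·anchors − 3·(intervening genes)`, minimum 5 anchors and a block
  e-value cutoff of 1e-5; blocks take subgenome labels from a segment
  table; per reference gene the retained copies across LF/MF1/MF2 are
  counted (0–3) and tandem clusters are genes of one family separated by at
  most one intervening gene. Duplicate types follow the precedence
  segmental > tandem > proximal > dispersed > singleton.
* **Molecular evolution** — Nei–Gojobori (NG86) Ka/Ks with Jukes–Cantor
  correction, divergence dating by `T = Ks/2R` (R = 1.5 × 10⁻⁸ synonymous
  substitutions/site/year), JC69 distances, neighbor-joining trees, and
  Goldman–Yang codon models with one-ratio vs two-ratio branch classes
  compared by a χ²(1) likelihood-ratio test.
* **Ortholog clustering** — reciprocal-hit similarity graphs weighted by
  −log10 e-value, Markov clustering (MCL), and ortholog / co-ortholog pair
  classification within clusters of ≥ 4 genes.
* **Expression divergence** — FPKM (> 10) and mean-normalized (> 1)
  high-expression calls, tissue specificity, log2 hierarchical clustering
  (1 − Pearson, average linkage), and Jaccard divergence of high-call
  tissue sets between homologs.
* **A WGT simulator** that triplicates a synthetic ancestor, fractionates
  each subgenome (default per-copy loss 0.3 / 0.5 / 0.65, with a
  dose-sensitivity retention bias for a designated family), inserts tandem
  duplicates, diverges coding sequences under a specified ω, and emits
  tissue-structured expression — all recorded in a truth table so every
  analysis stage can be validated by recovery.

## Worked example

Run the whole synthetic study from the command line:

```sh
pectevol all --seed 42 -o out
cat out/summary.tsv
```

which prints (abridged):

```
[classify]
PG      30
PME     36
PME_I   22

[retention]
PG   regions=90   retained=47  fraction=52.2%
PME  regions=108  retained=66  fraction=61.1%

[kaks]
pairs   1554
ks_mode_bin_center  0.15
mode_T_MY   5.0

[branchmodel]
one_ratio_lnL  -5219.4413
two_ratio_lnL  -5215.1061
lrt_stat    8.6704
lrt_p       0.00323
```

Reading this: the classifier recovers the simulated family sizes exactly
(30 PG, 36 PME of which 22 proPME); PME homeologs are retained in a larger
fraction of their candidate subgenome regions than PG (61% vs 52%),
reflecting the simulator's dose-sensitivity bias; the Ks distribution of
ancestor–copy pairs peaks in the 0.1–0.2 bin, dating the simulated
triplication to ~5 million years under `T = Ks/2R`; and on the
branch-model stage, data generated with distinct foreground/background ω
reject the one-ratio null (P ≈ 0.003).

Library use mirrors the CLI; for example:

```python
from pectevol import ng86_kaks, divergence_time
r = ng86_kaks("TTT", "TTA")        # S=0.5, N=2.5, Ka≈0.5716, Ks=0
t = divergence_time(0.4)           # 13.3 (million years)
```

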