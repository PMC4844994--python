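"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the three possible single-nucleotide changes at each position that leave
the amino acid unchanged (changes creating a stop codon count as
nonsynonymous, so every codon contributes exactly three sites).
*Differences* between codons differing at several positions are averaged
over all orderings of single-nucleotide steps, excluding pathways that pass
through a stop codon; a codon pair whose every pathway is blocked is masked.
Proportions are corrected with the Jukes–Cantor formula, and Ks converts to
divergence time via T = Ks / (2R) with R the synonymous substitution rate
per site per year (default 1.5e-8, the standard dicot nuclear rate).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA = dict(_TABLE.forward_table)

NUCLEOTIDES = "ACGT"
DEFAULT_RATE = 1.5e-8  # synonymous substitutions / site / year


class SaturationWarning(UserWarning):
    pass


@dataclass
class KaKsResult:
    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    Ka: float
    Ks: float
    ratio: float
    n_codons: int

    @property
    def saturated(self) -> bool:
        return math.isnan(self.Ks)


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a sense codon (0–3)."""
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if CODON_TO_AA.get(mutant) == aa:  # stops count as nonsynonymous
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_pair_differences(codon1: str, codon2: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences averaged over substitution
    pathways; ``None`` when every pathway runs through a stop codon."""
    if codon1 == codon2:
        return (0.0, 0.0)
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon1
        sd = nd = 0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
                break
            if nxt in STOP_CODONS:  # endpoint itself a stop: caller masks these
                blocked = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:
        return None
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return (sd, nd)


def jukes_cantor(p: float) -> float:
    """JC correction −(3/4)·ln(1 − 4p/3); NaN at or beyond saturation (p ≥ 0.75)."""
    if p < 0:
        raise ValueError("proportion must be ≥ 0")
    if p >= 0.75:
        return float("nan")
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return d if d != 0 else 0.0


def ng86_kaks(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka/Ks for one aligned coding-sequence pair.

    Gap- or ambiguity-containing codon columns and columns holding a stop
    codon in either sequence are masked (complete-codon deletion), as are the
    rare codon pairs whose every substitution pathway crosses a stop.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq1) % 3:
        raise ValueError(f"alignment length {len(seq1)} not divisible by 3")

    S = N = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (_is_clean(c1) and _is_clean(c2)):
            continue
        diffs = codon_pair_differences(c1, c2)
        if diffs is None:
            continue
        n_codons += 1
        s1, s2 = synonymous_site_fraction(c1), synonymous_site_fraction(c2)
        s_mean = (s1 + s2) / 2.0  # mean synonymous sites of the two codons
        S += s_mean
        N += 3.0 - s_mean
        sd += diffs[0]
        nd += diffs[1]
    if n_codons == 0:
        raise ValueError("zero unmasked codon columns")

    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = Ka / Ks if Ks and Ks > 0 and not math.isnan(Ks) and not math.isnan(Ka) else float("nan")
    return KaKsResult(S, N, sd, nd, pS, pN, Ka, Ks, ratio, n_codons)


def _is_clean(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(nt in NUCLEOTIDES for nt in codon)
        and codon not in STOP_CODONS
    )


def divergence_time(ks: float, rate: float = DEFAULT_RATE) -> float:
    """Divergence time T = Ks/(2R) in million years."""
    if ks < 0:
        raise ValueError("Ks must be ≥ 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return ks / (2.0 * rate) / 1e6


def ks_mode(values, bin_width: float = 0.1) -> tuple[float, np.ndarray, np.ndarray]:
    """Modal bin of a Ks distribution.

    Histogram uses half-open bins [lo, hi) of the given width on [0, max];
    returns (modal bin center, counts, bin edges); ties break to the smallest
    center.
    """
    values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if values.size == 0:
        raise ValueError("no finite Ks values")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width - 1e-12, bin_width)
    idx = np.minimum((values / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (smallest) on ties
    center = (mode_bin + 0.5) * bin_width
    return center, counts, edges
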