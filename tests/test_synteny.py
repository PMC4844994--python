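"""Collinearity chaining, tandem clusters, duplicate types, retention."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pectevol.io import Gene, GenomeAnnotation
from pectevol.synteny import (
    AnchorPair,
    ChainParams,
    SubgenomeSegment,
    assign_subgenomes,
    chain_collinear_blocks,
    classify_duplicates,
    detect_tandem_clusters,
    retention_summary,
    tandem_clusters_by_family,
)


def _annot(species, n, chrom="c1", prefix="g"):
    genes = [Gene(f"{prefix}{i}", chrom, i * 1000 + 1, i * 1000 + 500) for i in range(n)]
    return GenomeAnnotation(species, genes)


def _anchors(pairs, e=1e-50):
    return [AnchorPair(a, b, e) for a, b in pairs]


def best_chain_by_enumeration(rank_pairs, params):
    """Independent oracle: best collinear chain over all anchor subsets."""
    best = 0.0
    items = sorted(rank_pairs)
    for r in range(1, len(items) + 1):
        for subset in itertools.combinations(items, r):
            for sign in (1, -1):
                ras = [p[0] for p in subset]
                rbs = [sign * p[1] for p in subset]
                if ras != sorted(ras) or len(set(ras)) < len(ras):
                    continue
                if rbs != sorted(rbs) or len(set(rbs)) < len(rbs):
                    continue
                score = params.match_score * r
                for (a1, b1), (a2, b2) in zip(subset, subset[1:]):
                    score += params.gap_score * ((a2 - a1 - 1) + (abs(b2 - b1) - 1))
                best = max(best, score)
    return best


class TestChaining:
    def test_four_anchors_below_min_size_gives_no_block(self):
        a, b = _annot("A", 10, prefix="a"), _annot("B", 10, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(4)])
        assert chain_collinear_blocks(anchors, a, b) == []

    def test_six_consecutive_anchors_score_300(self):
        a, b = _annot("A", 10, prefix="a"), _annot("B", 10, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(6)])
        (block,) = chain_collinear_blocks(anchors, a, b)
        assert block.score == 300
        assert block.n_anchors == 6
        assert block.orientation == "same"

    def test_two_gene_gap_costs_six(self):
        a, b = _annot("A", 12, prefix="a"), _annot("B", 12, prefix="b")
        pairs = [("a0", "b0"), ("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4"),
                 ("a7", "b5")]  # 2 intervening genes on the A side
        (block,) = chain_collinear_blocks(_anchors(pairs), a, b)
        assert block.score == 294

    def test_inverted_blocks_are_found(self):
        a, b = _annot("A", 10, prefix="a"), _annot("B", 10, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{9 - i}") for i in range(6)])
        (block,) = chain_collinear_blocks(anchors, a, b)
        assert block.orientation == "inverted"
        assert block.score == 300

    def test_unknown_gene_raises(self):
        a, b = _annot("A", 4, prefix="a"), _annot("B", 4, prefix="b")
        with pytest.raises(KeyError, match="nope"):
            chain_collinear_blocks(_anchors([("nope", "b0")] * 1), a, b)

    def test_high_evalue_chain_discarded(self):
        a, b = _annot("A", 10, prefix="a"), _annot("B", 10, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(6)], e=0.9)
        assert chain_collinear_blocks(anchors, a, b) == []

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_dp_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        ras = rng.choice(12, size=n, replace=False)
        rbs = rng.choice(12, size=n, replace=False)
        params = ChainParams(min_anchors=2)
        a, b = _annot("A", 12, prefix="a"), _annot("B", 12, prefix="b")
        anchors = [AnchorPair(f"a{ra}", f"b{rb}", 1e-60) for ra, rb in zip(ras, rbs)]
        blocks = chain_collinear_blocks(anchors, a, b, params)
        dp_best = max((blk.score for blk in blocks), default=0.0)
        oracle = best_chain_by_enumeration(list(zip(map(int, ras), map(int, rbs))), params)
        if oracle >= params.match_score * params.min_anchors:
            assert dp_best == oracle

    def test_deleting_an_anchor_never_increases_best_score(self):
        rng = np.random.default_rng(5)
        a, b = _annot("A", 15, prefix="a"), _annot("B", 15, prefix="b")
        ras = rng.permutation(15)[:8]
        rbs = rng.permutation(15)[:8]
        anchors = [AnchorPair(f"a{ra}", f"b{rb}", 1e-60) for ra, rb in zip(ras, rbs)]
        params = ChainParams(min_anchors=2)
        full = max((blk.score for blk in chain_collinear_blocks(anchors, a, b, params)), default=0)
        for i in range(len(anchors)):
            sub = anchors[:i] + anchors[i + 1 :]
            best = max((blk.score for blk in chain_collinear_blocks(sub, a, b, params)), default=0)
            assert best <= full


class TestSubgenomes:
    def _blocks(self):
        a, b = _annot("A", 10, prefix="a"), _annot("B", 10, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(6)])
        return chain_collinear_blocks(anchors, a, b), b

    def test_block_inside_segment_gets_its_label(self):
        blocks, b = self._blocks()
        out = assign_subgenomes(blocks, [SubgenomeSegment("c1", 1, 10**6, "LF")], b)
        assert out[0].subgenome == "LF"

    def test_block_outside_all_segments_unassigned(self):
        blocks, b = self._blocks()
        out = assign_subgenomes(blocks, [SubgenomeSegment("c9", 1, 10**6, "LF")], b)
        assert out[0].subgenome == "unassigned"

    def test_conflicting_overlap_raises(self):
        blocks, b = self._blocks()
        segs = [SubgenomeSegment("c1", 1, 3000, "LF"), SubgenomeSegment("c1", 3001, 10**6, "MF1")]
        with pytest.raises(ValueError, match="conflicting"):
            assign_subgenomes(blocks, segs, b)


class TestTandem:
    def _family_at(self, ranks, n=30):
        annot = _annot("A", n)
        return annot, [f"g{r}" for r in ranks]

    def test_one_intervening_gene_links(self):
        annot, fam = self._family_at([10, 12])
        assert detect_tandem_clusters(annot, fam, 1) == [["g10", "g12"]]

    def test_two_intervening_genes_do_not_link(self):
        annot, fam = self._family_at([10, 13])
        assert detect_tandem_clusters(annot, fam, 1) == []

    def test_transitive_closure_builds_triplet_cluster(self):
        annot, fam = self._family_at([10, 11, 12])
        assert detect_tandem_clusters(annot, fam, 1) == [["g10", "g11", "g12"]]

    def test_cluster_membership_invariant_under_relabeling(self):
        annot, fam = self._family_at([3, 4, 20, 21])
        clusters = detect_tandem_clusters(annot, fam, 1)
        # relabel by permuting ids: same ranks, new names
        mapping = {f"g{r}": f"x{r}" for r in range(30)}
        genes2 = [Gene(mapping[g.id], g.chromosome, g.start, g.end) for g in annot.genes]
        annot2 = GenomeAnnotation("B", genes2)
        clusters2 = detect_tandem_clusters(annot2, [mapping[f] for f in fam], 1)
        assert [[mapping[g] for g in c] for c in clusters] == clusters2

    def test_family_scoped_clusters_ignore_unrelated_neighbors(self):
        annot = _annot("A", 10)
        # g2~g3 are paralogs; g4 is a paralog of a distant gene only
        pairs = [AnchorPair("g2", "g3"), AnchorPair("g4", "g9")]
        clusters = tandem_clusters_by_family(annot, pairs, 1)
        assert clusters == [["g2", "g3"]]


class TestDuplicateTypes:
    def _setup(self):
        a = _annot("A", 20, prefix="a")
        b = _annot("B", 20, prefix="b")
        anchors = _anchors([(f"a{i}", f"b{i}") for i in range(6)])
        blocks = chain_collinear_blocks(anchors, a, b)
        return a, b, blocks

    def test_block_anchor_beats_tandem(self):
        a, b, blocks = self._setup()
        clusters = [["b0", "b1"]]
        pairs = [AnchorPair("b0", "b1")]
        types = classify_duplicates(b, pairs, blocks, clusters)
        assert types["b0"] == "segmental"

    def test_no_hits_is_singleton(self):
        a, b, blocks = self._setup()
        types = classify_duplicates(b, [], [], [])
        assert types["b19"] == "singleton"

    def test_proximal_window(self):
        b = _annot("B", 20, prefix="b")
        types = classify_duplicates(b, [AnchorPair("b2", "b9")], [], [])
        assert types["b2"] == "proximal"  # rank distance 7 ≤ window 10

    def test_dispersed_beyond_window(self):
        b = _annot("B", 20, prefix="b")
        types = classify_duplicates(b, [AnchorPair("b2", "b16")], [], [])
        assert types["b2"] == "dispersed"

    def test_tandem_without_block(self):
        b = _annot("B", 20, prefix="b")
        types = classify_duplicates(b, [AnchorPair("b5", "b6")], [], [["b5", "b6"]])
        assert types["b5"] == "tandem"

    def test_every_gene_has_exactly_one_type(self):
        a, b, blocks = self._setup()
        types = classify_duplicates(b, [AnchorPair("b8", "b9")], blocks, [["b8", "b9"]])
        assert set(types) == {g.id for g in b.genes}
        assert set(types.values()) <= {"segmental", "tandem", "proximal", "dispersed", "singleton"}


class TestRetention:
    def _triplicated(self):
        """One reference chromosome anchored into three labeled subgenome blocks."""
        ref = _annot("A", 10, prefix="a")
        genes_b = []
        for k, sub in enumerate(("LF", "MF1", "MF2")):
            for i in range(10):
                genes_b.append(Gene(f"{sub}_b{i}", f"chr_{sub}", i * 1000 + 1, i * 1000 + 500))
        tgt = GenomeAnnotation("B", genes_b)
        anchors = []
        keep = {"LF": set(range(10)), "MF1": set(range(0, 10, 2)), "MF2": {0, 1}}
        for sub in ("LF", "MF1", "MF2"):
            anchors += [AnchorPair(f"a{i}", f"{sub}_b{i}") for i in sorted(keep[sub])]
        blocks = chain_collinear_blocks(anchors, ref, tgt, ChainParams(min_anchors=2))
        segs = [SubgenomeSegment(f"chr_{s}", 1, 10**6, s) for s in ("LF", "MF1", "MF2")]
        blocks = assign_subgenomes(blocks, segs, tgt)
        return ref, tgt, blocks, keep

    def test_three_subgenome_copies(self):
        ref, tgt, blocks, keep = self._triplicated()
        targets = {f"{s}_b0" for s in ("LF", "MF1", "MF2")}
        summary = retention_summary(["a0"], blocks, targets, ref)
        assert summary.copies["a0"] == 3

    def test_copy_counts_match_anchoring(self):
        ref, tgt, blocks, keep = self._triplicated()
        targets = {f"{s}_b{i}" for s, idx in keep.items() for i in idx}
        refs = [f"a{i}" for i in range(10)]
        summary = retention_summary(refs, blocks, targets, ref)
        for i in range(10):
            expected = sum(1 for s in keep if i in keep[s])
            assert summary.copies[f"a{i}"] == expected

    def test_retained_plus_nonsyntenic_partition_targets(self):
        ref, tgt, blocks, keep = self._triplicated()
        targets = {f"{s}_b{i}" for s, idx in keep.items() for i in idx} | {"MF2_b7"}
        refs = [f"a{i}" for i in range(10)]
        summary = retention_summary(refs, blocks, targets, ref)
        assert summary.syntenic_targets | summary.nonsyntenic_targets == targets
        assert not summary.syntenic_targets & summary.nonsyntenic_targets
        assert "MF2_b7" in summary.nonsyntenic_targets

    def test_copy_conservation(self):
        ref, tgt, blocks, keep = self._triplicated()
        targets = {f"{s}_b{i}" for s, idx in keep.items() for i in idx}
        refs = [f"a{i}" for i in range(10)]
        summary = retention_summary(refs, blocks, targets, ref)
        hist = summary.copy_histogram()
        assert sum(hist.values()) == len(refs)
        assert sum(k * v for k, v in hist.items()) == summary.n_retained

    def test_printed_fraction_arithmetic(self):
        # 102 retained over 199 regions reports 51.3%, i.e. the printed 51%
        from pectevol.synteny import RetentionSummary

        s = RetentionSummary(n_regions=199, n_retained=102)
        assert round(100 * s.retention_fraction, 1) == 51.3
        assert round(100 * s.retention_fraction) == 51
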