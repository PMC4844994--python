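"""Simulator construction, determinism, statistical calibration, recovery."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from pectevol.family import classify_all
from pectevol.kaks import ng86_kaks
from pectevol.simulate import (
    SimulationConfig,
    TruthRecord,
    apply_wgt_fractionation,
    noisy_anchor_table,
    read_truth_table,
    simulate_ancestral_genome,
    simulate_expression,
    write_truth_table,
    _retention_prob,
)
from pectevol.synteny import SUBGENOMES
from pectevol.expression import call_high_expression


class TestConfig:
    def test_loss_ordering_enforced(self):
        with pytest.raises(ValueError, match="LF"):
            SimulationConfig(p_loss=(0.5, 0.3, 0.65))

    def test_family_sizes_bounded(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(n_genes=10, n_pg=8, n_pme=8)

    def test_bias_must_be_at_least_one(self):
        with pytest.raises(ValueError, match="bias"):
            SimulationConfig(retention_bias={"PME": 0.5})


class TestAncestor:
    def test_construction_counts(self, small_config, ancestor):
        assert len(ancestor.annotation) == small_config.n_genes
        gh28 = {h.gene_id for h in ancestor.domain_hits
                if h.domain == "GH28" and h.evalue <= 1e-4}
        pme = {h.gene_id for h in ancestor.domain_hits
               if h.domain == "PME" and h.evalue <= 1e-4}
        assert len(gh28) == small_config.n_pg
        assert len(pme) == small_config.n_pme

    def test_seed_determinism(self, small_config, ancestor):
        again = simulate_ancestral_genome(small_config)
        assert again.cds == ancestor.cds
        assert [(h.gene_id, h.domain, h.evalue) for h in again.domain_hits] == [
            (h.gene_id, h.domain, h.evalue) for h in ancestor.domain_hits
        ]

    def test_decoys_exist_and_filter_recovers_labels_exactly(self, ancestor):
        decoys = [h for h in ancestor.domain_hits if h.evalue > 1e-4]
        assert decoys  # filter must have something to remove
        ids = [g.id for g in ancestor.annotation.genes]
        assignments = classify_all(ids, ancestor.domain_hits)
        called = {a.gene_id: (a.family, a.pme_type) for a in assignments
                  if a.family in ("PG", "PME")}
        assert called == ancestor.family


class TestFractionation:
    def test_no_loss_keeps_three_copies(self, small_config, ancestor):
        cfg = dataclasses.replace(small_config, p_loss=(0.0, 0.0, 0.0), tandem_rate=0.0)
        genome = apply_wgt_fractionation(ancestor, cfg)
        assert all(c == 3 for c in genome.copies_per_parent().values())

    def test_total_loss(self, small_config, ancestor):
        cfg = dataclasses.replace(small_config, p_loss=(1.0, 1.0, 1.0))
        genome = apply_wgt_fractionation(ancestor, cfg)
        assert all(r.fate == "lost" for r in genome.truth)

    def test_copy_conservation(self, small_config, ancestor, wgt_genome):
        primary = [r for r in wgt_genome.truth if r.duplicate_type != "tandem"]
        assert len(primary) == 3 * small_config.n_genes

    def test_subgenome_retention_calibrated(self):
        cfg = SimulationConfig(n_genes=2000, n_chromosomes=5, n_pg=0, n_pme=0, seed=11)
        genome = apply_wgt_fractionation(simulate_ancestral_genome(cfg), cfg)
        for s, p_loss in zip(SUBGENOMES, cfg.p_loss):
            n = cfg.n_genes
            kept = sum(1 for r in genome.truth
                       if r.subgenome == s and r.fate == "retained"
                       and r.duplicate_type != "tandem")
            q = 1.0 - p_loss
            se = math.sqrt(q * (1 - q) * n)
            assert abs(kept - q * n) <= 3 * se

    def test_family_bias_raises_retention(self):
        cfg = SimulationConfig(n_genes=2000, n_chromosomes=5, n_pg=0, n_pme=400,
                               retention_bias={"PME": 1.5}, seed=11)
        genome = apply_wgt_fractionation(simulate_ancestral_genome(cfg), cfg)
        fam = [r for r in genome.truth if r.family == "PME" and r.duplicate_type != "tandem"]
        bg = [r for r in genome.truth if r.family == "none" and r.duplicate_type != "tandem"]
        k_fam = sum(r.fate == "retained" for r in fam)
        k_bg = sum(r.fate == "retained" for r in bg)
        p_bg = k_bg / len(bg)
        # one-sided binomial: family retention under the background rate
        pval = stats.binomtest(k_fam, len(fam), p_bg, alternative="greater").pvalue
        assert pval < 0.05

    def test_odds_scaling_formula(self):
        assert _retention_prob(0.5, 1.0) == pytest.approx(0.5)
        assert _retention_prob(0.5, 1.5) == pytest.approx(0.6)  # odds 1 → 1.5
        assert _retention_prob(0.0, 2.0) == pytest.approx(1.0)
        assert _retention_prob(1.0, 2.0) == pytest.approx(0.0)

    def test_tandem_copies_have_near_zero_kaks(self, ancestor, wgt_genome):
        tandems = [r for r in wgt_genome.truth if r.duplicate_type == "tandem"]
        assert tandems
        for rec in tandems[:5]:
            parent_copy = rec.gene_id.rsplit("_t", 1)[0]
            r = ng86_kaks(wgt_genome.cds[parent_copy], wgt_genome.cds[rec.gene_id])
            assert r.nd == 0  # single synonymous change only
            assert r.sd <= 1

    def test_noisy_anchor_table_adds_spurious_hits(self, small_config, wgt_genome):
        noisy = noisy_anchor_table(wgt_genome, small_config, 0.05)
        assert len(noisy) == len(wgt_genome.anchors) + int(0.05 * len(wgt_genome.anchors))


class TestExpressionSim:
    def test_zero_noise_calls_match_design_exactly(self, small_config, wgt_genome):
        cfg = dataclasses.replace(small_config, dispersion=None)
        truth = wgt_genome.truth_by_id()
        genes = sorted(truth)
        fam = {g: (truth[g].family, truth[g].pme_type) for g in genes}
        matrix, designed = simulate_expression(genes, fam, cfg)
        calls = call_high_expression(matrix, 10.0)
        flower = calls.calls[cfg.family_high_tissue]
        assert all(bool(flower[g]) == designed[g] for g in genes)

    def test_designed_high_mostly_recovered_under_noise(self):
        cfg = SimulationConfig(n_genes=200, n_pg=40, n_pme=40, seed=9)
        ancestor = simulate_ancestral_genome(cfg)
        genes = [g.id for g in ancestor.annotation.genes]
        matrix, designed = simulate_expression(genes, ancestor.family, cfg)
        calls = call_high_expression(matrix, 10.0)
        high = calls.calls[cfg.family_high_tissue]
        designed_ids = [g for g, d in designed.items() if d]
        frac = sum(bool(high[g]) for g in designed_ids) / len(designed_ids)
        assert frac >= 0.9

    def test_all_background_has_no_specific_genes(self, small_config):
        matrix, designed = simulate_expression(["a", "b", "c"], {}, small_config)
        calls = call_high_expression(matrix, 10.0 * small_config.high_mean)
        assert not calls.calls.any().any()


class TestTruthTable:
    def test_round_trip(self, tmp_path, wgt_genome):
        path = tmp_path / "truth.tsv"
        write_truth_table(wgt_genome.truth, path)
        again = read_truth_table(path)
        assert [(r.gene_id, r.fate, r.subgenome) for r in again] == [
            (r.gene_id, r.fate, r.subgenome) for r in wgt_genome.truth
        ]

    def test_every_retained_gene_has_one_parent(self, wgt_genome, ancestor):
        for rec in wgt_genome.truth:
            if rec.fate == "retained":
                assert rec.parent in ancestor.annotation
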