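import logging

import numpy as np
import pytest

from regulonscan.genome import Gene, Genome, ScanConfig, UpstreamRegion, revcomp
from regulonscan.orthology import OrthologTable
from regulonscan.pwm import SiteSet, build_pwm, instantiate_consensus, score
from regulonscan.scan import (CalibrationResult, SiteHit, best_scores_per_gene,
                              calibrate_threshold, collect_hits, rescue_weak_sites,
                              scan_gene, scan_region)

from .conftest import APHS_CONSENSUS


@pytest.fixture(scope="module")
def aphs_motif():
    rng = np.random.default_rng(4)
    sites = tuple(instantiate_consensus(APHS_CONSENSUS, rng) for _ in range(40))
    return build_pwm(SiteSet("AphS", sites))


def region_of(seq, offset=350):
    return UpstreamRegion("g", "c", (0, len(seq)), seq, offset)


class TestScanRegion:
    def test_planted_consensus_is_top_hit(self, aphs_motif):
        rng = np.random.default_rng(8)
        bg = "".join(rng.choice(list("ACGT"), size=400))
        site = "".join("ACGT"[i] for i in aphs_motif.weights.argmax(axis=0))
        pos = 350 - 120  # index for a hit at position -120
        seq = bg[:pos] + site + bg[pos + len(site):]
        hits = scan_region(aphs_motif, region_of(seq))
        assert hits[0].position == -120
        assert hits[0].score == pytest.approx(aphs_motif.max_score())

    def test_palindromic_motif_strand_symmetry(self, aphs_motif):
        assert aphs_motif.palindromic
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd = sorted(round(h.score, 9) for h in scan_region(aphs_motif, region_of(seq, 150)))
        rev = sorted(round(h.score, 9) for h in
                     scan_region(aphs_motif, region_of(revcomp(seq), 150)))
        assert fwd == rev

    def test_all_n_region_scores_zero(self, aphs_motif):
        hits = scan_region(aphs_motif, region_of("N" * 100, 50))
        assert hits and all(h.score == 0.0 for h in hits)

    def test_short_region_yields_no_hits(self, aphs_motif):
        assert scan_region(aphs_motif, region_of("ACGT", 2)) == []

    def test_deterministic_tie_break(self, aphs_motif):
        seq = "N" * 60
        hits = scan_region(aphs_motif, region_of(seq, 30))
        positions = [h.position for h in hits]
        assert positions == sorted(positions)


class TestCalibration:
    def test_planted_genes_admitted_within_bound(self, clean_dataset):
        genomes, table, truth = clean_dataset
        sites = tuple(s.sequence for s in truth.planted_sites)
        motif = build_pwm(SiteSet("AphS", sites))
        planted_genes = {s.gene_id for s in truth.planted_sites}
        cal = calibrate_threshold(motif, genomes)
        for genome in genomes:
            best = best_scores_per_gene(motif, genome)
            admitted = {g for g, s in best.items() if s >= cal.threshold}
            n = len(genome.genes)
            assert len(admitted) <= 0.05 * n
            assert planted_genes & set(best) <= set(best)
            assert {g for g in admitted} >= {g for g in planted_genes if g in best}

    def test_max_fraction_one_admits_everything(self, toy_genome, aphs_motif):
        config = ScanConfig(max_hit_fraction=1.0)
        cal = calibrate_threshold(aphs_motif, [toy_genome], config=config)
        best = best_scores_per_gene(aphs_motif, toy_genome, config)
        assert cal.threshold == pytest.approx(min(best.values()))
        assert cal.per_genome_hit_fraction["toy"] == 1.0

    def test_threshold_monotone_in_fraction(self, clean_dataset):
        genomes, table, truth = clean_dataset
        sites = tuple(s.sequence for s in truth.planted_sites)
        motif = build_pwm(SiteSet("AphS", sites))
        best = {g.genome_id: best_scores_per_gene(motif, g) for g in genomes}
        prev = None
        for frac in (0.02, 0.05, 0.10, 0.25, 0.5):
            cal = calibrate_threshold(motif, genomes,
                                      config=ScanConfig(max_hit_fraction=frac),
                                      best_scores=best)
            if prev is not None:
                assert cal.threshold <= prev + 1e-12
            prev = cal.threshold

    def test_constant_motif_rejected(self, toy_genome):
        from regulonscan.pwm import _finalize, uniform_background
        flat = _finalize("flat", np.full((4, 6), 0.25), uniform_background(), 0.0, False)
        with pytest.raises(ValueError):
            calibrate_threshold(flat, [toy_genome])

    def test_training_conflicts_reported(self, clean_dataset):
        genomes, table, truth = clean_dataset
        sites = tuple(s.sequence for s in truth.planted_sites)
        motif = build_pwm(SiteSet("AphS", sites))
        # a deliberately unrelated gene cannot stay above threshold
        stray = genomes[0].genes[0].gene_id
        training = {genomes[0].genome_id: [stray]}
        cal = calibrate_threshold(motif, genomes, training)
        if (genomes[0].genome_id, stray) in cal.conflicts:
            assert cal.training_coverage < 1.0


def _mk_hit(genome, gene, pos, score_val, t, category="candidate"):
    return SiteHit("tf", genome, gene, pos, "+", score_val, score_val / t, category)


class TestRescue:
    def setup_method(self):
        self.t = 10.0
        self.cal = CalibrationResult("tf", self.t, {}, {}, 1.0, ())
        self.table = OrthologTable()
        for genome in ("g1", "g2"):
            self.table.add("grpX", genome, f"{genome}_x")
            self.table.add("grpY", genome, f"{genome}_y")

    def test_clause_a_positional_support(self, caplog):
        hits = [
            _mk_hit("g1", "g1_x", -150, 12.0, self.t, "strong"),
            _mk_hit("g2", "g2_x", -145, 9.3, self.t),
            _mk_hit("g2", "g2_x", -30, 9.6, self.t),  # stronger competitor, blocks (b)
        ]
        with caplog.at_level(logging.INFO, logger="regulonscan.scan"):
            rescued = rescue_weak_sites(hits, self.table, self.cal, ScanConfig())
        assert [(h.position, h.clause) for h in rescued if h.position == -145] == [(-145, "a")]
        assert any("clause (a)" in rec.message for rec in caplog.records)

    def test_clause_b_no_stronger_competitor(self):
        hits = [_mk_hit("g1", "g1_y", -80, 9.3, self.t)]
        rescued = rescue_weak_sites(hits, self.table, self.cal, ScanConfig())
        assert len(rescued) == 1 and rescued[0].clause == "b"

    def test_competing_site_blocks_clause_b(self):
        hits = [
            _mk_hit("g1", "g1_y", -80, 9.3, self.t),
            _mk_hit("g1", "g1_y", -200, 9.8, self.t),
        ]
        rescued = rescue_weak_sites(hits, self.table, self.cal, ScanConfig())
        assert [(h.position, h.clause) for h in rescued] == [(-200, "b")]

    def test_below_rescue_floor_never_rescued(self):
        # collect_hits drops sub-floor scores; rescue must also never admit one
        hits = [_mk_hit("g1", "g1_y", -80, 8.5, self.t)]
        hits = [h for h in hits if h.score >= 0.9 * self.t]
        assert rescue_weak_sites(hits, self.table, self.cal, ScanConfig()) == []

    def test_strong_hits_untouched(self, clean_dataset):
        genomes, table, truth = clean_dataset
        sites = tuple(s.sequence for s in truth.planted_sites)
        motif = build_pwm(SiteSet("AphS", sites))
        cal = calibrate_threshold(motif, genomes)
        hits = collect_hits(motif, genomes, cal)
        strong_before = {(h.genome_id, h.gene_id, h.position, h.strand, h.score)
                         for h in hits if h.category == "strong"}
        rescued = rescue_weak_sites(hits, table, cal)
        assert all(h.category == "weak_rescued" for h in rescued)
        strong_after = {(h.genome_id, h.gene_id, h.position, h.strand, h.score)
                        for h in hits if h.category == "strong"}
        assert strong_before == strong_after


class TestBoundInvariant:
    def test_hit_fraction_bound_holds_everywhere(self, planted_dataset):
        genomes, table, truth = planted_dataset
        sites = tuple(s.sequence for s in truth.planted_sites if s.category == "strong")
        motif = build_pwm(SiteSet("AphS", sites))
        cal = calibrate_threshold(motif, genomes)
        for frac in cal.per_genome_hit_fraction.values():
            assert frac <= 0.05 + 1e-12

    def test_scan_determinism(self, toy_genome, aphs_motif):
        h1 = scan_gene(aphs_motif, toy_genome.gene("gA"), toy_genome)
        h2 = scan_gene(aphs_motif, toy_genome.gene("gA"), toy_genome)
        assert h1 == h2
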