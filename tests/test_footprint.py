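from functools import lru_cache

import numpy as np
import pytest

from regulonscan.footprint import (GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH,
                                   _make_aligner, align_regions,
                                   conserved_windows)
from regulonscan.genome import extract_upstream
from regulonscan.synthetic import OperonSpec, PlantSpec, generate_dataset

from .conftest import APHS_CONSENSUS


def exhaustive_best_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion over
    every alignment path (independent of any aligner library)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            g = GAP_EXTEND if prev == "A" else GAP_OPEN
            best = max(best, g + rec(i + 1, j, "A"))
        if j < len(b):
            g = GAP_EXTEND if prev == "B" else GAP_OPEN
            best = max(best, g + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


class TestAlignRegions:
    def test_identical_regions_gapless(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        aln = align_regions({"a": seq, "b": seq})
        assert aln.n_columns == 400
        assert "-" not in aln.rows["a"] + aln.rows["b"]

    def test_single_gap_example(self):
        aln = align_regions({"a": "ACGTACGT", "b": "ACGACGT"})
        assert aln.n_columns == 8
        assert aln.rows["a"] == "ACGTACGT"
        assert aln.rows["b"].count("-") == 1

    def test_three_substituted_copies_gapless(self):
        base = list("ACGTACGTACGTACGTACGT")
        rows = {}
        for gid, pos in (("a", 3), ("b", 10), ("c", 17)):
            s = base.copy()
            s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            rows[gid] = "".join(s)
        aln = align_regions(rows)
        assert aln.n_columns == len(base)
        assert all("-" not in r for r in aln.rows.values())

    def test_ungapping_reproduces_input(self):
        rng = np.random.default_rng(1)
        regions = {f"g{i}": "".join(rng.choice(list("ACGT"), size=rng.integers(50, 80)))
                   for i in range(4)}
        aln = align_regions(regions)
        for gid, seq in regions.items():
            assert aln.ungapped(gid) == seq

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            align_regions({"a": "ACGT"})

    def test_pairwise_scores_match_exhaustive_enumeration(self):
        """The aligner's optima equal exhaustive-enumeration optima on short
        sequences under the stated scoring scheme."""
        rng = np.random.default_rng(9)
        aligner = _make_aligner()
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 13)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 13)))
            assert aligner.score(a, b) == pytest.approx(exhaustive_best_score(a, b))


class TestConservedWindows:
    def test_identical_rows_single_full_window(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        aln = align_regions({"a": seq, "b": seq, "c": seq})
        windows = conserved_windows(aln)
        assert len(windows) == 1
        assert (windows[0].col_start, windows[0].col_end) == (0, 400)
        assert windows[0].mean_identity == 1.0

    def test_planted_site_recovered_across_seeds(self):
        """Ancestor-derived groups (substitution rate 0.3 outside a verbatim
        14-mer plant) always yield a window overlapping the planted site."""
        for seed in range(1, 6):
            genomes, table, truth = generate_dataset(
                3, 12, OperonSpec(), 0.5,
                [PlantSpec("T", APHS_CONSENSUS, 1, sites_per_region=1)], seed=seed)
            group = sorted(truth.regulon_membership["T"])[0]
            regions, positions = {}, {}
            for g in genomes:
                gene_id = table.genes_of(group)[g.genome_id][0]
                region = extract_upstream(g.gene(gene_id), g)
                regions[g.genome_id] = region.sequence
                site = [s for s in truth.planted_sites if s.gene_id == gene_id][0]
                positions[g.genome_id] = region.gene_start_offset + site.position
            aln = align_regions(regions, group)
            windows = conserved_windows(aln)
            assert windows, f"no window at seed {seed}"
            hit = False
            for w in windows:
                for gid, (s, e) in w.row_intervals.items():
                    if s < positions[gid] + 14 and e > positions[gid]:
                        hit = True
            assert hit, f"no window overlaps the planted site at seed {seed}"

    def test_unrelated_sequences_rarely_conserved(self):
        """i.i.d. rows should essentially never show a 10-column 90% identical
        run; allow at most 1 window over 100 seeds."""
        found = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = {f"g{i}": "".join(rng.choice(list("ACGT"), size=120))
                    for i in range(3)}
            aln = align_regions(rows)
            found += bool(conserved_windows(aln, 0.9, 10))
        assert found <= 1

    def test_windows_disjoint_sorted_and_mapped(self, clean_dataset):
        genomes, table, truth = clean_dataset
        group = sorted(truth.regulon_membership["AphS"])[0]
        regions = {}
        for g in genomes:
            gene_id = table.genes_of(group)[g.genome_id][0]
            regions[g.genome_id] = extract_upstream(g.gene(gene_id), g).sequence
        aln = align_regions(regions, group)
        windows = conserved_windows(aln, 0.8, 5)
        for w1, w2 in zip(windows, windows[1:]):
            assert w1.col_end <= w2.col_start
        for w in windows:
            lengths = {e - s for (s, e) in w.row_intervals.values()}
            assert lengths == {w.width}

    def test_monotonicity_of_calling_rule(self, clean_dataset):
        """Lowering min_identity or min_window never loses a window: every
        stricter-parameter window is contained in a looser-parameter one."""
        genomes, table, truth = clean_dataset
        group = sorted(truth.regulon_membership["AphS"])[1]
        regions = {}
        for g in genomes:
            gene_id = table.genes_of(group)[g.genome_id][0]
            regions[g.genome_id] = extract_upstream(g.gene(gene_id), g).sequence
        aln = align_regions(regions, group)
        strict = conserved_windows(aln, 0.95, 12)
        loose = conserved_windows(aln, 0.85, 8)
        for w in strict:
            assert any(l.col_start <= w.col_start and l.col_end >= w.col_end
                       for l in loose)
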