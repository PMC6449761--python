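import pytest

from regulonscan.genome import Gene, Genome, ScanConfig
from regulonscan.orthology import OrthologTable
from regulonscan.regulon import (assemble_regulon, check_operon_persistence,
                                 detect_divergons, infer_operons)
from regulonscan.scan import SiteHit


def linear_genome(spec, genome_id="t", contig_len=20000):
    """spec: list of (gene_id, start, length, strand)."""
    genes = [Gene(g, "c", s, s + ln, st) for g, s, ln, st in spec]
    return Genome(genome_id, {"c": "A" * contig_len}, genes)


def hit(genome, gene, pos=-100, score=12.0, category="strong", tf="tf"):
    return SiteHit(tf, genome, gene, pos, "+", score, 1.2, category)


class TestInferOperons:
    def test_gaps_under_cap_merge(self):
        g = linear_genome([("a", 1000, 500, "+"), ("b", 1650, 500, "+"),
                           ("c", 2300, 500, "+")])  # gaps 150, 150
        ops = infer_operons(g)
        assert [op.gene_ids for op in ops] == [("a", "b", "c")]
        assert ops[0].leader == "a"

    def test_gap_over_cap_splits(self):
        g = linear_genome([("a", 1000, 500, "+"), ("b", 1650, 500, "+"),
                           ("c", 2400, 500, "+")])  # gaps 150, 250
        ops = infer_operons(g)
        assert [op.gene_ids for op in ops] == [("a", "b"), ("c",)]

    def test_strand_flip_splits(self):
        g = linear_genome([("a", 1000, 500, "+"), ("b", 1550, 500, "+"),
                           ("c", 2100, 500, "-")])  # all gaps 50
        ops = infer_operons(g)
        assert [op.gene_ids for op in ops] == [("a", "b"), ("c",)]

    def test_minus_strand_transcription_order_and_leader(self):
        g = linear_genome([("a", 1000, 500, "-"), ("b", 1600, 500, "-")])
        ops = infer_operons(g)
        assert ops[0].gene_ids == ("b", "a")  # 5'-most gene of a '-' run is rightmost
        assert ops[0].leader == "b"

    def test_partition_property(self, planted_dataset):
        genomes, _, _ = planted_dataset
        for genome in genomes:
            ops = infer_operons(genome)
            flat = [g for op in ops
                    for g in (op.gene_ids if op.strand == "+" else reversed(op.gene_ids))]
            assert sorted(flat) == sorted(g.gene_id for g in genome.genes)
            assert len(flat) == len(set(flat))

    def test_limit_cases(self):
        spec = [("a", 1000, 500, "+"), ("b", 1501, 500, "+"), ("c", 2100, 500, "+")]
        g = linear_genome(spec)
        singles = infer_operons(g, ScanConfig(operon_max_gap=0))
        assert [op.gene_ids for op in singles] == [("a",), ("b",), ("c",)]
        merged = infer_operons(g, ScanConfig(operon_max_gap=10**9))
        assert [op.gene_ids for op in merged] == [("a", "b", "c")]

    def test_overlapping_genes_always_merge(self):
        g = linear_genome([("a", 1000, 500, "+"), ("b", 1400, 500, "+")])
        assert [op.gene_ids for op in infer_operons(g, ScanConfig(operon_max_gap=0))] == \
            [("a", "b")]


class TestPersistence:
    def _table(self, adjacencies_per_genome):
        table = OrthologTable()
        for genome_id, groups in adjacencies_per_genome.items():
            for grp in groups:
                table.add(grp, genome_id, f"{genome_id}_{grp}")
        return table

    def test_supported_and_unsupported(self):
        operons = {}
        table = OrthologTable()
        for i, genome_id in enumerate(["g1", "g2", "g3", "g4", "g5"]):
            groups = ["A", "B"] if i < 3 else ["A"]
            for grp in groups:
                table.add(grp, genome_id, f"{genome_id}_{grp}")
            from regulonscan.regulon import Operon
            operons[genome_id] = [Operon(genome_id, "c",
                                         tuple(f"{genome_id}_{g}" for g in groups), "+")]
        support = check_operon_persistence(operons, table, min_genomes=2)
        assert support[("A", "B")] is True
        support1 = check_operon_persistence(
            {"g1": operons["g1"], "g4": operons["g4"]}, table, min_genomes=2)
        assert support1.get(("A", "B"), False) is False

    def test_insertion_skipped_in_adjacency(self):
        """A genome-specific unmapped gene inside an operon does not break the
        flanking conserved adjacency."""
        from regulonscan.regulon import Operon
        table = OrthologTable()
        for genome_id in ("g1", "g2"):
            table.add("A", genome_id, f"{genome_id}_A")
            table.add("B", genome_id, f"{genome_id}_B")
        operons = {
            "g1": [Operon("g1", "c", ("g1_A", "g1_B"), "+")],
            "g2": [Operon("g2", "c", ("g2_A", "g2_ins", "g2_B"), "+")],
        }
        support = check_operon_persistence(operons, table, 2)
        assert support[("A", "B")] is True


class TestAssembleRegulon:
    def _setup(self):
        table = OrthologTable()
        operons = {}
        genomes = ["g1", "g2", "g3", "g4", "g5"]
        from regulonscan.regulon import Operon
        for genome_id in genomes:
            ops = []
            for grp_pair in (("A", "B"), ("C",), ("D",)):
                gene_ids = tuple(f"{genome_id}_{g}" for g in grp_pair)
                for g in grp_pair:
                    table.add(g, genome_id, f"{genome_id}_{g}")
                ops.append(Operon(genome_id, "c", gene_ids, "+"))
            operons[genome_id] = ops
        return table, operons

    def test_support_counting_and_extension(self):
        table, operons = self._setup()
        hits = [hit(g, f"{g}_A") for g in ("g1", "g2", "g3")]
        reg = assemble_regulon("tf", hits, table, operons)
        assert reg.support == {"A": 3}
        assert set(reg.core) == {"A"}
        # operon extension pulls in B behind leader A
        for g in ("g1", "g2", "g3"):
            assert reg.extended[g] == {f"{g}_A", f"{g}_B"}

    def test_singleton_excluded_from_core(self):
        table, operons = self._setup()
        hits = [hit("g1", "g1_C")]
        reg = assemble_regulon("tf", hits, table, operons)
        assert reg.core == {}
        assert set(reg.singletons) == {"C"}

    def test_weak_rescued_counts_unless_strict(self):
        table, operons = self._setup()
        hits = [hit("g1", "g1_D"), hit("g2", "g2_D", category="weak_rescued")]
        assert set(assemble_regulon("tf", hits, table, operons).core) == {"D"}
        strict = assemble_regulon("tf", hits, table, operons, strict=True)
        assert strict.core == {}

    def test_genome_order_invariance(self):
        table, operons = self._setup()
        hits = [hit(g, f"{g}_A") for g in ("g1", "g2")] + [hit("g3", "g3_C")]
        r1 = assemble_regulon("tf", hits, table, operons)
        r2 = assemble_regulon("tf", list(reversed(hits)), table,
                              dict(reversed(list(operons.items()))))
        assert r1.support == r2.support and r1.extended == r2.extended

    def test_core_monotone_in_min_genomes(self):
        table, operons = self._setup()
        hits = ([hit(g, f"{g}_A") for g in ("g1", "g2", "g3")]
                + [hit(g, f"{g}_C") for g in ("g1", "g2")])
        prev = None
        for m in (1, 2, 3, 4):
            reg = assemble_regulon("tf", hits, table, operons,
                                   ScanConfig(min_genomes=m))
            if prev is not None:
                assert set(reg.core) <= prev
            prev = set(reg.core)

    def test_extension_respects_persistence_split(self):
        from regulonscan.regulon import Operon
        table = OrthologTable()
        operons = {}
        # adjacency A-B persists in g1+g2; B-X exists only in g1
        for genome_id, groups in (("g1", ["A", "B", "X"]), ("g2", ["A", "B"])):
            for g in groups:
                table.add(g, genome_id, f"{genome_id}_{g}")
            operons[genome_id] = [Operon(genome_id, "c",
                                         tuple(f"{genome_id}_{g}" for g in groups), "+")]
        hits = [hit("g1", "g1_A"), hit("g2", "g2_A")]
        reg = assemble_regulon("tf", hits, table, operons)
        assert reg.extended["g1"] == {"g1_A", "g1_B"}  # X cut off at the split
        assert reg.extended["g2"] == {"g2_A", "g2_B"}


class TestDivergons:
    def test_head_to_head_with_shared_hit(self):
        g = linear_genome([("a", 1000, 500, "-"), ("b", 1800, 500, "+")])
        shared = hit("t", "b", pos=-150)  # b.start + (-150) = 1650, inside overlap
        out = detect_divergons(g, [shared])
        assert len(out) == 1
        a_id, b_id, hits_found = out[0]
        assert (a_id, b_id) == ("a", "b")
        assert hits_found == [shared]

    def test_tail_to_tail_not_a_divergon(self):
        g = linear_genome([("a", 1000, 500, "+"), ("b", 1800, 500, "-")])
        assert detect_divergons(g, []) == []

    def test_wide_pair_windows_do_not_overlap(self):
        g = linear_genome([("a", 1000, 500, "-"), ("b", 2500, 500, "+")])
        # intergenic span 1000 > 2 * 350: no shared window
        assert detect_divergons(g, []) == []
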