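"""Operon inference, cross-genome persistence, regulon assembly, divergons.

Operons are strings of same-strand genes with intergenic distances below a
cap (default 200 nt); adjacencies conserved in several genomes mark
persistent transcription units.  An ortholog group joins a regulon's core
when its genes are preceded by candidate binding sites in at least
``min_genomes`` genomes; regulons are then extended to include all genes in
the (persistence-checked) operons downstream of each hit-bearing gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Gene, Genome, ScanConfig, extract_upstream
from .orthology import OrthologTable
from .scan import SiteHit

__all__ = [
    "Operon",
    "Regulon",
    "infer_operons",
    "check_operon_persistence",
    "assemble_regulon",
    "detect_divergons",
]


@dataclass(frozen=True)
class Operon:
    """Genes of one transcription unit in transcription order; the leader is
    the 5'-most gene, whose upstream region carries any regulatory sites."""

    genome_id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    strand: str

    @property
    def leader(self) -> str:
        return self.gene_ids[0]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class Regulon:
    tf_name: str
    # group_id -> {genome_id -> [SiteHit, ...]} for core member groups
    core: dict[str, dict[str, list[SiteHit]]] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)  # group -> #genomes with hits
    # genome_id -> set of gene ids (hit genes plus operon extension)
    extended: dict[str, set[str]] = field(default_factory=dict)
    singletons: dict[str, dict[str, list[SiteHit]]] = field(default_factory=dict)

    @property
    def core_groups(self) -> set[str]:
        return set(self.core)


def infer_operons(genome: Genome, config: ScanConfig = ScanConfig()) -> list[Operon]:
    """Partition genes into operons: maximal same-contig, same-strand runs
    split wherever the intergenic gap exceeds ``operon_max_gap``.

    Gaps are ``next.start - previous.end`` in genomic order; overlapping genes
    (negative gap) always merge.  For '-' strand runs the transcription order
    is the reverse of the genomic order and the leader is the 3'-most gene in
    genomic coordinates.
    """
    operons: list[Operon] = []
    run: list[Gene] = []

    def flush() -> None:
        if not run:
            return
        genes = run if run[0].strand == "+" else list(reversed(run))
        operons.append(Operon(genome.genome_id, run[0].contig_id,
                              tuple(g.gene_id for g in genes), run[0].strand))
        run.clear()

    for gene in genome.genes:  # sorted by (contig, start)
        if run:
            prev = run[-1]
            same = (gene.contig_id == prev.contig_id and gene.strand == prev.strand
                    and gene.start - prev.end <= config.operon_max_gap)
            if not same:
                flush()
        run.append(gene)
    flush()
    return operons


def check_operon_persistence(
    operons_per_genome: dict[str, list[Operon]],
    ortholog_table: OrthologTable,
    min_genomes: int = 2,
) -> dict[tuple[str, str], bool]:
    """Which ordered ortholog-group adjacencies inside operons persist in at
    least ``min_genomes`` genomes.

    Adjacency is evaluated on ortholog-group order in transcription order,
    skipping genes without a group assignment, so a genome-specific insertion
    does not break the flanking conserved adjacency.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for genome_id, operons in operons_per_genome.items():
        for op in operons:
            groups = [g for g in (ortholog_table.group_of(genome_id, gid)
                                  for gid in op.gene_ids) if g is not None]
            for a, b in zip(groups, groups[1:]):
                seen.setdefault((a, b), set()).add(genome_id)
    return {adj: len(genomes) >= min_genomes for adj, genomes in seen.items()}


def _extend_from(gene_id: str, operon: Operon, genome_id: str,
                 ortholog_table: OrthologTable,
                 persistence: dict[tuple[str, str], bool]) -> list[str]:
    """Genes of the candidate transcription unit starting at ``gene_id``:
    downstream through the operon while adjacencies stay persistent."""
    idx = operon.gene_ids.index(gene_id)
    members = [gene_id]
    prev_group = ortholog_table.group_of(genome_id, gene_id)
    for nxt in operon.gene_ids[idx + 1:]:
        nxt_group = ortholog_table.group_of(genome_id, nxt)
        if prev_group is not None and nxt_group is not None:
            if not persistence.get((prev_group, nxt_group), False):
                break
        members.append(nxt)
        if nxt_group is not None:
            prev_group = nxt_group
    return members


def assemble_regulon(
    tf_name: str,
    hits: list[SiteHit],
    ortholog_table: OrthologTable,
    operons_per_genome: dict[str, list[Operon]],
    config: ScanConfig = ScanConfig(),
    strict: bool = False,
) -> Regulon:
    """Assemble the cross-genome regulon from categorized site hits.

    Core members are ortholog groups whose genes carry a ``strong`` (or, by
    default, also ``weak_rescued``) hit in at least ``min_genomes`` genomes;
    ``strict=True`` counts strong hits only.  Groups with hits in exactly one
    genome are kept aside as singleton candidates.  Each hit-bearing gene
    seeds a transcription unit extended downstream through its operon, with
    unsupported adjacencies (not persisting in ``min_genomes`` genomes)
    splitting the extension.
    """
    categories = {"strong"} if strict else {"strong", "weak_rescued"}
    use = [h for h in hits if h.category in categories]
    persistence = check_operon_persistence(operons_per_genome, ortholog_table,
                                           config.min_genomes)
    operon_of: dict[tuple[str, str], Operon] = {}
    for genome_id, operons in operons_per_genome.items():
        for op in operons:
            for gid in op.gene_ids:
                operon_of[(genome_id, gid)] = op

    by_group: dict[str, dict[str, list[SiteHit]]] = {}
    for h in sorted(use, key=lambda h: (h.genome_id, h.gene_id, -h.score, h.position)):
        group = ortholog_table.group_of(h.genome_id, h.gene_id)
        if group is None:
            continue
        by_group.setdefault(group, {}).setdefault(h.genome_id, []).append(h)

    regulon = Regulon(tf_name)
    for group in sorted(by_group):
        evidence = by_group[group]
        n = len(evidence)
        if n >= config.min_genomes:
            regulon.core[group] = evidence
            regulon.support[group] = n
        elif n == 1:
            regulon.singletons[group] = evidence

    for group, evidence in regulon.core.items():
        for genome_id, gene_hits in evidence.items():
            gene_ids = {h.gene_id for h in gene_hits}
            members = regulon.extended.setdefault(genome_id, set())
            for gene_id in gene_ids:
                op = operon_of.get((genome_id, gene_id))
                if op is None:
                    members.add(gene_id)
                else:
                    members.update(_extend_from(gene_id, op, genome_id,
                                                ortholog_table, persistence))
    return regulon


def detect_divergons(
    genome: Genome,
    hits: list[SiteHit],
    config: ScanConfig = ScanConfig(),
) -> list[tuple[str, str, list[SiteHit]]]:
    """Head-to-head divergently transcribed gene pairs with shared hits.

    A pair is adjacent genes on one contig, the left one on '-' and the right
    one on '+', whose upstream scan windows overlap; any hit lying in the
    overlap of both windows is attributed to both genes.
    """
    def abs_interval(h: SiteHit, gene: Gene, L: int) -> tuple[int, int]:
        if gene.strand == "+":
            start = gene.start + h.position
        else:
            start = gene.end - h.position - L
        return start, start + L

    by_gene: dict[str, list[SiteHit]] = {}
    for h in hits:
        if h.genome_id == genome.genome_id:
            by_gene.setdefault(h.gene_id, []).append(h)

    out = []
    genes = genome.genes
    for a, b in zip(genes, genes[1:]):
        if a.contig_id != b.contig_id or not (a.strand == "-" and b.strand == "+"):
            continue
        ra = extract_upstream(a, genome, config).interval
        rb = extract_upstream(b, genome, config).interval
        lo, hi = max(ra[0], rb[0]), min(ra[1], rb[1])
        if lo >= hi:
            continue
        shared = []
        for gene in (a, b):
            for h in by_gene.get(gene.gene_id, ()):
                L = 1  # positions suffice; use site start only
                s, _ = abs_interval(h, gene, L)
                if lo <= s < hi:
                    shared.append(h)
        out.append((a.gene_id, b.gene_id, shared))
    return out
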