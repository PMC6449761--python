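"""Synthetic multi-genome datasets with planted regulons and full ground truth.

The generator emulates the comparative setting the reconstruction procedure
assumes: several related genomes sharing ortholog families, operonic gene
organization (same-strand runs with short intergenic gaps, long gaps between
transcription units), and upstream regions derived from a common ancestor so
that phylogenetic footprinting sees genuine conservation.  Transcription
factor binding sites are planted into the upstream regions of selected
ortholog groups as instantiations of an IUPAC consensus, copied verbatim
across genomes (substitution rate zero inside sites), with a configurable
fraction deliberately weakened to score just below the calibrated threshold
— the scenario the weak-site rescue rule addresses.

The gene/gap layout is identical across genomes (sequence content diverges
by per-base substitution), so operon organization trivially persists across
genomes, as the comparative operon rule assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Gene, Genome, ScanConfig, revcomp
from .orthology import OrthologTable
from .pwm import SiteSet, build_pwm, instantiate_consensus, score
from .scan import best_scores_per_gene, calibrate_threshold

__all__ = [
    "PlantSpec",
    "OperonSpec",
    "PlantedSite",
    "SyntheticTruth",
    "generate_dataset",
    "plant_divergon",
]

logger = logging.getLogger(__name__)
_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """The requested plant cannot fit the scan window / layout."""


class LayoutError(ValueError):
    """Genes do not have the geometric arrangement the operation requires."""


@dataclass(frozen=True)
class PlantSpec:
    """What to plant for one transcription factor."""

    tf_name: str
    consensus: str
    n_target_groups: int
    sites_per_region: int | tuple[int, int] = 2
    weak_fraction: float = 0.0
    site_position_range: tuple[int, int] = (-300, -40)  # relative to gene start

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ConfigurationError("consensus must be non-empty")
        if not 0.0 <= self.weak_fraction <= 1.0:
            raise ConfigurationError("weak_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class OperonSpec:
    """Distributions of operon run lengths, intergenic gaps and gene lengths."""

    run_length_range: tuple[int, int] = (1, 3)
    intra_gap_range: tuple[int, int] = (20, 150)     # below the operon cap
    inter_gap_range: tuple[int, int] = (450, 700)    # above the cap, fits the window
    gene_length_range: tuple[int, int] = (600, 1200)


@dataclass(frozen=True)
class PlantedSite:
    tf_name: str
    genome_id: str
    gene_id: str
    group_id: str
    position: int  # site start relative to gene start, negative = upstream
    strand: str    # relative to the gene; planted sites read in gene sense
    sequence: str
    category: str  # strong | weak


@dataclass
class SyntheticTruth:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    regulon_membership: dict[str, set[str]] = field(default_factory=dict)
    operon_layout: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def sites_of(self, tf_name: str) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.tf_name == tf_name]


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: set[int] | None = None) -> str:
    """Per-base substitution at ``rate``, uniform among the other three bases;
    indices in ``protected`` are copied verbatim."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    idx = lut[codes]
    mask = rng.random(len(seq)) < rate
    if protected:
        mask[list(protected)] = False
    shift = rng.integers(1, 4, size=len(seq))
    new_idx = np.where(mask, (idx + shift) % 4, idx)
    return "".join(_BASES[new_idx])


def generate_dataset(
    n_genomes: int,
    n_groups: int,
    operon_spec: OperonSpec = OperonSpec(),
    gc_content: float = 0.55,
    plants: list[PlantSpec] = (),
    seed: int = 0,
    substitution_rate: float = 0.3,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[Genome], OrthologTable, SyntheticTruth]:
    """Generate genomes with shared ortholog families and planted regulons.

    Returns the genomes, the ortholog table realized by their gene
    complements, and the ground truth (planted sites, regulon membership,
    operon layout).  Deterministic for a fixed seed.  Weakened site copies
    are targeted into the score band ``[rescue_factor * t, t)`` of a
    threshold ``t`` calibrated, inside the generator, from a PWM built on the
    strong planted sites, iterating weakening and recalibration to a fixed
    point.
    """
    if n_genomes < 2:
        raise ConfigurationError("need at least 2 genomes")
    if not 0 < gc_content < 1:
        raise ConfigurationError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    group_ids = [f"G{i:04d}" for i in range(n_groups)]

    # ---- shared layout: runs of groups, strands, lengths, gaps -------------
    runs: list[list[str]] = []
    i = 0
    lo, hi = operon_spec.run_length_range
    while i < n_groups:
        k = int(rng.integers(lo, hi + 1))
        runs.append(group_ids[i:i + k])
        i += k
    run_strands = [str(rng.choice(["+", "-"])) for _ in runs]
    glo, ghi = operon_spec.gene_length_range
    gene_len = {g: int(rng.integers(glo, ghi + 1)) for g in group_ids}
    ilo, ihi = operon_spec.inter_gap_range
    if ilo <= config.operon_max_gap:
        raise ConfigurationError("inter-run gaps must exceed operon_max_gap")
    gap_lo = max(ilo, config.upstream_span + 20)
    leader_gap = {ri: int(rng.integers(gap_lo, max(ihi, gap_lo) + 1))
                  for ri in range(len(runs))}
    wlo, whi = operon_spec.intra_gap_range
    intra_gap = {(ri, j): int(rng.integers(wlo, whi + 1))
                 for ri, run in enumerate(runs) for j in range(1, len(run))}

    # ---- ancestral sequences ----------------------------------------------
    anc_gene = {g: _random_seq(gene_len[g], gc_content, rng) for g in group_ids}
    anc_leader_gap = {ri: _random_seq(leader_gap[ri], gc_content, rng) for ri in range(len(runs))}
    anc_intra_gap = {key: _random_seq(n, gc_content, rng) for key, n in intra_gap.items()}

    # ---- choose targets and plant into ancestors ---------------------------
    truth = SyntheticTruth()
    leaders = {run[0]: ri for ri, run in enumerate(runs)}
    # (run_index, offset_in_gap, instantiation, tf, slot) per planted site
    plants_by_run: dict[int, list[tuple[int, str, str, int]]] = {}
    target_groups_of: dict[str, list[str]] = {}
    for spec in plants:
        L = len(spec.consensus)
        plo, phi = spec.site_position_range
        if phi - plo < L or plo < -config.upstream_span:
            raise ConfigurationError(f"{spec.tf_name}: window too small for consensus")
        candidates = [g for g in leaders if g not in
                      {t for ts in target_groups_of.values() for t in ts}]
        if spec.n_target_groups > len(candidates):
            raise ConfigurationError(f"{spec.tf_name}: not enough operon leaders to target")
        chosen = sorted(str(g) for g in rng.choice(candidates, size=spec.n_target_groups, replace=False))
        target_groups_of[spec.tf_name] = list(chosen)
        truth.regulon_membership[spec.tf_name] = set(chosen)
        for g in chosen:
            ri = leaders[g]
            gap_n = leader_gap[ri]
            if isinstance(spec.sites_per_region, int):
                k = spec.sites_per_region
            else:
                k = int(rng.integers(spec.sites_per_region[0], spec.sites_per_region[1] + 1))
            taken: list[tuple[int, int]] = []
            for slot in range(k):
                for _attempt in range(200):
                    pos = int(rng.integers(max(plo, -gap_n), phi - L + 1))
                    if all(pos + L <= a or pos >= b for a, b in taken):
                        break
                else:
                    raise ConfigurationError(f"{spec.tf_name}: cannot place {k} sites")
                taken.append((pos, pos + L))
                site_seq = instantiate_consensus(spec.consensus, rng)
                off = gap_n + pos  # gene start sits at the end of the leader gap
                anc_leader_gap[ri] = (anc_leader_gap[ri][:off] + site_seq
                                      + anc_leader_gap[ri][off + L:])
                plants_by_run.setdefault(ri, []).append((off, site_seq, spec.tf_name, slot))

    # ---- realize each genome ----------------------------------------------
    genomes: list[Genome] = []
    table = OrthologTable()
    # site copy records for weakening: (tf, genome_id, gene_id, group, pos, contig_start, strand, seq, weak?)
    site_records: list[dict] = []
    weak_flags = {}
    for spec in plants:
        for g in target_groups_of[spec.tf_name]:
            ri = leaders[g]
            for (off, _seq, tf, slot) in plants_by_run.get(ri, []):
                if tf != spec.tf_name:
                    continue
                for gi in range(n_genomes):
                    weak_flags[(tf, gi, g, slot)] = bool(rng.random() < spec.weak_fraction)

    for gi in range(n_genomes):
        genome_id = f"genome{gi + 1}"
        contig_parts: list[str] = []
        genes: list[Gene] = []
        pos0 = 0
        layout: list[tuple[str, ...]] = []
        for ri, run in enumerate(runs):
            strand = run_strands[ri]
            protected = {off + d for (off, s, _tf, _slot) in plants_by_run.get(ri, [])
                         for d in range(len(s))}
            gap_seq = _mutate(anc_leader_gap[ri], substitution_rate, rng, protected)
            block = [gap_seq]
            spans: list[tuple[int, int]] = []  # transcription-frame gene intervals
            cursor = len(gap_seq)
            for j, g in enumerate(run):
                if j > 0:
                    gseq = _mutate(anc_intra_gap[(ri, j)], substitution_rate, rng)
                    block.append(gseq)
                    cursor += len(gseq)
                gene_seq = _mutate(anc_gene[g], substitution_rate, rng)
                block.append(gene_seq)
                spans.append((cursor, cursor + len(gene_seq)))
                cursor += len(gene_seq)
            block_seq = "".join(block)
            B = len(block_seq)
            if strand == "-":
                block_seq = revcomp(block_seq)
            gene_ids = []
            for j, g in enumerate(run):
                s, e = spans[j]
                gene_id = f"{genome_id}_{g}"
                gene_ids.append(gene_id)
                if strand == "+":
                    gs, ge = pos0 + s, pos0 + e
                else:
                    gs, ge = pos0 + B - e, pos0 + B - s
                genes.append(Gene(gene_id, "chr", gs, ge, strand, locus_tag=gene_id))
                table.add(g, genome_id, gene_id)
            layout.append(tuple(gene_ids))
            leader_gene_id = gene_ids[0]
            for (off, sseq, tf, slot) in plants_by_run.get(ri, []):
                rel = off - len(gap_seq)  # position relative to the leader gene start
                if strand == "+":
                    contig_start = pos0 + off
                else:
                    contig_start = pos0 + B - off - len(sseq)
                site_records.append(dict(
                    tf=tf, genome_id=genome_id, gene_id=leader_gene_id,
                    group=table.group_of(genome_id, leader_gene_id),
                    position=rel, contig_start=contig_start, strand=strand,
                    sequence=sseq,
                    weak=weak_flags.get((tf, gi, table.group_of(genome_id, leader_gene_id), slot), False),
                    slot=slot,
                ))
            contig_parts.append(block_seq)
            pos0 += B
        tail = _random_seq(200, gc_content, rng)
        contig_parts.append(tail)
        genomes.append(Genome(genome_id, {"chr": "".join(contig_parts)}, genes))

    truth.operon_layout = {g.genome_id: [] for g in genomes}
    for gi, genome in enumerate(genomes):
        prefix = genome.genome_id + "_"
        truth.operon_layout[genome.genome_id] = [
            tuple(prefix + g for g in run) for run in runs
        ]

    # ---- weaken designated site copies -------------------------------------
    if any(rec["weak"] for rec in site_records):
        _weaken_sites(genomes, site_records, plants, config)

    for rec in site_records:
        truth.planted_sites.append(PlantedSite(
            rec["tf"], rec["genome_id"], rec["gene_id"], rec["group"],
            rec["position"], "+", rec["sequence"],
            "weak" if rec["weak"] else "strong"))
    return genomes, table, truth


def _splice(genome: Genome, contig_id: str, start: int, strand: str, site_seq: str) -> None:
    seq = genome.contigs[contig_id]
    piece = site_seq if strand == "+" else revcomp(site_seq)
    genome.contigs[contig_id] = seq[:start] + piece + seq[start + len(piece):]


def _weaken_sites(genomes: list[Genome], site_records: list[dict],
                  plants: list[PlantSpec], config: ScanConfig,
                  max_rounds: int = 5) -> None:
    """Iteratively mutate weak-designated site copies into the rescue band.

    The reference PWM per factor is built from the strong planted copies;
    the threshold is recalibrated after each weakening round because the
    weakened copies themselves shift the per-gene score distribution.
    """
    by_genome = {g.genome_id: g for g in genomes}
    for spec in plants:
        recs = [r for r in site_records if r["tf"] == spec.tf_name]
        strong_seqs = tuple(r["sequence"] for r in recs if not r["weak"])
        if len(strong_seqs) < 2 or not any(r["weak"] for r in recs):
            continue
        motif = build_pwm(SiteSet(spec.tf_name, strong_seqs))
        for _round in range(max_rounds):
            best = {g.genome_id: best_scores_per_gene(motif, g, config) for g in genomes}
            cal = calibrate_threshold(motif, genomes, config=config, best_scores=best)
            t = cal.threshold
            lo = config.rescue_factor * t
            done = True
            for rec in recs:
                if not rec["weak"]:
                    continue
                s = score(motif, rec["sequence"])
                if lo <= s < t:
                    continue
                done = False
                new_seq = _weaken_one(rec["sequence"], motif, lo, t)
                _splice(by_genome[rec["genome_id"]], "chr", rec["contig_start"],
                        rec["strand"], new_seq)
                rec["sequence"] = new_seq
            if done:
                break


def _weaken_one(site_seq: str, motif, lo: float, hi: float) -> str:
    """Greedy single-base substitutions until the score lands in [lo, hi).

    Each step applies the substitution with the lowest resulting score that
    stays >= lo; deterministic tie-breaking by (position, base)."""
    cur = site_seq
    for _step in range(4 * len(site_seq)):
        s_cur = score(motif, cur)
        if lo <= s_cur < hi:
            return cur
        cands = []
        for j in range(len(cur)):
            for b in "ACGT":
                if b == cur[j]:
                    continue
                v = cur[:j] + b + cur[j + 1:]
                sv = score(motif, v)
                if lo <= sv < s_cur:
                    cands.append((sv, j, b, v))
        if not cands:
            logger.warning("cannot weaken site %s into [%.3f, %.3f)", site_seq, lo, hi)
            return cur
        in_band = [c for c in cands if c[0] < hi]
        if in_band:
            cur = max(in_band, key=lambda c: (c[0], -c[1]))[3]
        else:
            cur = min(cands, key=lambda c: (c[0], c[1], c[2]))[3]
    return cur


def plant_divergon(
    genome: Genome,
    gene_a: str,
    gene_b: str,
    shared_site_spec: PlantSpec,
    seed: int = 0,
    config: ScanConfig = ScanConfig(),
) -> tuple[Genome, PlantedSite]:
    """Plant one site in the shared intergenic region of a divergent pair.

    The two genes must be adjacent on one contig, on opposite strands, heads
    apart (left gene on '-', right gene on '+'), and the site is placed at
    the midpoint of the shared window overlap so it lies in both genes'
    upstream windows.  Returns a new genome and the planted-site record
    (positions reported relative to ``gene_a``).
    """
    rng = np.random.default_rng(seed)
    a, b = genome.gene(gene_a), genome.gene(gene_b)
    if a.contig_id != b.contig_id:
        raise LayoutError("genes on different contigs")
    left, right = (a, b) if a.start <= b.start else (b, a)
    if not (left.strand == "-" and right.strand == "+"):
        raise LayoutError("genes are not a divergently transcribed head-to-head pair")
    if left.end > right.start:
        raise LayoutError("genes overlap")
    lo = max(left.end, right.start - config.upstream_span)
    hi = min(right.start, left.end + config.upstream_span)
    L = len(shared_site_spec.consensus)
    if hi - lo < L:
        raise LayoutError("shared window overlap too small for the site")
    site_seq = instantiate_consensus(shared_site_spec.consensus, rng)
    start = (lo + hi - L) // 2
    contigs = dict(genome.contigs)
    seq = contigs[a.contig_id]
    contigs[a.contig_id] = seq[:start] + site_seq + seq[start + L:]
    new_genome = Genome(genome.genome_id, contigs, list(genome.genes))
    rel = start - a.start if a.strand == "+" else a.end - (start + L)
    planted = PlantedSite(shared_site_spec.tf_name, genome.genome_id, a.gene_id,
                          "", rel, "+" if a.strand == "+" else "-",
                          site_seq, "strong")
    return new_genome, planted
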