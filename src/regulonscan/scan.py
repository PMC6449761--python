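"""PWM scanning of upstream windows, threshold calibration, weak-site rescue.

Score thresholds are calibrated per transcription factor so that the fraction
of genes preceded by at least one above-threshold candidate site does not
exceed a bound (default 5%) in every genome.  Sites scoring within 10% of the
threshold are additionally rescued when their position matches a stronger
site upstream of an orthologous gene, or when no stronger site competes in
the same region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .genome import Gene, Genome, ScanConfig, UpstreamRegion, extract_upstream
from .pwm import Motif

__all__ = [
    "SiteHit",
    "CalibrationResult",
    "scan_gene",
    "scan_region",
    "best_scores_per_gene",
    "calibrate_threshold",
    "collect_hits",
    "rescue_weak_sites",
]

logger = logging.getLogger(__name__)

_CODE = np.zeros(256, dtype=np.int8) + 4  # everything unknown -> N row
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class SiteHit:
    """A scored candidate binding site, positioned relative to the gene start
    (negative = upstream); ``strand`` is relative to the gene orientation."""

    tf_name: str
    genome_id: str
    gene_id: str
    position: int
    strand: str
    score: float
    score_ratio: float = float("nan")  # score / threshold, once calibrated
    category: str = "candidate"        # candidate | strong | weak_rescued
    clause: str = ""                   # rescue clause "a" or "b" when weak_rescued


@dataclass(frozen=True)
class CalibrationResult:
    tf_name: str
    threshold: float
    per_genome_min_threshold: dict[str, float]
    per_genome_hit_fraction: dict[str, float]
    training_coverage: float
    conflicts: tuple[tuple[str, str], ...]  # (genome_id, gene_id) training genes lost


def _window_scores(motif: Motif, sequence: str) -> np.ndarray:
    """Scores of every length-L window of ``sequence`` (empty if too short)."""
    L = motif.length
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < L:
        return np.empty(0)
    W = np.vstack([motif.weights, np.zeros(motif.length)])  # row 4 = N -> 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return W[windows, np.arange(L)].sum(axis=1)


def scan_region(motif: Motif, region: UpstreamRegion, genome_id: str = "",
                tf_name: str | None = None) -> list[SiteHit]:
    """Score every window of the region on both strands (one strand for a
    symmetrized palindromic motif), sorted by descending score; ties broken by
    position, then '+' strand.  A region shorter than the motif yields no
    hits (logged)."""
    from .genome import revcomp

    tf = tf_name if tf_name is not None else motif.tf_name
    L = motif.length
    if len(region) < L:
        logger.debug("region of %s shorter than motif (%d < %d): no hits",
                     region.gene_id, len(region), L)
        return []
    hits = []
    fwd = _window_scores(motif, region.sequence)
    for i, s in enumerate(fwd):
        hits.append(SiteHit(tf, genome_id, region.gene_id,
                            region.to_relative(i), "+", float(s)))
    if not motif.palindromic:
        rev = _window_scores(motif, revcomp(region.sequence))
        n = len(region)
        for i, s in enumerate(rev):
            # window i on the revcomp covers forward positions [n-L-i, n-i)
            hits.append(SiteHit(tf, genome_id, region.gene_id,
                                region.to_relative(n - L - i), "-", float(s)))
    hits.sort(key=lambda h: (-h.score, h.position, h.strand != "+"))
    return hits


def scan_gene(motif: Motif, gene: Gene, genome: Genome,
              config: ScanConfig = ScanConfig()) -> list[SiteHit]:
    region = extract_upstream(gene, genome, config)
    return scan_region(motif, region, genome.genome_id)


def best_scores_per_gene(motif: Motif, genome: Genome,
                         config: ScanConfig = ScanConfig()) -> dict[str, float]:
    """Best window score per gene (-inf for genes whose window is too short)."""
    out = {}
    for gene in genome.genes:
        hits = scan_gene(motif, gene, genome, config)
        out[gene.gene_id] = hits[0].score if hits else float("-inf")
    return out


def calibrate_threshold(
    motif: Motif,
    genomes: list[Genome],
    training_genes: dict[str, list[str]] | None = None,
    config: ScanConfig = ScanConfig(),
    best_scores: dict[str, dict[str, float]] | None = None,
) -> CalibrationResult:
    """Calibrate the per-TF score threshold against the hit-fraction bound.

    For each genome the minimal admissible threshold is the smallest observed
    best-gene score ``t`` with ``|{genes: best >= t}| / |genes| <=
    max_hit_fraction``; the reported threshold is the maximum of these minima
    (the lowest value keeping every genome within the bound).  Training genes
    whose best score falls below it are reported as conflicts, never silently
    admitted.  ``best_scores`` may carry precomputed per-genome score maps.
    """
    if best_scores is None:
        best_scores = {g.genome_id: best_scores_per_gene(motif, g, config) for g in genomes}
    per_genome_min: dict[str, float] = {}
    for genome in genomes:
        scores = np.array(sorted(best_scores[genome.genome_id].values(), reverse=True))
        if scores.size == 0:
            raise ValueError(f"genome {genome.genome_id!r} has no genes")
        if np.allclose(scores, scores[0]):
            raise ValueError("motif scores are constant; calibration impossible")
        k_max = int(np.floor(config.max_hit_fraction * scores.size))
        # smallest observed score t with count(best >= t) <= k_max; if even
        # the top score is shared by too many genes, any value just above it
        # (zero hits) satisfies the bound
        admissible = [s for s in scores if _count_ge(scores, s) <= k_max]
        if admissible:
            per_genome_min[genome.genome_id] = float(min(admissible))
        else:
            per_genome_min[genome.genome_id] = float(np.nextafter(scores[0], np.inf))
    threshold = max(per_genome_min.values())

    fractions = {}
    for genome in genomes:
        scores = np.fromiter(best_scores[genome.genome_id].values(), dtype=float)
        fractions[genome.genome_id] = float((scores >= threshold).sum() / scores.size)

    conflicts = []
    n_train = n_kept = 0
    if training_genes:
        for gid, gene_ids in training_genes.items():
            for gene_id in gene_ids:
                n_train += 1
                if best_scores[gid][gene_id] >= threshold:
                    n_kept += 1
                else:
                    conflicts.append((gid, gene_id))
    coverage = n_kept / n_train if n_train else float("nan")
    result = CalibrationResult(motif.tf_name, threshold, per_genome_min,
                               fractions, coverage, tuple(conflicts))
    for gid, frac in fractions.items():
        logger.info("calibration %s: genome %s threshold=%.3f hit fraction=%.3f",
                    motif.tf_name, gid, threshold, frac)
    return result


def _count_ge(sorted_desc: np.ndarray, t: float) -> int:
    return int((sorted_desc >= t).sum())


def collect_hits(
    motif: Motif,
    genomes: list[Genome],
    calibration: CalibrationResult,
    config: ScanConfig = ScanConfig(),
) -> list[SiteHit]:
    """All hits scoring at least ``rescue_factor * threshold``, categorized
    ``strong`` (>= threshold) or left ``candidate`` (rescue decides later)."""
    t = calibration.threshold
    floor_score = config.rescue_factor * t
    out = []
    for genome in genomes:
        for gene in genome.genes:
            for h in scan_gene(motif, gene, genome, config):
                if h.score < floor_score:
                    break  # hits are sorted by descending score
                category = "strong" if h.score >= t else "candidate"
                out.append(replace(h, score_ratio=h.score / t if t != 0 else float("nan"),
                                   category=category))
    return out


def rescue_weak_sites(
    hits: list[SiteHit],
    ortholog_table,
    calibration: CalibrationResult,
    config: ScanConfig = ScanConfig(),
) -> list[SiteHit]:
    """Rescue sub-threshold candidates per the two published clauses.

    A candidate with ``rescue_factor * t <= score < t`` is rescued iff
    (a) an orthologous gene in another genome carries a strong hit whose
    position relative to the gene start differs by at most
    ``position_tolerance``, or (b) no other candidate or strong hit in the
    same gene's region scores higher.  Rescued hits are returned with
    category ``weak_rescued`` and the admitting clause; strong hits are never
    altered.  Every rescue is logged with its clause.
    """
    strong = [h for h in hits if h.category == "strong"]
    strong_by_group: dict[str, list[SiteHit]] = {}
    for h in strong:
        group = ortholog_table.group_of(h.genome_id, h.gene_id)
        if group is not None:
            strong_by_group.setdefault(group, []).append(h)
    best_in_region: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.genome_id, h.gene_id)
        if h.score > best_in_region.get(key, float("-inf")):
            best_in_region[key] = h.score

    rescued = []
    for h in hits:
        if h.category != "candidate":
            continue
        clause = ""
        group = ortholog_table.group_of(h.genome_id, h.gene_id)
        if group is not None:
            for s in strong_by_group.get(group, ()):
                if s.genome_id != h.genome_id and abs(s.position - h.position) <= config.position_tolerance:
                    clause = "a"
                    break
        if not clause and h.score >= best_in_region[(h.genome_id, h.gene_id)]:
            clause = "b"
        if clause:
            rescued.append(replace(h, category="weak_rescued", clause=clause))
            logger.info("rescued weak site %s %s/%s pos=%d score=%.3f (%.2f of threshold) via clause (%s)",
                        h.tf_name, h.genome_id, h.gene_id, h.position, h.score,
                        h.score_ratio, clause)
    return rescued
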