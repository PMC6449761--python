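"""End-to-end regulon reconstruction: footprint -> PWM -> calibrate -> scan
-> rescue -> operons -> regulon -> motif geometry, plus the run manifest.

``reconstruct_regulon`` is the library heart: given genomes, an ortholog
table and training groups for one transcription factor, it runs every stage
and returns all intermediate artifacts.  ``run_pipeline`` wraps it with file
I/O, configuration and a checksummed manifest so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .footprint import RegionAlignment, align_regions, conserved_windows
from .genome import Genome, ScanConfig, extract_upstream
from .geometry import check_palindrome, site_phasing
from .orthology import OrthologTable
from .pwm import Motif, SiteSet, build_pwm
from .regulon import Operon, Regulon, assemble_regulon, detect_divergons, infer_operons
from .scan import (CalibrationResult, SiteHit, best_scores_per_gene,
                   calibrate_threshold, collect_hits, rescue_weak_sites)
from .synthetic import OperonSpec, PlantSpec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["ReconstructionResult", "reconstruct_regulon", "PipelineConfig",
           "TFConfig", "run_pipeline", "symmetric_background"]


def symmetric_background(genomes: list[Genome]) -> np.ndarray:
    """Average genome-wide mononucleotide frequencies, complement-symmetrized
    so that scanning is strand-neutral."""
    freqs = np.zeros(4)
    for g in genomes:
        f = g.base_frequencies()
        freqs += np.array([f[b] for b in "ACGT"])
    freqs /= len(genomes)
    at = (freqs[0] + freqs[3]) / 2
    cg = (freqs[1] + freqs[2]) / 2
    return np.array([at, cg, cg, at])


@dataclass
class ReconstructionResult:
    tf_name: str
    alignments: dict[str, RegionAlignment]
    windows: dict[str, object]  # group -> chosen ConservedWindow
    site_set: SiteSet
    motif: Motif
    calibration: CalibrationResult
    hits: list[SiteHit]          # strong + sub-threshold candidates
    rescued: list[SiteHit]
    final_hits: list[SiteHit]    # strong + weak_rescued
    operons: dict[str, list[Operon]]
    regulon: Regulon


def footprint_training_sites(
    tf_name: str,
    genomes: list[Genome],
    ortholog_table: OrthologTable,
    training_groups: list[str],
    config: ScanConfig = ScanConfig(),
    min_identity: float = 0.9,
    min_window: int = 10,
) -> tuple[SiteSet, dict[str, RegionAlignment], dict[str, object]]:
    """Footprint the training groups and extract a uniform-length site set.

    Per group, orthologous upstream regions are star-aligned and the best
    conserved window (widest, then highest identity) is taken as the site
    seed; windows are center-cropped to the minimal chosen width so all
    training sites have one length.
    """
    by_id = {g.genome_id: g for g in genomes}
    alignments: dict[str, RegionAlignment] = {}
    chosen: dict[str, object] = {}
    for group in training_groups:
        regions = {}
        for genome_id, gene_ids in ortholog_table.genes_of(group).items():
            if genome_id not in by_id or not gene_ids:
                continue
            gene = by_id[genome_id].gene(gene_ids[0])
            seq = extract_upstream(gene, by_id[genome_id], config).sequence
            if seq:
                regions[genome_id] = seq
        if len(regions) < 2:
            logger.warning("group %s: fewer than 2 regions, skipped", group)
            continue
        aln = align_regions(regions, group)
        alignments[group] = aln
        windows = conserved_windows(aln, min_identity, min_window)
        if not windows:
            logger.warning("group %s: no conserved window found", group)
            continue
        chosen[group] = max(windows, key=lambda w: (w.width, w.mean_identity))
    if not chosen:
        raise RuntimeError(f"{tf_name}: footprinting found no conserved windows")
    # uniform site length: the (upper) median chosen width is robust to one
    # degraded group; narrower windows cannot supply full-length sites and
    # their groups are dropped, wider ones are center-cropped
    import statistics
    L = int(statistics.median_high([w.width for w in chosen.values()]))
    dropped = [g for g, w in chosen.items() if w.width < L]
    for g in dropped:
        logger.warning("group %s: window narrower than motif length %d, dropped", g, L)
        del chosen[g]
    def segments(group, off):
        w = chosen[group]
        out = []
        for genome_id, (s, _e) in sorted(w.row_intervals.items()):
            seq = alignments[group].ungapped(genome_id)[s + off: s + off + L]
            if set(seq) <= set("ACGT"):
                out.append((genome_id, group, s + off, seq))
        return out

    # first pass: center-crop each window to length L
    first = {g: segments(g, (chosen[g].width - L) // 2) for g in chosen}

    # refinement: windows may carry chance-conserved flanking columns, so the
    # center crop can be out of register between groups; re-pick each group's
    # offset to best match the pooled first-pass profile (one EM-style pass)
    profile = np.full((4, L), 1.0)  # +1 pseudocount
    for segs in first.values():
        for _gid, _grp, _s, seq in segs:
            for j, b in enumerate(seq):
                profile["ACGT".index(b), j] += 1
    logp = np.log(profile / profile.sum(axis=0, keepdims=True))

    def seg_score(segs):
        return sum(logp["ACGT".index(b), j]
                   for _gid, _grp, _s, seq in segs for j, b in enumerate(seq))

    sites, prov = [], []
    for group in chosen:
        offsets = range(chosen[group].width - L + 1)
        best = max((segments(group, o) for o in offsets), key=seg_score)
        for genome_id, grp, start, seq in best:
            sites.append(seq)
            prov.append((genome_id, grp, start, "+"))
    return SiteSet(tf_name, tuple(sites), tuple(prov)), alignments, chosen


def reconstruct_regulon(
    tf_name: str,
    genomes: list[Genome],
    ortholog_table: OrthologTable,
    training_groups: list[str],
    config: ScanConfig = ScanConfig(),
    palindromic: bool | None = None,
    min_identity: float = 0.9,
    min_window: int = 10,
    pseudocount: float = 0.5,
    strict: bool = False,
) -> ReconstructionResult:
    """Run every reconstruction stage for one transcription factor."""
    site_set, alignments, windows = footprint_training_sites(
        tf_name, genomes, ortholog_table, training_groups, config,
        min_identity, min_window)
    motif = build_pwm(site_set, pseudocount, symmetric_background(genomes),
                      palindromic=palindromic)
    training_genes = {
        g.genome_id: [gid for group in training_groups
                      for gid in ortholog_table.genes_of(group).get(g.genome_id, [])]
        for g in genomes
    }
    best = {g.genome_id: best_scores_per_gene(motif, g, config) for g in genomes}
    calibration = calibrate_threshold(motif, genomes, training_genes, config, best)
    hits = collect_hits(motif, genomes, calibration, config)
    rescued = rescue_weak_sites(hits, ortholog_table, calibration, config)
    final_hits = [h for h in hits if h.category == "strong"] + rescued
    operons = {g.genome_id: infer_operons(g, config) for g in genomes}
    regulon = assemble_regulon(tf_name, final_hits, ortholog_table, operons,
                               config, strict=strict)
    return ReconstructionResult(tf_name, alignments, windows, site_set, motif,
                                calibration, hits, rescued, final_hits,
                                operons, regulon)


# ------------------------------------------------------------ file pipeline ---

@dataclass
class TFConfig:
    name: str
    consensus: str | None = None          # used by the synth stage
    palindromic: bool | None = None
    training_groups: list[str] = field(default_factory=list)
    n_target_groups: int = 5
    sites_per_region: int = 2
    weak_fraction: float = 0.0


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    scan: ScanConfig = field(default_factory=ScanConfig)
    tfs: list[TFConfig] = field(default_factory=list)
    # synthetic input
    synth_n_genomes: int = 0
    synth_n_groups: int = 0
    synth_gc: float = 0.55
    # or file input
    genome_paths: list[str] = field(default_factory=list)  # GenBank files
    ortholog_path: str | None = None
    min_identity: float = 0.9
    min_window: int = 10
    pseudocount: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides or {})
        scan = ScanConfig(**raw.pop("scan", {}))
        tfs = [TFConfig(**tf) for tf in raw.pop("tfs", [])]
        return cls(scan=scan, tfs=tfs, **raw)

    def validate(self) -> None:
        if not self.tfs:
            raise ValueError("no TFs configured")
        if self.synth_n_genomes == 0:
            for p in self.genome_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if not self.ortholog_path or not Path(self.ortholog_path).exists():
                raise FileNotFoundError(self.ortholog_path or "<ortholog table>")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write every output under ``config.outdir`` and a
    manifest declaring each file with its checksum.  Re-running with the same
    config and inputs reproduces identical outputs."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    written: list[Path] = []

    def save(path: Path) -> Path:
        written.append(path)
        return path

    # --- stage 1: inputs (synthetic or files) ------------------------------
    if config.synth_n_genomes:
        plants = [PlantSpec(tf.name, tf.consensus, tf.n_target_groups,
                            tf.sites_per_region, tf.weak_fraction)
                  for tf in config.tfs if tf.consensus]
        genomes, table, truth = generate_dataset(
            config.synth_n_genomes, config.synth_n_groups,
            OperonSpec(), config.synth_gc, plants, seed=config.seed,
            config=config.scan)
        table.to_tsv(save(out / "orthologs.tsv"))
        for g in genomes:
            rio.write_gff_fasta(g, save(out / f"{g.genome_id}.gff3"),
                                save(out / f"{g.genome_id}.fna"))
        truth_rows = [(s.tf_name, s.genome_id, s.gene_id, s.group_id, s.position,
                       s.strand, s.sequence, s.category) for s in truth.planted_sites]
        import pandas as pd
        pd.DataFrame(truth_rows, columns=["tf", "genome", "gene", "group", "position",
                                          "strand", "sequence", "category"]
                     ).to_csv(save(out / "truth_sites.tsv"), sep="\t", index=False)
        for tf in config.tfs:
            if not tf.training_groups and tf.name in truth.regulon_membership:
                tf.training_groups = sorted(truth.regulon_membership[tf.name])
    else:
        genomes = [rio.read_genbank(p) for p in config.genome_paths]
        table = OrthologTable.from_tsv(config.ortholog_path)
        truth = None

    for g in genomes:
        rio.write_gene_table(g, save(out / f"{g.genome_id}.genes.tsv"))

    # --- stages 2-8 per TF --------------------------------------------------
    results = {}
    import pandas as pd
    for tf in config.tfs:
        res = reconstruct_regulon(tf.name, genomes, table, tf.training_groups,
                                  config.scan, tf.palindromic,
                                  config.min_identity, config.min_window,
                                  config.pseudocount)
        results[tf.name] = res
        for group, aln in res.alignments.items():
            rio.write_alignment_fasta(aln, save(out / f"{tf.name}.{group}.aln.fasta"))
        rio.write_motif_meme(res.motif, save(out / f"{tf.name}.meme"))
        rio.write_motif_tsv(res.motif, save(out / f"{tf.name}.pwm.tsv"))
        cal = res.calibration
        pd.DataFrame([(g, cal.threshold, cal.per_genome_min_threshold[g],
                       cal.per_genome_hit_fraction[g]) for g in sorted(cal.per_genome_hit_fraction)],
                     columns=["genome", "threshold", "min_admissible", "hit_fraction"]
                     ).to_csv(save(out / f"{tf.name}.calibration.tsv"), sep="\t", index=False)
        rio.write_hits_tsv(res.final_hits, save(out / f"{tf.name}.hits.tsv"))
        reg_rows = [(tf.name, grp, res.regulon.support[grp], "core",
                     ";".join(f"{gid}:{','.join(h.gene_id for h in hs)}"
                              for gid, hs in sorted(res.regulon.core[grp].items())))
                    for grp in sorted(res.regulon.core)]
        reg_rows += [(tf.name, grp, 1, "singleton", "") for grp in sorted(res.regulon.singletons)]
        pd.DataFrame(reg_rows, columns=["tf", "group", "support", "category", "evidence"]
                     ).to_csv(save(out / f"{tf.name}.regulon.tsv"), sep="\t", index=False)
        # geometry report
        pal = check_palindrome(res.motif.consensus.replace("n", "N"))
        geo_rows = [(tf.name, res.motif.consensus, pal.is_palindrome, pal.length, pal.parity)]
        pd.DataFrame(geo_rows, columns=["tf", "consensus", "is_palindrome", "length", "parity"]
                     ).to_csv(save(out / f"{tf.name}.geometry.tsv"), sep="\t", index=False)
        phas_rows = []
        by_gene: dict[tuple[str, str], list[SiteHit]] = {}
        for h in res.final_hits:
            by_gene.setdefault((h.genome_id, h.gene_id), []).append(h)
        Lm = res.motif.length
        for (genome_id, gene_id), hs in sorted(by_gene.items()):
            if len(hs) < 2:
                continue
            centers = sorted(h.position + Lm / 2 for h in hs)
            rep = site_phasing(centers, config.scan.bp_per_turn)
            phas_rows.append((tf.name, genome_id, gene_id,
                              ",".join(f"{d:g}" for d in rep.distances),
                              ",".join(str(t) for t in rep.turns)))
        pd.DataFrame(phas_rows, columns=["tf", "genome", "gene", "distances", "turns"]
                     ).to_csv(save(out / f"{tf.name}.phasing.tsv"), sep="\t", index=False)

    for g in genomes:
        ops = infer_operons(g, config.scan)
        rio.write_operons_gff(ops, g, save(out / f"{g.genome_id}.operons.gff3"))
        div = detect_divergons(g, [h for r in results.values() for h in r.final_hits],
                               config.scan)
        pd.DataFrame([(g.genome_id, a, b, len(sh)) for a, b, sh in div],
                     columns=["genome", "gene_minus", "gene_plus", "shared_hits"]
                     ).to_csv(save(out / f"{g.genome_id}.divergons.tsv"), sep="\t", index=False)

    # --- manifest ------------------------------------------------------------
    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        fh.write("# regulonscan run manifest\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("config:\n")
        cfg_echo = yaml.safe_dump({
            "outdir": config.outdir, "seed": config.seed,
            "scan": {k: getattr(config.scan, k) for k in
                     ("upstream_span", "downstream_span", "max_hit_fraction",
                      "rescue_factor", "operon_max_gap", "min_genomes",
                      "position_tolerance", "bp_per_turn")},
            "tfs": [tf.name for tf in config.tfs],
        }, sort_keys=True)
        for line in cfg_echo.splitlines():
            fh.write(f"  {line}\n")
        fh.write("outputs:\n")
        for path in sorted(written):
            fh.write(f"  {_sha256(path)}  {path.relative_to(out)}\n")
    return {"results": results, "genomes": genomes, "orthologs": table,
            "truth": truth, "manifest": manifest, "outputs": written}
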