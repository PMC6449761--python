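"""Genome and gene data model, sequence utilities, upstream-window extraction.

Coordinates are 0-based half-open throughout; conversion from 1-based
conventions (GenBank) happens at the I/O boundary only.  Scanning for
transcription-factor binding sites is anchored to a fixed window around the
annotated gene start: a span upstream of the start plus a short span
downstream of it, oriented 5'->3' with respect to the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "IUPAC_SETS",
    "Gene",
    "Genome",
    "UpstreamRegion",
    "ScanConfig",
    "revcomp",
    "iupac_set",
    "extract_upstream",
]

# IUPAC nucleotide codes -> the set of plain bases each denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
# case-preserving complement table
_COMP_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_VALID = set(_COMPLEMENT) | {c.lower() for c in _COMPLEMENT}


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def revcomp(sequence: str) -> str:
    """Reverse complement under IUPAC complementation (M<->K, R<->Y, W, S fixed).

    Case is preserved per character.  Raises :class:`InvalidAlphabetError` on
    any non-IUPAC character.
    """
    bad = set(sequence) - _VALID
    if bad:
        raise InvalidAlphabetError(f"non-IUPAC characters: {sorted(bad)!r}")
    return sequence.translate(_COMP_TABLE)[::-1]


def iupac_set(code: str) -> frozenset[str]:
    """Set of plain bases denoted by a single IUPAC code (case-insensitive)."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise InvalidAlphabetError(f"not an IUPAC code: {code!r}") from None


@dataclass(frozen=True)
class Gene:
    """An annotated gene on a contig, 0-based half-open, strand '+' or '-'."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Contig coordinate of the annotated gene start (5' end)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class Genome:
    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig_id!r}")
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(f"{g.gene_id}: interval exceeds contig length")
        self.genes.sort(key=lambda g: (g.contig_id, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in genome {self.genome_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide mononucleotide frequencies (A,C,G,T; N ignored)."""
        counts = dict.fromkeys("ACGT", 0)
        for seq in self.contigs.values():
            up = seq.upper()
            for b in "ACGT":
                counts[b] += up.count(b)
        total = sum(counts.values()) or 1
        return {b: counts[b] / total for b in "ACGT"}


@dataclass(frozen=True)
class UpstreamRegion:
    """The scan window of one gene, oriented 5'->3' relative to the gene.

    ``interval`` is the (start, end) half-open slice on the contig;
    ``gene_start_offset`` is the index of the annotated gene start within the
    oriented ``sequence`` (equal to the upstream span unless truncated at a
    contig edge on the upstream side).
    """

    gene_id: str
    contig_id: str
    interval: tuple[int, int]
    sequence: str
    gene_start_offset: int

    def __len__(self) -> int:
        return len(self.sequence)

    def to_relative(self, index: int) -> int:
        """Map an index in the oriented sequence to a position relative to the
        gene start (negative = upstream)."""
        return index - self.gene_start_offset


@dataclass(frozen=True)
class ScanConfig:
    """Tunable constants of the reconstruction procedure.

    Defaults follow the published protocol: a 350 nt upstream / 50 nt
    downstream scan window around the gene start, candidate-site thresholds
    calibrated so that at most 5% of genes per genome carry a site, rescue of
    sites scoring within 10% of the threshold, a 200 nt intergenic-distance
    cap for operons, and cross-genome support in at least ``min_genomes``
    genomes ("several genomes").  ``bp_per_turn`` is the B-DNA helical pitch
    used to express site spacings in DNA turns.
    """

    upstream_span: int = 350
    downstream_span: int = 50
    max_hit_fraction: float = 0.05
    rescue_factor: float = 0.90
    operon_max_gap: int = 200
    min_genomes: int = 2
    position_tolerance: int = 20
    bp_per_turn: float = 10.5
    truncate_at_neighbor: bool = False

    def __post_init__(self) -> None:
        if self.upstream_span < 0 or self.downstream_span < 0:
            raise ValueError("spans must be >= 0")
        if not 0 < self.max_hit_fraction <= 1:
            raise ValueError("max_hit_fraction must lie in (0, 1]")
        if not 0 < self.rescue_factor < 1:
            raise ValueError("rescue_factor must lie in (0, 1)")

    def evolve(self, **kwargs) -> "ScanConfig":
        return replace(self, **kwargs)


def extract_upstream(gene: Gene, genome: Genome, config: ScanConfig = ScanConfig()) -> UpstreamRegion:
    """Extract the oriented scan window of ``gene``.

    For a '+' strand gene the window on the contig is
    ``[start - upstream_span, start + downstream_span)``; for a '-' strand
    gene it is the mirror image ``[end - downstream_span, end + upstream_span)``
    with the slice reverse-complemented.  Windows are clipped (not rejected)
    at contig edges.  If ``truncate_at_neighbor`` is set, the upstream side is
    additionally clipped at the nearest annotated neighbor gene boundary.
    """
    if gene.gene_id not in genome or genome.gene(gene.gene_id) != gene:
        raise KeyError(f"gene {gene.gene_id!r} does not belong to genome {genome.genome_id!r}")
    contig = genome.contigs[gene.contig_id]
    n = len(contig)
    if gene.strand == "+":
        lo = gene.start - config.upstream_span
        hi = gene.start + config.downstream_span
    else:
        lo = gene.end - config.downstream_span
        hi = gene.end + config.upstream_span
    if config.truncate_at_neighbor:
        lo, hi = _clip_to_neighbors(gene, genome, lo, hi)
    lo_c, hi_c = max(0, lo), min(n, hi)
    seq = contig[lo_c:hi_c]
    if gene.strand == "+":
        offset = gene.start - lo_c
    else:
        seq = revcomp(seq)
        offset = hi_c - gene.end
    return UpstreamRegion(gene.gene_id, gene.contig_id, (lo_c, hi_c), seq.upper(), offset)


def _clip_to_neighbors(gene: Gene, genome: Genome, lo: int, hi: int) -> tuple[int, int]:
    # only the upstream side is limited; the downstream span stays fixed
    for other in genome.genes:
        if other.contig_id != gene.contig_id or other.gene_id == gene.gene_id:
            continue
        if gene.strand == "+" and other.end <= gene.start:
            lo = max(lo, other.end)
        elif gene.strand == "-" and other.start >= gene.end:
            hi = min(hi, other.start)
    return lo, hi
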