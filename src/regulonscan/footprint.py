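"""Phylogenetic footprinting: align orthologous upstream regions and call
runs of conserved columns as candidate binding-site seeds.

Binding sites are more conserved than intergenic sequence in general, so
stretches of consecutive near-identical alignment columns in orthologous
upstream regions mark candidate sites.  Regions are combined by a star
multiple alignment: every region is globally aligned to the longest one
(match +1, mismatch -1, gap open -3, gap extend -1) and the pairwise
alignments are merged on the center sequence's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = [
    "RegionAlignment",
    "ConservedWindow",
    "align_regions",
    "conserved_windows",
]

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -3.0, -1.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN     # first gap position
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass
class RegionAlignment:
    """A gapped multiple alignment of one ortholog group's upstream regions."""

    group_id: str
    rows: dict[str, str]  # genome_id -> gapped sequence, all equal length

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, genome_id: str) -> str:
        return self.rows[genome_id].replace("-", "")


@dataclass(frozen=True)
class ConservedWindow:
    """A maximal run of gapless, near-identical alignment columns."""

    group_id: str
    col_start: int  # half-open column interval in the alignment
    col_end: int
    row_intervals: dict[str, tuple[int, int]]  # genome_id -> ungapped coords
    mean_identity: float

    @property
    def width(self) -> int:
        return self.col_end - self.col_start


def align_regions(regions: dict[str, str], group_id: str = "") -> RegionAlignment:
    """Star multiple alignment of >= 2 upstream-region sequences.

    ``regions`` maps genome_id -> sequence.  The longest sequence (ties: first
    in insertion order) is the star center; all others are pairwise aligned to
    it and merged on the center's coordinates.
    """
    if len(regions) < 2:
        raise ValueError("footprinting needs at least 2 orthologous regions")
    for gid, seq in regions.items():
        if not seq:
            raise ValueError(f"empty region for genome {gid!r}")
    center_id = max(regions, key=lambda g: len(regions[g]))
    center = regions[center_id].upper()
    aligner = _make_aligner()

    # pairwise alignments as (center_gapped, other_gapped) strings
    pair: dict[str, tuple[str, str]] = {}
    for gid, seq in regions.items():
        if gid == center_id:
            continue
        aln = aligner.align(center, seq.upper())[0]
        c_row, o_row = str(aln[0]), str(aln[1])
        pair[gid] = (c_row, o_row)

    # per center position c (0..len(center)), maximal number of insertion
    # columns placed immediately before center base c
    inserts = [0] * (len(center) + 1)
    for c_row, _ in pair.values():
        pos, run = 0, 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                inserts[pos] = max(inserts[pos], run)
                run, pos = 0, pos + 1
        inserts[pos] = max(inserts[pos], run)

    def pad(c_row: str, o_row: str) -> str:
        out, pos, run = [], 0, 0
        buf = []
        for cc, oc in zip(c_row, o_row):
            if cc == "-":
                buf.append(oc)
                run += 1
            else:
                out.append("-" * (inserts[pos] - run))
                out.extend(buf)
                buf, run = [], 0
                out.append(oc)
                pos += 1
        out.append("-" * (inserts[pos] - run))
        out.extend(buf)
        return "".join(out)

    rows = {center_id: pad(center, center)}
    for gid, (c_row, o_row) in pair.items():
        rows[gid] = pad(c_row, o_row)
    return RegionAlignment(group_id, rows)


def conserved_windows(
    alignment: RegionAlignment,
    min_identity: float = 0.9,
    min_window: int = 10,
) -> list[ConservedWindow]:
    """Maximal runs of >= ``min_window`` consecutive gapless columns whose
    modal-base identity is >= ``min_identity``.

    Column identity is the frequency of the most common plain base among the
    rows (gaps and N never count toward the mode).  Gap columns break runs.
    Returned windows are disjoint and sorted by column start.
    """
    rows = list(alignment.rows.values())
    ids = list(alignment.rows.keys())
    if len(rows) < 2:
        raise ValueError("alignment must have >= 2 rows")
    n_rows, n_cols = len(rows), alignment.n_columns

    good = []
    for j in range(n_cols):
        column = [r[j] for r in rows]
        if "-" in column:
            good.append(None)
            continue
        counts = {b: 0 for b in "ACGT"}
        for ch in column:
            if ch in counts:
                counts[ch] += 1
        good.append(max(counts.values()) / n_rows)

    # cumulative ungapped position per row for coordinate mapping
    cum = [[0] * (n_cols + 1) for _ in rows]
    for i, r in enumerate(rows):
        for j, ch in enumerate(r):
            cum[i][j + 1] = cum[i][j] + (ch != "-")

    windows: list[ConservedWindow] = []
    j = 0
    while j < n_cols:
        if good[j] is not None and good[j] >= min_identity:
            k = j
            while k < n_cols and good[k] is not None and good[k] >= min_identity:
                k += 1
            if k - j >= min_window:
                row_intervals = {
                    ids[i]: (cum[i][j], cum[i][k]) for i in range(n_rows)
                }
                mean_id = sum(good[c] for c in range(j, k)) / (k - j)
                windows.append(ConservedWindow(alignment.group_id, j, k, row_intervals, mean_id))
            j = k
        else:
            j += 1
    return windows
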