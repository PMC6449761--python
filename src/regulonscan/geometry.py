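"""Motif-structure analyses: palindromes, half-site spacers, LysR boxes, phasing.

Binding motifs of homodimeric regulators are DNA palindromes (equal to their
own IUPAC reverse complement); HTH-XRE family repressors bind short repeated
half-sites (e.g. TGCA) at characteristic spacers; LysR-family boxes are
inverted repeats conforming to the T-N11-A pattern; and multi-site
arrangements of sigma54-dependent activators are phased in whole DNA helical
turns so that bound dimers face the same side of the helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

from .genome import InvalidAlphabetError, iupac_set, revcomp

__all__ = [
    "PalindromeCheck",
    "SpacerHistogram",
    "PhasingReport",
    "check_palindrome",
    "enumerate_halfsite_spacers",
    "lysr_box_spacer",
    "central_gap",
    "site_phasing",
]


@dataclass(frozen=True)
class PalindromeCheck:
    is_palindrome: bool
    length: int
    parity: str  # "even" | "odd"

    def __iter__(self):
        return iter((self.is_palindrome, self.length, self.parity))


def check_palindrome(consensus: str) -> PalindromeCheck:
    """Is the IUPAC consensus its own reverse complement?

    For odd lengths the central position is exempted from the comparison (any
    center symbol is allowed, as in odd LysR-type palindromes).
    """
    rc = revcomp(consensus).upper()  # validates the alphabet
    s = consensus.upper()
    L = len(s)
    half = L // 2
    is_pal = L > 0 and s[:half] == rc[:half]
    return PalindromeCheck(is_pal, L, "even" if L % 2 == 0 else "odd")


@dataclass
class SpacerHistogram:
    """Occurrence counts of half-site pairs by spacer length.

    The spacer is measured end-of-first to start-of-second half-site.  Each
    occurrence records (sequence index, offset of first half-site,
    orientation), orientation being ``direct`` (both copies on the given
    strand) or ``inverted`` (second copy is the reverse complement).  For a
    self-complementary half-site the two orientations coincide and every pair
    is reported once, tagged ``direct``.
    """

    half_site: str
    counts: dict[int, int] = field(default_factory=dict)
    sources: list[tuple[int, int, str]] = field(default_factory=list)

    def add(self, spacer: int, seq_index: int, offset: int, orientation: str) -> None:
        self.counts[spacer] = self.counts.get(spacer, 0) + 1
        self.sources.append((seq_index, offset, orientation))


def _occurrences(seq: str, pattern: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def enumerate_halfsite_spacers(
    sequences: list[str],
    half_site: str = "TGCA",
    spacer_range: range = range(0, 21),
) -> SpacerHistogram:
    """Count ordered half-site pairs per spacer length over plain sequences.

    Both direct-repeat and inverted-repeat pair orientations are enumerated
    and tagged; pairs never span sequence boundaries.
    """
    half_site = half_site.upper()
    if set(half_site) - set("ACGT"):
        raise InvalidAlphabetError("half_site must be non-degenerate (A,C,G,T)")
    rc = revcomp(half_site)
    hist = SpacerHistogram(half_site)
    lo, hi = min(spacer_range), max(spacer_range)
    k = len(half_site)
    for idx, seq in enumerate(sequences):
        seq = seq.upper()
        fwd = _occurrences(seq, half_site)
        if rc == half_site:
            # palindromic half-site: orientations coincide, count pairs once
            for a in range(len(fwd)):
                for b in range(a + 1, len(fwd)):
                    gap = fwd[b] - (fwd[a] + k)
                    if lo <= gap <= hi:
                        hist.add(gap, idx, fwd[a], "direct")
            continue
        rev = _occurrences(seq, rc)
        for i in fwd:
            for j in fwd:
                gap = j - (i + k)
                if j > i and lo <= gap <= hi:
                    hist.add(gap, idx, i, "direct")
            for j in rev:
                gap = j - (i + k)
                if j > i and lo <= gap <= hi:
                    hist.add(gap, idx, i, "inverted")
    return hist


class PatternNotFoundError(ValueError):
    """The consensus contains no qualifying symmetric base pair."""


def lysr_box_spacer(consensus: str) -> int:
    """Spacer of the LysR-type T-N_x-A signature inside a box consensus.

    Finds the outermost symmetric position pair ``(i, L-1-i)`` (smallest
    ``i``) whose IUPAC sets contain T and A respectively, and returns the
    number of intervening positions, ``L - 2 - 2i``.
    """
    s = consensus.upper()
    L = len(s)
    for i in range(L // 2):
        if "T" in iupac_set(s[i]) and "A" in iupac_set(s[L - 1 - i]):
            return L - 2 - 2 * i
    raise PatternNotFoundError(f"no T...A symmetric pair in {consensus!r}")


def central_gap(consensus: str) -> int:
    """Length of the unconstrained (all-N) gap between the two arms of an
    inverted-repeat consensus such as AkACC-N5-GGTAT (returns 5)."""
    s = consensus.upper()
    for c in s:
        iupac_set(c)
    L = len(s)
    lo = L // 2
    hi = (L + 1) // 2  # odd length: center starts in the gap
    while lo > 0 and s[lo - 1] == "N":
        lo -= 1
    while hi < L and s[hi] == "N":
        hi += 1
    return hi - lo


@dataclass(frozen=True)
class PhasingReport:
    """Helical phasing of a multi-site arrangement."""

    centers: tuple[float, ...]
    distances: tuple[float, ...]  # consecutive center-to-center, nt
    turns: tuple[int, ...]        # nearest whole DNA turns per distance
    bp_per_turn: float


def site_phasing(site_centers: list[float], bp_per_turn: float = 10.5) -> PhasingReport:
    """Consecutive center distances and their nearest-integer DNA turn counts.

    Uses round-half-up so e.g. 31 nt at 10.5 bp/turn is 2.95 -> 3 turns.
    """
    if len(site_centers) < 2:
        raise ValueError("phasing needs at least 2 site centers")
    centers = tuple(sorted(site_centers))
    distances = tuple(b - a for a, b in zip(centers, centers[1:]))
    turns = tuple(int(floor(d / bp_per_turn + 0.5)) for d in distances)
    return PhasingReport(centers, distances, turns, bp_per_turn)
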