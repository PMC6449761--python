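"""Position weight matrices: construction, scoring, symmetrization, consensus.

A motif is a 4xL column-stochastic frequency matrix (rows A, C, G, T) with an
additive pseudocount, plus the log-odds weight matrix against a mononucleotide
background.  Scores of candidate windows are sums of per-position natural-log
odds; an ``N`` base contributes zero (likelihood ratio one).  Binding sites of
homodimeric factors are palindromic, so a motif can be symmetrized by
averaging each column with the complement of its mirror column; a symmetrized
motif scores a window and its reverse complement identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import IUPAC_SETS, InvalidAlphabetError, revcomp

__all__ = [
    "SiteSet",
    "Motif",
    "build_pwm",
    "score",
    "symmetrize",
    "derive_consensus",
    "information_content",
    "uniform_background",
    "instantiate_consensus",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# complement permutation of the A,C,G,T row order: A<->T, C<->G
_COMP_PERM = np.array([3, 2, 1, 0])

# base set -> IUPAC letter (degenerate codes lowercased, as in printed consensi)
_SET_TO_IUPAC = {frozenset(v): (k if len(v) == 1 else k.lower()) for k, v in IUPAC_SETS.items()}


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def _as_background(background) -> np.ndarray:
    if background is None:
        return uniform_background()
    if isinstance(background, dict):
        background = [background[b] for b in BASES]
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a length-4 distribution over A,C,G,T")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be positive")
    return bg


@dataclass(frozen=True)
class SiteSet:
    """A training set of aligned binding sites for one transcription factor."""

    tf_name: str
    sites: tuple[str, ...]
    provenance: tuple[tuple, ...] = ()  # (genome_id, gene_id, position, strand) per site

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a site set needs at least 2 sites")
        lengths = {len(s) for s in self.sites}
        if len(lengths) != 1:
            raise ValueError(f"sites have unequal lengths: {sorted(lengths)}")
        for s in self.sites:
            if set(s.upper()) - set(BASES):
                raise InvalidAlphabetError(f"site {s!r} not over A,C,G,T")

    @property
    def length(self) -> int:
        return len(self.sites[0])


@dataclass(frozen=True)
class Motif:
    tf_name: str
    frequencies: np.ndarray  # 4 x L, columns sum to 1
    weights: np.ndarray      # 4 x L, ln(freq / background)
    background: np.ndarray   # length 4
    pseudocount: float
    palindromic: bool = False
    consensus: str = field(default="")

    def __post_init__(self) -> None:
        if self.frequencies.shape[0] != 4:
            raise ValueError("frequency matrix must be 4 x L")
        colsums = self.frequencies.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")

    @property
    def length(self) -> int:
        return self.frequencies.shape[1]

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())


def build_pwm(
    sites: SiteSet,
    pseudocount: float = 0.5,
    background=None,
    palindromic: bool | None = None,
) -> Motif:
    """Build a log-odds PWM from aligned sites.

    Frequencies are ``(count(b, j) + 4 * pseudocount * bg(b)) / (n + 4 * pseudocount)``
    so that columns stay stochastic for any background; weights are natural
    logs of frequency over background.  ``palindromic=None`` auto-detects a
    self-reverse-complementary consensus and symmetrizes the motif;
    ``palindromic=True`` forces symmetrization.
    """
    bg = _as_background(background)
    L = sites.length
    counts = np.zeros((4, L))
    for s in sites.sites:
        for j, b in enumerate(s.upper()):
            counts[_BASE_INDEX[b], j] += 1
    n = len(sites.sites)
    freqs = (counts + 4.0 * pseudocount * bg[:, None]) / (n + 4.0 * pseudocount)
    motif = _finalize(sites.tf_name, freqs, bg, pseudocount, palindromic=False)
    if palindromic or (palindromic is None and _is_selfcomp(motif.consensus)):
        motif = symmetrize(motif)
    return motif


def _finalize(tf_name: str, freqs: np.ndarray, bg: np.ndarray, pseudocount: float,
              palindromic: bool) -> Motif:
    with np.errstate(divide="ignore"):  # pseudocount 0 gives -inf weights
        weights = np.log(freqs / bg[:, None])
    m = Motif(tf_name, freqs, weights, bg, pseudocount, palindromic, "")
    return Motif(tf_name, freqs, weights, bg, pseudocount, palindromic, derive_consensus(m))


def _is_selfcomp(consensus: str) -> bool:
    try:
        return revcomp(consensus).upper() == consensus.upper()
    except InvalidAlphabetError:
        return False


def score(motif: Motif, window: str) -> float:
    """Log-odds score of one window of exactly motif length.

    ``N`` bases contribute 0.  Raises ``ValueError`` on a length mismatch or
    a non-ACGTN character.
    """
    if len(window) != motif.length:
        raise ValueError(f"window length {len(window)} != motif length {motif.length}")
    total = 0.0
    for j, b in enumerate(window.upper()):
        if b == "N":
            continue
        try:
            total += motif.weights[_BASE_INDEX[b], j]
        except KeyError:
            raise InvalidAlphabetError(f"unexpected character {b!r} in window") from None
    return float(total)


def symmetrize(motif: Motif) -> Motif:
    """Average the motif with its own reverse complement.

    ``freq'(b, j) = (freq(b, j) + freq(comp(b), L-1-j)) / 2``; the background
    is likewise averaged with its complement so that the symmetry
    ``weight(b, j) = weight(comp(b), L-1-j)`` holds exactly.  Idempotent; a
    palindromic motif is a fixed point.
    """
    f = motif.frequencies
    f_sym = 0.5 * (f + f[_COMP_PERM, ::-1])
    bg_sym = 0.5 * (motif.background + motif.background[_COMP_PERM])
    return _finalize(motif.tf_name, f_sym, bg_sym, motif.pseudocount, palindromic=True)


def derive_consensus(motif: Motif, inclusion_threshold: float = 0.25) -> str:
    """IUPAC consensus: per column, the code for bases at frequency >= threshold.

    A column where no base or all four bases qualify becomes ``n``.
    Single-base codes are uppercase, degenerate codes lowercase (the printed
    convention for motif consensi).
    """
    out = []
    for j in range(motif.length):
        qual = frozenset(BASES[i] for i in range(4) if motif.frequencies[i, j] >= inclusion_threshold)
        if not qual or len(qual) == 4:
            out.append("n")
        else:
            out.append(_SET_TO_IUPAC[qual])
    return "".join(out)


def information_content(motif: Motif) -> tuple[np.ndarray, float]:
    """Per-column information in bits and the total.

    For a uniform background this is ``2 + sum_b f log2 f``; in general the
    Kullback-Leibler form ``sum_b f log2(f / bg)``.
    """
    f = motif.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / motif.background[:, None]), 0.0)
    per_column = terms.sum(axis=0)
    return per_column, float(per_column.sum())


def instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete A,C,G,T realization of an IUPAC consensus, each degenerate
    position resolved uniformly among its allowed bases."""
    out = []
    for c in consensus:
        choices = sorted(IUPAC_SETS[c.upper()])
        out.append(choices[0] if len(choices) == 1 else rng.choice(choices))
    return "".join(out)
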