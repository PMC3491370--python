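"""Cross-species conserved window, position weight matrix and consensus matching.

Given pre-aligned (equal-length) homologous sequences, the conserved
window is the minimal interval containing every invariant column — the
positions where all species carry the same base.  Restricting the
alignment to such a window yields a position weight matrix whose
per-column information content (2 + sum_b f_b log2 f_b, in bits, 0..2 for
DNA) quantifies conservation, and whose majority-base consensus can be
compared against IUPAC transcription-factor motifs (e.g. a CTCF
consensus) on both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp

__all__ = [
    "ConservedWindow",
    "PWM",
    "ConsensusMatch",
    "conserved_window",
    "build_pwm",
    "consensus_match",
    "IUPAC",
]

ALPHABET = "ACGT"

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(motif: str) -> str:
    return motif.upper().translate(_IUPAC_RC)[::-1]


@dataclass
class ConservedWindow:
    start: int
    end: int  # half-open alignment coordinates
    invariant_columns: np.ndarray
    empty: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    counts: np.ndarray  # 4 x W, rows in ACGT order
    frequencies: np.ndarray  # 4 x W, column sums = 1
    information_content: np.ndarray  # bits per column, in [0, 2]
    pseudocount: float = 0.0

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.frequencies.argmax(axis=0))


@dataclass
class ConsensusMatch:
    offset: int  # motif start relative to target start (may be negative)
    strand: str  # "+" | "-"
    matched_positions: int
    consensus_length: int


def conserved_window(sequences: list[str]) -> ConservedWindow:
    """Minimal interval containing all columns invariant across sequences.

    Columns inside the window need not all be invariant.  No invariant
    column at all gives an empty window with ``empty=True``.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be pre-aligned to equal length")
    mat = np.array([list(s.upper()) for s in sequences])
    invariant = np.flatnonzero((mat == mat[0]).all(axis=0))
    if invariant.size == 0:
        return ConservedWindow(0, 0, invariant, empty=True)
    return ConservedWindow(int(invariant[0]), int(invariant[-1]) + 1, invariant)


def build_pwm(sequences: list[str], pseudocount: float = 0.0) -> PWM:
    """Column base counts, pseudocounted frequencies and information content.

    Ambiguous bases are excluded column-wise from the counts (with a
    warning); IC per column is ``2 + sum_b f_b log2 f_b`` with
    ``0*log(0) = 0``, which is exact for pseudocount 0 (sequence-logo
    convention).
    """
    if not sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    mat = np.array([list(s.upper()) for s in sequences])
    counts = np.stack([(mat == b).sum(axis=0) for b in ALPHABET]).astype(float)
    excluded = mat.shape[0] - counts.sum(axis=0)
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} ambiguous bases excluded from PWM counts",
            stacklevel=2,
        )
    denom = counts.sum(axis=0) + 4.0 * pseudocount
    freqs = (counts + pseudocount) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return PWM(counts, freqs, ic, pseudocount)


def _match_at(target: str, motif: str, offset: int) -> int:
    matched = 0
    for i, sym in enumerate(motif):
        pos = offset + i
        if 0 <= pos < len(target) and target[pos] in IUPAC.get(sym, frozenset()):
            matched += 1
    return matched


def consensus_match(target: str, motif: str) -> ConsensusMatch:
    """Best IUPAC-class agreement of ``motif`` with ``target``, both strands.

    All offsets with at least one overlapping position are scanned,
    including partial overlaps (so a motif longer than the target is
    handled symmetrically); ties prefer the forward strand, then the
    smaller offset.
    """
    target = target.upper()
    motif = motif.upper()
    best = None
    for strand, m in (("+", motif), ("-", revcomp_iupac(motif))):
        for offset in range(-len(m) + 1, len(target)):
            score = _match_at(target, m, offset)
            key = (-score, strand == "-", offset)
            if best is None or key < best[0]:
                best = (key, ConsensusMatch(offset, strand, score, len(motif)))
    return best[1]
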