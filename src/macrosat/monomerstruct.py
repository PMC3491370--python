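"""Monomer decomposition of a tandem array, divergence and VNTR structure.

Because an internal VNTR makes monomer length non-constant (the mouse
array's units run 3.8-5.7 kb), monomers cannot be cut at a fixed period.
Instead segmentation is phased by an *anchor*: a k-mer that recurs once
per monomer at a fixed template offset.  Cut points at the anchor
occurrences tile the array into monomers; the register of that tiling is
arbitrary for a circularly permutable repeat, so downstream comparisons
treat the monomer sequence of VNTR copy numbers as a circular word.

Inter-monomer divergence is measured from global pairwise alignments with
affine gap penalties, as substitutions per aligned (match or mismatch)
column; gap columns are excluded from the denominator, so VNTR copy-number
differences — which stay contiguous under affine scoring — do not dilute
or inflate a statistic meant to describe point divergence.  (Unit-cost
edit-distance alignment is unsuitable here: a mismatch column and an
insertion+deletion pair cost the same, so optimal paths are massively
degenerate and percent identity becomes ill-determined.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .tandemscan import self_matches, _offset_families

__all__ = [
    "MonomerSet",
    "DivergenceMatrix",
    "VntrCall",
    "AnchorError",
    "find_anchor",
    "segment_monomers",
    "divergence_matrix",
    "detect_vntr",
]

class AnchorError(ValueError):
    pass


@dataclass
class MonomerSet:
    array_interval: tuple[int, int]
    anchor: str
    monomer_intervals: list[tuple[int, int]]
    leading_flank: tuple[int, int]  # [0, first anchor), not a monomer

    @property
    def lengths(self) -> list[int]:
        return [b - a for a, b in self.monomer_intervals]

    def sequences(self, array_sequence: str) -> list[str]:
        return [array_sequence[a:b] for a, b in self.monomer_intervals]


@dataclass
class DivergenceMatrix:
    percent: np.ndarray  # n x n, symmetric, zero diagonal
    aligned_columns: np.ndarray  # columns entering each pair's denominator


@dataclass
class VntrCall:
    unit_interval: tuple[int, int] | None  # within the reference monomer
    unit_length: int
    copies_per_monomer: list[int]
    reference_monomer: int | None  # index of the monomer carrying unit_interval


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _regular_count(positions: list[int], tol: float = 0.40) -> int:
    """Occurrences all of whose adjacent spacings sit within ``tol`` of the
    median spacing — the signature of once-per-monomer recurrence."""
    spacings = np.diff(positions)
    med = float(np.median(spacings))
    ok = (spacings >= (1 - tol) * med) & (spacings <= (1 + tol) * med)
    count = 0
    for i in range(len(positions)):
        left = ok[i - 1] if i > 0 else True
        right = ok[i] if i < len(spacings) else True
        if left and right:
            count += 1
    return count


def find_anchor(array_sequence: str, k: int = 16) -> tuple[str, list[int]]:
    """Choose the k-mer that best recurs once per repeat unit.

    Scoring: for each k-mer with >= 2 occurrences, count occurrences whose
    neighbouring spacings lie within 40% of the k-mer's own median spacing.
    Ties are broken by earliest first occurrence (so the segmentation
    register lands near the start of the unit, ahead of any internal
    sub-repeat), then lexicographically.  The winning k-mer is then
    re-located with a small Hamming allowance so units carrying a point
    mutation inside the anchor are still cut.
    """
    index = _kmer_positions(array_sequence, k)
    best = None  # (-score, first_pos, kmer, positions)
    for kmer, positions in index.items():
        if len(positions) < 2:
            continue
        score = _regular_count(positions)
        cand = (-score, positions[0], kmer)
        if best is None or cand < best[0]:
            best = (cand, positions)
    if best is None or -best[0][0] < 2:
        raise AnchorError("no periodic anchor")
    anchor = best[0][2]

    # approximate re-scan (Hamming <= k//5) to recover mutated anchors
    arr = np.frombuffer(array_sequence.encode("ascii"), dtype=np.uint8)
    target = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    dist = (windows != target).sum(axis=1)
    max_ham = max(1, k // 5)
    hits = np.flatnonzero(dist <= max_ham)

    # de-duplicate hits closer than half the typical spacing, keeping the
    # closest match to the anchor
    exact = best[1]
    med = float(np.median(np.diff(exact))) if len(exact) > 1 else len(array_sequence)
    positions: list[int] = []
    for pos in hits:
        if positions and pos - positions[-1] < 0.5 * med:
            if dist[pos] < dist[positions[-1]]:
                positions[-1] = int(pos)
        else:
            positions.append(int(pos))
    return anchor, positions


def segment_monomers(array_sequence: str, anchor_positions: list[int]) -> MonomerSet:
    """Cut the array at anchor occurrences.

    Monomer count equals anchor count; the last monomer runs to the array
    end, and the partial sequence before the first anchor is reported as a
    flank, not a monomer.
    """
    if len(anchor_positions) < 2:
        raise ValueError("need at least 2 anchor positions to segment")
    pos = sorted(anchor_positions)
    ends = pos[1:] + [len(array_sequence)]
    intervals = list(zip(pos, ends))
    return MonomerSet(
        array_interval=(pos[0], len(array_sequence)),
        anchor="",
        monomer_intervals=intervals,
        leading_flank=(0, pos[0]),
    )


def _aligner() -> Align.PairwiseAligner:
    # affine penalties keep length differences in contiguous gap blocks and
    # make substitution-only paths strictly optimal for equal-length inputs
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -0.5
    return aligner


_PAIR_ALIGNER = _aligner()


def _pair_divergence(a: str, b: str) -> tuple[float, int]:
    """Percent substitution divergence from a global affine-gap alignment.

    Substituted columns over aligned (match + mismatch) columns; gap
    columns enter neither numerator nor denominator, so length differences
    (VNTR copy-number variation) leave the statistic untouched.
    """
    alignment = _PAIR_ALIGNER.align(a, b)[0]
    subs = 0
    columns = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        x = np.frombuffer(a[qs:qe].encode("ascii"), dtype=np.uint8)
        y = np.frombuffer(b[ts:te].encode("ascii"), dtype=np.uint8)
        columns += x.size
        subs += int((x != y).sum())
    if columns == 0:
        raise ValueError("alignment has no scorable columns")
    return 100.0 * subs / columns, columns


def divergence_matrix(monomers: list[str]) -> DivergenceMatrix:
    """Pairwise percent substitution divergence between monomers.

    Affine gap scoring keeps VNTR copy-number length differences in
    contiguous gap blocks, which are excluded from the statistic, so the
    matrix describes point divergence of the shared sequence regardless of
    per-monomer VNTR expansion.
    """
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers")
    if any(len(m) == 0 for m in monomers):
        raise ValueError("empty monomer")
    seqs = list(monomers)
    n = len(seqs)
    pct = np.zeros((n, n))
    cols = np.zeros((n, n), dtype=int)
    for i in range(n):
        cols[i, i] = len(seqs[i])
        for j in range(i + 1, n):
            d, c = _pair_divergence(seqs[i], seqs[j])
            pct[i, j] = pct[j, i] = d
            cols[i, j] = cols[j, i] = c
    return DivergenceMatrix(pct, cols)


def _internal_repeats(
    monomers: list[str], k: int = 11, min_segment: int = 25
) -> tuple[list[dict | None], float]:
    """Per-monomer internal tandem signal and the consensus unit length.

    For each monomer, forward self-matches at small offsets mark an
    internal sub-repeat; the dominant offset family gives that monomer's
    unit estimate and the matched span its extent.  Monomers whose unit
    disagrees with the across-monomer median by more than 20% are treated
    as having no consistent signal.  Returns ``(per_monomer, unit_length)``
    with ``unit_length == 0.0`` when no monomer has an internal repeat.
    """
    per_monomer: list[dict | None] = []
    for mono in monomers:
        if len(mono) < k:
            per_monomer.append(None)
            continue
        segs = [
            s
            for s in self_matches(mono, k=k, min_segment=min_segment)
            if s.strand == "forward"
        ]
        if not segs:
            per_monomer.append(None)
            continue
        families = _offset_families(segs)
        dominant = max(families, key=lambda f: (f["footprint"], -f["offset"]))
        span_start = min(s.q_start for s in segs)
        span_end = max(s.t_end for s in segs)
        per_monomer.append(
            {
                "unit": dominant["offset"],
                "footprint": span_end - span_start,
                "start": span_start,
            }
        )
    informative = [m for m in per_monomer if m is not None]
    if not informative:
        return per_monomer, 0.0
    unit_length = float(np.median([m["unit"] for m in informative]))
    consistent = [
        m if (m is not None and abs(m["unit"] - unit_length) <= 0.2 * unit_length) else None
        for m in per_monomer
    ]
    if not any(m is not None for m in consistent):
        return consistent, 0.0
    return consistent, unit_length


def _copies(info: dict | None, unit_length: float) -> int:
    if info is None or not unit_length:
        return 1
    return max(1, round(info["footprint"] / unit_length))


def detect_vntr(
    monomers: list[str],
    k: int = 11,
    min_segment: int = 25,
) -> VntrCall:
    """Find the internal tandem sub-repeat and per-monomer copy counts.

    Within each monomer, forward self-matches at small diagonal offsets
    mark the VNTR: the dominant offset family gives the unit length, and
    the span of the internal matches (first to last matched base) covers
    ``copies x unit`` bases, so ``copies = round(span / unit)`` (minimum
    1; a monomer with a single copy has no internal self-match at all).
    The unit interval is reported on the monomer with the strongest
    internal repeat, where the unit is directly observable.
    """
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers")
    internal, unit_length = _internal_repeats(monomers, k=k, min_segment=min_segment)
    if not unit_length:
        return VntrCall(None, 0, [1] * len(monomers), None)
    copies = [_copies(m, unit_length) for m in internal]
    ref_idx = max(
        (i for i, m in enumerate(internal) if m is not None),
        key=lambda i: internal[i]["footprint"],
    )
    ref = internal[ref_idx]
    unit_interval = (ref["start"], ref["start"] + int(round(unit_length)))
    return VntrCall(unit_interval, int(round(unit_length)), copies, ref_idx)
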