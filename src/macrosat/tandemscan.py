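"""Self-alignment of a sequence against itself and repeat calling.

The scanner finds all maximal exact matches of length >= ``min_segment``
between distinct positions of a sequence (forward strand) and between the
sequence and its reverse complement (reverse strand), by exact k-mer
seeding: on a given dotplot diagonal, a maximal exact run of length L
appears as L - k + 1 consecutive seed hits, so merging consecutive hits
per diagonal reconstructs every maximal run exactly — no heuristic
extension step is needed.

Tandem arrays appear as families of forward segments sharing a common
diagonal offset (the repeat period); inverted repeats appear as
reverse-strand segments linking two loci.  Periodicity is estimated from
the offset family with the largest dotplot footprint: matches between
adjacent repeat units tile the whole array, whereas matches internal to a
unit (e.g. a VNTR sub-repeat) cover only their sub-region, so footprint
coverage separates the unit period from both its internal sub-periods and
its multiples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "MatchSegment",
    "Dotplot",
    "TandemArrayCall",
    "InvertedRepeatCall",
    "self_matches",
    "exact_match_runs",
    "build_dotplot",
    "call_tandem_arrays",
    "call_inverted_repeats",
    "survey_chromosome",
]


@dataclass(frozen=True)
class MatchSegment:
    """An exact match between two intervals (0-based, half-open).

    For reverse segments both intervals are given on the input sequence;
    the t-interval matches the reverse complement of the q-interval.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # "forward" | "reverse"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def offset(self) -> int:
        return self.t_start - self.q_start


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def exact_match_runs(
    query: str, target: str, k: int, min_segment: int
) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= ``min_segment`` bp between two sequences.

    Returns ``(q_start, t_start, length)`` triples.  Exhaustive for runs of
    length >= k: every such run contains an exact k-mer seed on its
    diagonal.
    """
    index = _kmer_index(target, k)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    runs = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i > prev + 1:
                length = prev + k - run_start
                if length >= min_segment:
                    runs.append((run_start, run_start + diag, length))
                run_start = i
            prev = i
        length = prev + k - run_start
        if length >= min_segment:
            runs.append((run_start, run_start + diag, length))
    return runs


def self_matches(sequence: str, k: int = 13, min_segment: int = 25) -> list[MatchSegment]:
    """All maximal exact self-matches on both strands.

    The trivial main-diagonal match is excluded and symmetric duplicates
    (q,t)/(t,q) are collapsed: forward segments always have
    ``t_start > q_start`` and reverse segments have their left interval
    first.
    """
    if not 4 <= k <= 32:
        raise ValueError(f"k={k} outside supported range [4, 32]")
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} < k={k}")

    segments: list[MatchSegment] = []
    # forward: only positive diagonals (collapses (q,t)/(t,q) symmetry and
    # drops the main diagonal)
    index = _kmer_index(sequence, k)
    by_diag: dict[int, list[int]] = {}
    for kmer, positions in index.items():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                by_diag.setdefault(j - i, []).append(i)
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i > prev + 1:
                length = prev + k - run_start
                if length >= min_segment:
                    segments.append(
                        MatchSegment(
                            run_start, run_start + length,
                            run_start + diag, run_start + diag + length,
                            "forward",
                        )
                    )
                run_start = i
            prev = i
        length = prev + k - run_start
        if length >= min_segment:
            segments.append(
                MatchSegment(
                    run_start, run_start + length,
                    run_start + diag, run_start + diag + length,
                    "forward",
                )
            )

    # reverse: match against the reverse complement, then map the target
    # interval back onto the input sequence
    seen: set[tuple[int, int, int, int]] = set()
    for q_start, rc_start, length in exact_match_runs(
        sequence, revcomp(sequence), k, min_segment
    ):
        t_lo, t_hi = n - rc_start - length, n - rc_start
        q_lo, q_hi = q_start, q_start + length
        if (t_lo, t_hi) < (q_lo, q_hi):
            q_lo, q_hi, t_lo, t_hi = t_lo, t_hi, q_lo, q_hi
        key = (q_lo, q_hi, t_lo, t_hi)
        if key not in seen:
            seen.add(key)
            segments.append(MatchSegment(q_lo, q_hi, t_lo, t_hi, "reverse"))

    segments.sort(key=lambda s: (s.q_start, s.t_start, s.strand))
    return segments


@dataclass
class Dotplot:
    """Binned match-density grids; a diagnostic artifact, not a caller input."""

    bin_size: int
    forward_counts: np.ndarray
    reverse_counts: np.ndarray

    def to_tsv(self, path, strand: str = "forward") -> None:
        grid = self.forward_counts if strand == "forward" else self.reverse_counts
        np.savetxt(path, grid, fmt="%d", delimiter="\t")


def build_dotplot(
    sequence_length: int, segments: list[MatchSegment], bin_size: int = 500
) -> Dotplot:
    nbins = math.ceil(sequence_length / bin_size)
    fwd = np.zeros((nbins, nbins), dtype=int)
    rev = np.zeros((nbins, nbins), dtype=int)
    for seg in segments:
        offs = np.arange(seg.length)
        qb = (seg.q_start + offs) // bin_size
        if seg.strand == "forward":
            tb = (seg.t_start + offs) // bin_size
            np.add.at(fwd, (qb, tb), 1)
            np.add.at(fwd, (tb, qb), 1)  # keep the grid symmetric
        else:
            tb = (seg.t_end - 1 - offs) // bin_size
            np.add.at(rev, (qb, tb), 1)
            np.add.at(rev, (tb, qb), 1)
    return Dotplot(bin_size, fwd, rev)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


@dataclass
class TandemArrayCall:
    interval: tuple[int, int]
    copy_estimate: float
    period_stats: tuple[int, float, int]  # (min, median, max) unit-family offset
    support: int

    @property
    def span(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class InvertedRepeatCall:
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    spacer: int
    support: int


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for a, b in sorted(intervals):
        if a > end:
            total += b - a
            end = b
        elif b > end:
            total += b - end
            end = b
    return total


def _offset_families(
    segs: list[MatchSegment], tol: float = 0.10
) -> list[dict]:
    """Cluster segment offsets within ``tol`` relative tolerance.

    Returns one record per family with its member segments, weighted-median
    offset and dotplot footprint coverage (union of q- and t-intervals).
    """
    ordered = sorted(segs, key=lambda s: s.offset)
    families: list[list[MatchSegment]] = []
    for seg in ordered:
        if families and seg.offset <= families[-1][0].offset * (1 + tol):
            families[-1].append(seg)
        else:
            families.append([seg])
    out = []
    for members in families:
        offsets = np.array([s.offset for s in members], dtype=float)
        weights = np.array([s.length for s in members], dtype=float)
        order = np.argsort(offsets)
        cum = np.cumsum(weights[order])
        median = float(offsets[order][np.searchsorted(cum, cum[-1] / 2.0)])
        footprint = _union_length(
            [(s.q_start, s.q_end) for s in members]
            + [(s.t_start, s.t_end) for s in members]
        )
        out.append(
            {"members": members, "offset": median, "footprint": footprint}
        )
    return out


def _unit_period(segs: list[MatchSegment]) -> tuple[float, tuple[int, float, int]] | None:
    """Estimate the repeat unit period of one segment cluster.

    Matches between copies k units apart tile (most of) the array for every
    small k, so all unit-multiple families have comparable footprint
    coverage; an internal sub-repeat (e.g. a VNTR) covers only its own
    sub-region.  The unit family is therefore the smallest-offset family
    whose footprint is within 60% of the best; families whose offset rounds
    to one unit are pooled (monomer-length variation spreads adjacent-unit
    offsets), multiples fold out.
    """
    families = _offset_families(segs)
    if not families:
        return None
    best_footprint = max(f["footprint"] for f in families)
    dominant = min(
        (f for f in families if f["footprint"] >= 0.6 * best_footprint),
        key=lambda f: f["offset"],
    )
    pooled = [
        s
        for fam in families
        if round(fam["offset"] / dominant["offset"]) == 1
        for s in fam["members"]
    ]
    offsets = np.array([s.offset for s in pooled], dtype=float)
    weights = np.array([s.length for s in pooled], dtype=float)
    order = np.argsort(offsets)
    cum = np.cumsum(weights[order])
    period = float(offsets[order][np.searchsorted(cum, cum[-1] / 2.0)])
    stats = (int(offsets.min()), period, int(offsets.max()))
    return period, stats


def call_tandem_arrays(
    segments: list[MatchSegment],
    min_span: int = 10_000,
    min_copies: int = 3,
    max_gap: int = 2_000,
) -> list[TandemArrayCall]:
    """Cluster forward self-matches into tandem-array calls.

    Segments are clustered by overlapping dotplot footprints (the interval
    from q_start to t_end) with gaps up to ``max_gap`` bridged; a cluster
    whose union footprint spans >= ``min_span`` and whose periodicity
    implies >= ``min_copies`` units becomes one call with
    ``copy_estimate = span / unit period``.
    """
    fwd = sorted(
        (s for s in segments if s.strand == "forward" and s.offset > 0),
        key=lambda s: s.q_start,
    )
    calls = []
    cluster: list[MatchSegment] = []
    cluster_end = -1

    def flush(cluster: list[MatchSegment]) -> None:
        start = min(s.q_start for s in cluster)
        end = max(s.t_end for s in cluster)
        if end - start < min_span:
            return
        est = _unit_period(cluster)
        if est is None:
            return
        period, stats = est
        copies = (end - start) / period
        if copies < max(2, min_copies):
            return
        calls.append(TandemArrayCall((start, end), copies, stats, len(cluster)))

    for seg in fwd:
        if cluster and seg.q_start <= cluster_end + max_gap:
            cluster.append(seg)
            cluster_end = max(cluster_end, seg.t_end)
        else:
            if cluster:
                flush(cluster)
            cluster = [seg]
            cluster_end = seg.t_end
    if cluster:
        flush(cluster)
    calls.sort(key=lambda c: c.interval)
    return calls


def call_inverted_repeats(
    segments: list[MatchSegment],
    min_arm: int = 1_000,
    max_spacer: int = 50_000,
    max_gap: int = 2_000,
) -> list[InvertedRepeatCall]:
    """Cluster reverse-strand matches into inverted-repeat calls.

    Only segments whose q-interval lies entirely left of their t-interval
    contribute; arms are the union footprints of the clustered q- and
    t-intervals, and the spacer is the gap between the arms.  Calls with
    arm lengths differing by more than 20% are discarded as unbalanced.
    """
    rev = sorted(
        (s for s in segments if s.strand == "reverse" and s.q_end <= s.t_start),
        key=lambda s: s.q_start,
    )
    clusters: list[list[MatchSegment]] = []
    for seg in rev:
        placed = False
        for cl in clusters:
            q_lo = min(s.q_start for s in cl)
            q_hi = max(s.q_end for s in cl)
            t_lo = min(s.t_start for s in cl)
            t_hi = max(s.t_end for s in cl)
            if (
                seg.q_start <= q_hi + max_gap
                and seg.q_end >= q_lo - max_gap
                and seg.t_start <= t_hi + max_gap
                and seg.t_end >= t_lo - max_gap
            ):
                cl.append(seg)
                placed = True
                break
        if not placed:
            clusters.append([seg])

    calls = []
    for cl in clusters:
        left = (min(s.q_start for s in cl), max(s.q_end for s in cl))
        right = (min(s.t_start for s in cl), max(s.t_end for s in cl))
        if right[0] < left[1]:  # arms must not overlap
            continue
        arm_lens = (left[1] - left[0], right[1] - right[0])
        if min(arm_lens) < min_arm:
            continue
        if min(arm_lens) < 0.8 * max(arm_lens):
            continue
        spacer = right[0] - left[1]
        if spacer > max_spacer:
            continue
        calls.append(InvertedRepeatCall(left, right, spacer, len(cl)))
    calls.sort(key=lambda c: c.left_arm)
    return calls


def survey_chromosome(
    genome: str,
    window: int = 500_000,
    step: int = 250_000,
    k: int = 13,
    min_segment: int = 25,
    min_span: int = 10_000,
    min_copies: int = 3,
    max_gap: int = 2_000,
) -> list[dict]:
    """Windowed tandem-repeat survey of a chromosome.

    Each window is scanned independently; a window reports the largest call
    overlapping it by at least 50% of the call's span (span 0 if none).
    Returns one row dict per window.
    """
    if window < step:
        raise ValueError("window must be >= step")
    n = len(genome)
    if window > n:
        logger.warning(
            "window (%d) exceeds genome length (%d); using a single window", window, n
        )
        window = step = n

    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts:
        starts = [0]

    # pool calls from all windows, de-duplicating heavily overlapping ones
    pooled: list[TandemArrayCall] = []
    for w_start in starts:
        chunk = genome[w_start : w_start + window]
        segs = self_matches(chunk, k=k, min_segment=min_segment)
        for call in call_tandem_arrays(
            segs, min_span=min_span, min_copies=min_copies, max_gap=max_gap
        ):
            a, b = call.interval
            shifted = TandemArrayCall(
                (a + w_start, b + w_start),
                call.copy_estimate,
                call.period_stats,
                call.support,
            )
            dup = False
            for i, prev in enumerate(pooled):
                lo = max(prev.interval[0], shifted.interval[0])
                hi = min(prev.interval[1], shifted.interval[1])
                if hi - lo >= 0.5 * min(prev.span, shifted.span):
                    if shifted.span > prev.span:
                        pooled[i] = shifted
                    dup = True
                    break
            if not dup:
                pooled.append(shifted)

    rows = []
    for w_start in starts:
        w_end = min(w_start + window, n)
        best = None
        for call in pooled:
            lo = max(call.interval[0], w_start)
            hi = min(call.interval[1], w_end)
            if hi - lo >= 0.5 * call.span and (best is None or call.span > best.span):
                best = call
        rows.append(
            {
                "window_start": w_start,
                "window_end": w_end,
                "largest_span": best.span if best else 0,
                "period_median": best.period_stats[1] if best else 0.0,
                "copy_estimate": round(best.copy_estimate, 2) if best else 0.0,
            }
        )
    return rows
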