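"""Base composition, CpG statistics and CpG-island calling.

Island criteria follow the classical Gardiner-Garden & Frommer thresholds
(length >= 200 bp, GC >= 50%, CpG observed/expected >= 0.6), evaluated on
every 200-bp window stepped by 1 bp; overlapping qualifying windows are
merged, so an island is the maximal extent covered by qualifying windows.
Ambiguous bases (anything outside ACGT) are excluded from all counts, and
a CpG spanning an ambiguous base is not counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CgiCall",
    "gc_fraction",
    "at_fraction",
    "cpg_count",
    "cpg_obs_exp",
    "find_cgis",
]


@dataclass
class CgiCall:
    interval: tuple[int, int]
    gc_fraction: float
    cpg_count: int
    obs_exp: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def _counts(seq: str) -> tuple[int, int, int]:
    s = seq.upper()
    c = s.count("C")
    g = s.count("G")
    unambig = c + g + s.count("A") + s.count("T")
    return c, g, unambig


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / #unambiguous bases; errors on all-ambiguous input."""
    if not sequence:
        raise ValueError("empty sequence")
    c, g, unambig = _counts(sequence)
    if unambig == 0:
        raise ValueError("sequence contains no unambiguous base")
    return (c + g) / unambig


def at_fraction(sequence: str) -> float:
    return 1.0 - gc_fraction(sequence)


def cpg_count(sequence: str) -> int:
    """Number of CG dinucleotides (CG cannot overlap itself)."""
    return sequence.upper().count("CG")


def cpg_obs_exp(sequence: str) -> float:
    """Observed CpG count over (#C * #G / #unambiguous bases).

    Zero C or zero G makes the expectation degenerate; the ratio is then
    reported as 0 with a warning.
    """
    c, g, unambig = _counts(sequence)
    if c == 0 or g == 0:
        warnings.warn("no C or no G: CpG obs/exp reported as 0", stacklevel=2)
        return 0.0
    return cpg_count(sequence) / (c * g / unambig)


def find_cgis(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
) -> list[CgiCall]:
    """CpG islands as merged runs of qualifying ``min_length``-bp windows.

    A window qualifies when GC fraction, CpG obs/exp and length all meet
    the thresholds; overlapping qualifying windows merge into one island
    covering their union, whose metrics are then reported for the merged
    interval.
    """
    n = len(sequence)
    if n < min_length:
        raise ValueError(f"sequence length {n} < min_length {min_length}")
    s = sequence.upper()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_acgt = is_c | is_g | (arr == ord("A")) | (arr == ord("T"))
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def window_sum(mask: np.ndarray, width: int) -> np.ndarray:
        cum = np.concatenate(([0], np.cumsum(mask)))
        return cum[width:] - cum[:-width]

    w = min_length
    c_w = window_sum(is_c, w)
    g_w = window_sum(is_g, w)
    ok_w = window_sum(is_acgt, w)
    # a CpG belongs to a window only if both bases lie inside it
    cpg_w = window_sum(is_cpg, w - 1)[: n - w + 1] if w >= 2 else is_cpg[: n - w + 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        gc_ok = np.where(ok_w > 0, (c_w + g_w) / np.maximum(ok_w, 1), 0.0) >= min_gc
        expected = c_w * g_w / np.maximum(ok_w, 1)
        oe_ok = np.where(expected > 0, cpg_w / np.maximum(expected, 1e-300), 0.0) >= min_obs_exp
    qualifying = gc_ok & oe_ok & (ok_w > 0)

    calls = []
    starts = np.flatnonzero(qualifying)
    if starts.size:
        run_start = prev = starts[0]
        runs = []
        for i in starts[1:]:
            if i >= prev + w:  # windows no longer overlap: close the island
                runs.append((run_start, prev + w))
                run_start = i
            prev = i
        runs.append((run_start, prev + w))
        for a, b in runs:
            region = s[a:b]
            calls.append(
                CgiCall(
                    interval=(int(a), int(b)),
                    gc_fraction=gc_fraction(region),
                    cpg_count=cpg_count(region),
                    obs_exp=cpg_obs_exp(region),
                )
            )
    return calls
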