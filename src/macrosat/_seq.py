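"""Low-level DNA string utilities shared across modules.

Sequences are plain upper-case Python strings over {A,C,G,T} (ambiguity
codes tolerated where a function says so).  Mutation helpers operate on
uint8 views for speed.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# base byte -> index in ACGT, 255 for anything else
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """uint8 byte view of a sequence (copy)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_dna(length: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform sequence over the four bases."""
    return decode(_BASES[rng.integers(0, 4, size=length)])


def substitute(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply i.i.d. per-base substitutions; a hit always changes the base.

    Returns the mutated sequence and the 0-based positions that were
    substituted.
    """
    arr = encode(seq)
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        idx = _BASE_INDEX[arr[hits]]
        # shift by 1..3 so the new base always differs from the old one
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASES[(idx + shift) % 4]
    return decode(arr), hits


def apply_indels(
    seq: str,
    rate: float,
    max_len: int,
    rng: np.random.Generator,
) -> str:
    """Insert/delete at i.i.d. per-base event rate.

    Event lengths are geometric (p=0.5) capped at ``max_len``; insertions
    and deletions are equally likely.  Applied right-to-left so earlier
    event coordinates stay valid.
    """
    if rate <= 0:
        return seq
    arr = list(seq)
    sites = np.flatnonzero(rng.random(len(arr)) < rate)[::-1]
    for pos in sites:
        length = min(int(rng.geometric(0.5)), max_len)
        if rng.random() < 0.5:
            ins = random_dna(length, rng)
            arr[pos:pos] = list(ins)
        else:
            del arr[pos : pos + length]
    return "".join(arr)
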