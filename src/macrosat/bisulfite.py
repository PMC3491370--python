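"""Bisulfite clone methylation calling and two-group comparison.

A sequenced clone of bisulfite-converted DNA reads C where the genomic
cytosine was methylated and T where it was unmethylated.  At each
reference CpG a clone is therefore called methylated (C), unmethylated
(T) or absent (any other base or a deletion — typically a CpG-destroying
variant, drawn as a dash in methylation lollipop diagrams).

Per-clone percent methylation (absent sites excluded from the
denominator) is the unit of analysis; groups are compared with the
two-tailed Welch t-test (unequal variances, Welch-Satterthwaite degrees
of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from .seqsim import ABSENT, METHYLATED, UNMETHYLATED, cpg_sites

__all__ = [
    "CloneProfile",
    "GroupComparison",
    "call_clone_methylation",
    "percent_methylation",
    "compare_groups",
    "welch_ttest",
]

MIN_CLONES_RECOMMENDED = 9  # methylation profiles are usually >= 9 clones
CONVERSION_QC_THRESHOLD = 0.95


@dataclass
class CloneProfile:
    clone_id: str
    site_states: list[str]  # M / U / - per reference CpG, in order
    conversion_qc: float | None = None  # fraction of non-CpG C read as T

    def __post_init__(self) -> None:
        bad = set(self.site_states) - {METHYLATED, UNMETHYLATED, ABSENT}
        if bad:
            raise ValueError(f"invalid site states: {sorted(bad)}")

    @property
    def conversion_failed(self) -> bool:
        return self.conversion_qc is not None and self.conversion_qc < CONVERSION_QC_THRESHOLD


@dataclass
class GroupComparison:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    t: float
    dof: float
    p: float
    zero_variance_flag: bool = False


def _map_clone_to_reference(reference: str, clone: str) -> list[str | None]:
    """Per-reference-position clone base (None where deleted).

    Global alignment with C/T treated as equal (bisulfite conversion is
    not a mismatch); raises if identity under that equivalence is < 80%.
    """
    if len(clone) == len(reference):
        # synthetic clones and indel-free Sanger reads share coordinates
        mapped: list[str | None] = list(clone)
        matches = sum(
            1
            for r, c in zip(reference, clone)
            if r == c or (r == "C" and c == "T") or (r == "T" and c == "C")
        )
        if matches / len(reference) < 0.8:
            raise ValueError("clone does not match region")
        return mapped
    result = edlib.align(
        clone,
        reference,
        mode="NW",
        task="path",
        additionalEqualities=[("C", "T")],
    )
    identity = 1.0 - result["editDistance"] / max(len(reference), len(clone))
    if identity < 0.8:
        raise ValueError("clone does not match region")
    mapped = [None] * len(reference)
    qi = ti = 0
    for n, op in _cigar_ops(result["cigar"]):
        if op in "=X":
            for _ in range(n):
                mapped[ti] = clone[qi]
                qi += 1
                ti += 1
        elif op == "I":  # insertion in clone
            qi += n
        else:  # deletion: reference bases unmatched
            ti += n
    return mapped


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def call_clone_methylation(
    reference: str, clone: str, clone_id: str = "clone"
) -> CloneProfile:
    """Three-state methylation call at every reference CpG.

    Also computes conversion QC: the fraction of non-CpG reference
    cytosines reading T.  A QC below 0.95 flags failed conversion (the
    clone is flagged, not dropped).
    """
    sites = cpg_sites(reference)
    if sites.size == 0:
        raise ValueError("reference contains no CpG site")
    mapped = _map_clone_to_reference(reference, clone)
    states = []
    for pos in sites:
        base = mapped[pos]
        if base == "C":
            states.append(METHYLATED)
        elif base == "T":
            states.append(UNMETHYLATED)
        else:
            states.append(ABSENT)
    non_cpg_c = [
        i for i, r in enumerate(reference) if r == "C" and i not in set(sites)
    ]
    covered = [i for i in non_cpg_c if mapped[i] is not None]
    qc = (
        sum(1 for i in covered if mapped[i] == "T") / len(covered)
        if covered
        else None
    )
    profile = CloneProfile(clone_id, states, conversion_qc=qc)
    if profile.conversion_failed:
        warnings.warn(
            f"{clone_id}: conversion QC {qc:.2f} < {CONVERSION_QC_THRESHOLD}",
            stacklevel=2,
        )
    return profile


def percent_methylation(profile: CloneProfile) -> float | None:
    """100 * methylated / (methylated + unmethylated); absent sites excluded.

    Returns None (with a warning) when every site is absent.
    """
    m = profile.site_states.count(METHYLATED)
    u = profile.site_states.count(UNMETHYLATED)
    if m + u == 0:
        warnings.warn(f"{profile.clone_id}: all sites absent, clone dropped", stacklevel=2)
        return None
    return 100.0 * m / (m + u)


def welch_ttest(values1, values2) -> GroupComparison:
    """Two-tailed Welch t-test on two samples of per-clone percentages."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 clones per group")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if m1 == m2:
            return GroupComparison(m1, m2, 0.0, 0.0, n1, n2, 0.0, float(n1 + n2 - 2), 1.0)
        return GroupComparison(
            m1, m2, 0.0, 0.0, n1, n2,
            float("inf") if m1 > m2 else float("-inf"),
            float(n1 + n2 - 2), 0.0, zero_variance_flag=True,
        )
    t = (m1 - m2) / np.sqrt(se2)
    dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return GroupComparison(
        float(m1), float(m2), float(np.sqrt(v1)), float(np.sqrt(v2)),
        n1, n2, float(t), float(dof), float(p),
    )


def compare_groups(
    profiles1: list[CloneProfile], profiles2: list[CloneProfile]
) -> GroupComparison:
    """Welch comparison of per-clone percent methylation between two groups.

    Clones with every site absent are dropped; fewer than 9 clones per
    group draws a warning (profiles are conventionally built from at
    least nine independent clones) but is not an error.
    """
    vals1 = [p for p in (percent_methylation(c) for c in profiles1) if p is not None]
    vals2 = [p for p in (percent_methylation(c) for c in profiles2) if p is not None]
    for name, vals in (("group 1", vals1), ("group 2", vals2)):
        if len(vals) < MIN_CLONES_RECOMMENDED:
            warnings.warn(
                f"{name}: only {len(vals)} informative clones "
                f"(< {MIN_CLONES_RECOMMENDED} conventionally used)",
                stacklevel=2,
            )
    return welch_ttest(vals1, vals2)
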