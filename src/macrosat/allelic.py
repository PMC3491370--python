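"""Strain-SNP discovery and allele-specific read assignment.

SNPs discriminating two strains are called from clone sequencing of each
strain: a position is a variant when the two within-strain consensus
(modal) bases differ and each strain's modal fraction clears a support
threshold.

Reads are assigned to a haplotype by perfect-identity placement: a read
belongs to haplotype A when some exact substring match of at least
``min_overlap`` bp between read and haplotype A covers a discriminating
site, and no such qualifying match exists against haplotype B (and
symmetrically for B).  Reads matching both haplotypes — or covering no
discriminating site — are uninformative.  This automates manual
allele-calling at 100% sequence identity over a minimum of 30 bp.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .tandemscan import exact_match_runs

__all__ = [
    "StrainVariant",
    "ReadAssignment",
    "AssignmentSummary",
    "HaplotypeAssigner",
    "call_strain_snps",
    "assign_read",
    "summarize_assignments",
    "apply_variants",
]

LABEL_A = "A"
LABEL_B = "B"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class StrainVariant:
    position: int  # 0-based on the reference
    allele_A: str
    allele_B: str
    support_A: float  # modal fraction among strain-A clones
    support_B: float


@dataclass
class ReadAssignment:
    read_id: str
    label: str  # A / B / uninformative
    matched_overlap: int  # longest qualifying perfect match, bp
    discriminating_sites_covered: int
    flag: str = ""


@dataclass
class AssignmentSummary:
    counts: dict[str, int]
    fractions: dict[str, float]  # over informative reads only
    total: int
    informative: int


def _align_to_reference(clone: str, reference: str) -> list[str | None] | None:
    """Per-reference-position clone base, or None if unalignable (<80% id)."""
    if len(clone) == len(reference):
        matches = sum(1 for a, b in zip(clone, reference) if a == b)
        if matches / len(reference) < 0.8:
            return None
        return list(clone)
    result = edlib.align(clone, reference, mode="NW", task="path")
    if 1.0 - result["editDistance"] / max(len(clone), len(reference)) < 0.8:
        return None
    mapped: list[str | None] = [None] * len(reference)
    qi = ti = 0
    num = ""
    for ch in result["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                mapped[ti] = clone[qi]
                qi += 1
                ti += 1
        elif ch == "I":
            qi += n
        else:
            ti += n
    return mapped


def call_strain_snps(
    clones_A: list[str],
    clones_B: list[str],
    reference: str,
    min_support: float = 0.9,
) -> list[StrainVariant]:
    """Positions where the two strains' clone consensuses disagree.

    Per position and strain, the consensus is the modal base among clones
    covering it; a variant requires both modal fractions >= ``min_support``
    and different consensus bases.  Unalignable clones are skipped with a
    warning.
    """
    if len(clones_A) < 2 or len(clones_B) < 2:
        raise ValueError("need at least 2 clones per strain")

    def consensus_profile(clones: list[str], strain: str):
        mapped = []
        for i, clone in enumerate(clones):
            m = _align_to_reference(clone, reference)
            if m is None:
                warnings.warn(f"strain {strain} clone {i} unalignable, skipped", stacklevel=2)
            else:
                mapped.append(m)
        if len(mapped) < 2:
            raise ValueError(f"strain {strain}: fewer than 2 alignable clones")
        cons = []
        for pos in range(len(reference)):
            bases = Counter(
                m[pos] for m in mapped if m[pos] is not None and m[pos] in "ACGT"
            )
            if not bases:
                cons.append((None, 0.0))
                continue
            base, count = bases.most_common(1)[0]
            cons.append((base, count / sum(bases.values())))
        return cons

    cons_a = consensus_profile(clones_A, "A")
    cons_b = consensus_profile(clones_B, "B")
    variants = []
    for pos, ((a, fa), (b, fb)) in enumerate(zip(cons_a, cons_b)):
        if a is None or b is None or a == b:
            continue
        if fa >= min_support and fb >= min_support:
            variants.append(StrainVariant(pos, a, b, fa, fb))
    return variants


def apply_variants(reference: str, variants: list[StrainVariant]) -> tuple[str, str]:
    """Build the two haplotype sequences from reference + variants."""
    hap_a = list(reference)
    hap_b = list(reference)
    for v in variants:
        hap_a[v.position] = v.allele_A
        hap_b[v.position] = v.allele_B
    return "".join(hap_a), "".join(hap_b)


class HaplotypeAssigner:
    """Assign reads to haplotypes by the perfect-identity/min-overlap rule.

    Pre-indexes both haplotypes once so that large read sets assign
    quickly; discriminating sites are the positions where the haplotypes
    differ (haplotypes must be equal length — substitution SNPs only).
    """

    def __init__(self, haplotype_A: str, haplotype_B: str, min_overlap: int = 30):
        if len(haplotype_A) != len(haplotype_B):
            raise ValueError("haplotypes must have equal length")
        self.hap_a = haplotype_A
        self.hap_b = haplotype_B
        self.min_overlap = min_overlap
        self.sites = np.flatnonzero(
            np.frombuffer(haplotype_A.encode(), dtype=np.uint8)
            != np.frombuffer(haplotype_B.encode(), dtype=np.uint8)
        )
        # any exact run >= min_overlap contains an aligned exact k-mer for
        # k = min_overlap // 2, so seeding at that k is exhaustive
        self.k = max(8, min_overlap // 2)

    def _qualifying(self, read: str, hap: str) -> tuple[int, int]:
        """(best overlap, sites covered) over perfect matches >= min_overlap
        that cover at least one discriminating site."""
        best_len = 0
        best_sites = 0
        for q_start, t_start, length in exact_match_runs(read, hap, self.k, self.min_overlap):
            lo = np.searchsorted(self.sites, t_start)
            hi = np.searchsorted(self.sites, t_start + length)
            covered = int(hi - lo)
            if covered >= 1 and (length, covered) > (best_len, best_sites):
                best_len, best_sites = length, covered
        return best_len, best_sites

    def assign(self, read: str, read_id: str = "read") -> ReadAssignment:
        if len(read) < self.min_overlap:
            return ReadAssignment(
                read_id, UNINFORMATIVE, 0, 0, flag="read shorter than min_overlap"
            )
        len_a, sites_a = self._qualifying(read, self.hap_a)
        len_b, sites_b = self._qualifying(read, self.hap_b)
        if len_a and not len_b:
            return ReadAssignment(read_id, LABEL_A, len_a, sites_a)
        if len_b and not len_a:
            return ReadAssignment(read_id, LABEL_B, len_b, sites_b)
        return ReadAssignment(read_id, UNINFORMATIVE, max(len_a, len_b), 0)


def assign_read(
    read: str,
    haplotype_A: str,
    haplotype_B: str,
    min_overlap: int = 30,
    read_id: str = "read",
) -> ReadAssignment:
    """One-shot convenience wrapper around :class:`HaplotypeAssigner`."""
    return HaplotypeAssigner(haplotype_A, haplotype_B, min_overlap).assign(read, read_id)


def summarize_assignments(assignments: list[ReadAssignment]) -> AssignmentSummary:
    counts = Counter(a.label for a in assignments)
    counts.setdefault(LABEL_A, 0)
    counts.setdefault(LABEL_B, 0)
    counts.setdefault(UNINFORMATIVE, 0)
    informative = counts[LABEL_A] + counts[LABEL_B]
    fractions = {
        LABEL_A: counts[LABEL_A] / informative if informative else float("nan"),
        LABEL_B: counts[LABEL_B] / informative if informative else float("nan"),
    }
    return AssignmentSummary(dict(counts), fractions, len(assignments), informative)
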