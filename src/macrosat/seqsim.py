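"""Synthetic-data generators with full ground truth.

Every downstream stage of the pipeline (tandem-array calling, monomer and
VNTR decomposition, bisulfite methylation profiling, allele-specific read
assignment, conserved-motif extraction) is exercised against sequences
produced here, so each generator returns both the data and a truth record
describing exactly what was planted.

Design notes
------------
* Background sequence is i.i.d. uniform over the four bases: it carries no
  repeat structure of its own, so any false tandem call is attributable to
  the caller, not the simulator.
* One seed per simulation call; per-monomer / per-clone / per-read
  sub-streams are derived deterministically from it via
  ``numpy.random.SeedSequence.spawn``, so identical specs give
  byte-identical output.
* The array generator's ``divergence`` parameter is the expected pairwise
  divergence *between* monomers; each monomer is therefore mutated at
  ``divergence / 2`` relative to the shared template (two independently
  mutated copies differ at roughly twice the per-copy rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import apply_indels, random_dna, revcomp, substitute

__all__ = [
    "ArraySpec",
    "PlantedTruth",
    "BisulfiteSimSpec",
    "AllelicSimSpec",
    "SpeciesSimSpec",
    "SimClone",
    "SimRead",
    "generate_array",
    "generate_inverted_repeat",
    "plant_features",
    "simulate_bisulfite_clones",
    "simulate_allelic_reads",
    "simulate_species_monomers",
    "default_array_spec",
    "design_monomer_template",
    "design_cgi_fragment",
    "biased_dna",
]

METHYLATED = "M"
UNMETHYLATED = "U"
ABSENT = "-"


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


def cpg_sites(seq: str) -> np.ndarray:
    """0-based start positions of CG dinucleotides."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


# ---------------------------------------------------------------------------
# tandem array
# ---------------------------------------------------------------------------


@dataclass
class ArraySpec:
    """Parameters of a planted macrosatellite array.

    ``monomer_template`` must carry one copy of ``vntr_unit`` starting at
    ``vntr_insert_position``; additional copies per monomer are inserted
    adjacent to it, so a monomer with ``c`` copies has length
    ``len(monomer_template) + (c - 1) * len(vntr_unit)`` (before indels).

    ``divergence`` is the expected pairwise inter-monomer divergence; each
    monomer is substituted at ``divergence / 2`` relative to the template.
    """

    monomer_template: str
    copy_count: int
    vntr_unit: str
    vntr_insert_position: int
    vntr_copies: Sequence[int]
    divergence: float = 0.05
    indel_rate: float = 0.0
    max_indel_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.copy_count >= 1, "copy_count", "must be a positive integer")
        _check(
            len(self.vntr_copies) == self.copy_count,
            "vntr_copies",
            f"length {len(self.vntr_copies)} != copy_count {self.copy_count}",
        )
        _check(
            all(c >= 1 for c in self.vntr_copies),
            "vntr_copies",
            "every entry must be >= 1",
        )
        _check(0.0 <= self.divergence <= 1.0, "divergence", "must lie in [0, 1]")
        _check(0.0 <= self.indel_rate <= 1.0, "indel_rate", "must lie in [0, 1]")
        _check(
            0 <= self.vntr_insert_position
            <= len(self.monomer_template) - len(self.vntr_unit),
            "vntr_insert_position",
            "VNTR unit must fit inside the template",
        )
        p = self.vntr_insert_position
        _check(
            self.monomer_template[p : p + len(self.vntr_unit)] == self.vntr_unit,
            "vntr_insert_position",
            "template must contain one copy of vntr_unit at this offset",
        )


@dataclass
class PlantedTruth:
    """Ground-truth coordinates of every simulated feature (0-based, half-open)."""

    array_interval: tuple[int, int]
    monomer_intervals: list[tuple[int, int]]
    vntr_copy_counts: list[int]
    variant_positions: list[np.ndarray]
    vntr_unit_length: int = 0
    vntr_local_start: int = 0  # unit offset within each monomer
    inverted_repeat_arms: tuple[tuple[int, int], tuple[int, int]] | None = None

    def shifted(self, offset: int) -> "PlantedTruth":
        """Truth with all genome-scale intervals moved by ``offset`` bp."""
        s, e = self.array_interval
        return PlantedTruth(
            array_interval=(s + offset, e + offset),
            monomer_intervals=[(a + offset, b + offset) for a, b in self.monomer_intervals],
            vntr_copy_counts=list(self.vntr_copy_counts),
            variant_positions=self.variant_positions,
            vntr_unit_length=self.vntr_unit_length,
            vntr_local_start=self.vntr_local_start,
            inverted_repeat_arms=None
            if self.inverted_repeat_arms is None
            else tuple(
                (a + offset, b + offset) for a, b in self.inverted_repeat_arms
            ),
        )


def design_monomer_template(
    total_length: int,
    unit_length: int,
    insert_position: int,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Random monomer template of ``total_length`` bp carrying one VNTR unit.

    Returns ``(template, unit)`` with the unit placed at ``insert_position``.
    """
    if not 0 <= insert_position <= total_length - unit_length:
        raise ValueError("insert_position: unit must fit inside the template")
    left = random_dna(insert_position, rng)
    unit = random_dna(unit_length, rng)
    right = random_dna(total_length - insert_position - unit_length, rng)
    return left + unit + right, unit


def default_array_spec(seed: int = 0, divergence: float = 0.05) -> ArraySpec:
    """Study-condition array: 3.8-kb template, 7 monomers, 900-bp VNTR at
    copies [2,1,3,2,1,2,3] (array span ~33 kb, emulating the ~36-kb locus)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 94]))
    template, unit = design_monomer_template(3800, 900, 900, rng)
    return ArraySpec(
        monomer_template=template,
        copy_count=7,
        vntr_unit=unit,
        vntr_insert_position=900,
        vntr_copies=[2, 1, 3, 2, 1, 2, 3],
        divergence=divergence,
        indel_rate=0.0,
        seed=seed,
    )


def generate_array(spec: ArraySpec) -> tuple[str, PlantedTruth]:
    """Concatenate ``copy_count`` mutated monomers and record exact truth.

    Each monomer is the template with its VNTR expanded to the requested
    copy number, then substituted at ``divergence / 2`` per base (and
    optionally indel-mutated).  Identical spec + seed give identical output.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.copy_count)
    p = spec.vntr_insert_position
    unit = spec.vntr_unit
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    variants: list[np.ndarray] = []
    pos = 0
    for copies, stream in zip(spec.vntr_copies, streams):
        rng = np.random.default_rng(stream)
        monomer = (
            spec.monomer_template[:p]
            + unit * (copies - 1)
            + spec.monomer_template[p:]
        )
        monomer, subs = substitute(monomer, spec.divergence / 2.0, rng)
        monomer = apply_indels(monomer, spec.indel_rate, spec.max_indel_len, rng)
        parts.append(monomer)
        intervals.append((pos, pos + len(monomer)))
        variants.append(subs)
        pos += len(monomer)
    truth = PlantedTruth(
        array_interval=(0, pos),
        monomer_intervals=intervals,
        vntr_copy_counts=list(spec.vntr_copies),
        variant_positions=variants,
        vntr_unit_length=len(unit),
        vntr_local_start=p,
    )
    return "".join(parts), truth


def generate_inverted_repeat(
    arm_length: int, spacer_length: int, seed: int = 0
) -> tuple[str, tuple[tuple[int, int], tuple[int, int]]]:
    """Palindromic fragment ``arm + spacer + revcomp(arm)`` with arm truth."""
    rng = np.random.default_rng(seed)
    arm = random_dna(arm_length, rng)
    spacer = random_dna(spacer_length, rng)
    seq = arm + spacer + revcomp(arm)
    arms = (
        (0, arm_length),
        (arm_length + spacer_length, 2 * arm_length + spacer_length),
    )
    return seq, arms


def biased_dna(
    length: int,
    rng: np.random.Generator,
    gc: float = 0.42,
    cpg_factor: float = 0.2,
) -> str:
    """Composition-biased sequence with first-order CpG suppression.

    Bases are drawn at the given GC fraction; after a C, the probability
    of G is multiplied by ``cpg_factor`` (renormalized), emulating the
    CpG depletion of mammalian genomic DNA (observed/expected ~ 0.2).
    ``cpg_factor=1`` with ``gc=0.5`` reduces to the uniform model.
    """
    if not 0 < gc < 1:
        raise ValueError("gc: must lie strictly in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    p_after_c = p.copy()
    p_after_c[2] *= cpg_factor
    p_after_c /= p_after_c.sum()
    cum = np.cumsum(p)
    cum_after_c = np.cumsum(p_after_c)
    draws = rng.random(length)
    out = []
    prev_c = False
    for u in draws:
        idx = int(np.searchsorted(cum_after_c if prev_c else cum, u))
        base = "ACGT"[min(idx, 3)]
        out.append(base)
        prev_c = base == "C"
    return "".join(out)


def design_cgi_fragment(
    length: int,
    n_cpgs: int,
    gc: float,
    rng: np.random.Generator,
) -> str:
    """GC-rich fragment carrying ~``n_cpgs`` CG dinucleotides.

    Emulates a compact CpG island (a few hundred bp, dozens of CpGs,
    elevated GC) for planting next to a simulated array.  CG dinucleotides
    are placed at spaced positions; the remaining bases are drawn at the
    GC fraction needed to hit the overall target, avoiding incidental CG
    formation so the CpG count stays close to ``n_cpgs``.
    """
    if 2 * n_cpgs > length:
        raise ValueError("n_cpgs: too many CpGs for the fragment length")
    slots = np.sort(rng.choice(length // 2 - 1, size=n_cpgs, replace=False)) * 2
    seq = [""] * length
    for s in slots:
        seq[s], seq[s + 1] = "C", "G"
    # remaining GC needed once the planted CGs are accounted for
    rest = length - 2 * n_cpgs
    gc_rest = max(0.0, min(1.0, (gc * length - 2 * n_cpgs) / max(rest, 1)))
    prev = ""
    for i in range(length):
        if seq[i]:
            prev = seq[i]
            continue
        while True:
            if rng.random() < gc_rest:
                base = "GC"[rng.integers(0, 2)]
            else:
                base = "AT"[rng.integers(0, 2)]
            nxt = seq[i + 1] if i + 1 < length else ""
            if (prev == "C" and base == "G") or (base == "C" and nxt == "G"):
                continue  # would create an unplanned CpG
            break
        seq[i] = base
        prev = base
    return "".join(seq)


# ---------------------------------------------------------------------------
# feature planting
# ---------------------------------------------------------------------------


def plant_features(
    background_length: int,
    features: Sequence[tuple[str, int]],
    seed: int = 0,
    background: str | None = None,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Embed sequences in a random background.

    ``features`` is a list of ``(sequence, position)``; the planted
    subsequence is recoverable verbatim at ``[position, position + len)``.
    The background is i.i.d. uniform from ``seed`` unless an explicit
    ``background`` string (e.g. from :func:`biased_dna`) is supplied.
    Returns the genome string and BED-style truth rows
    ``(start, end, name)`` sorted by start.
    """
    if background is not None and len(background) != background_length:
        raise ValueError("background: length does not match background_length")
    spans = sorted(
        ((pos, pos + len(s), i) for i, (s, pos) in enumerate(features)),
        key=lambda t: t[0],
    )
    bad = [
        f"feature_{i} [{a},{b})"
        for (a, b, i) in spans
        if a < 0 or b > background_length
    ]
    if bad:
        raise ValueError(f"features outside background: {', '.join(bad)}")
    overlaps = [
        f"feature_{i} [{a},{b}) overlaps feature_{j} [{c},{d})"
        for (a, b, i), (c, d, j) in zip(spans, spans[1:])
        if b > c
    ]
    if overlaps:
        raise ValueError(f"overlapping features: {'; '.join(overlaps)}")

    genome = list(
        background
        if background is not None
        else random_dna(background_length, np.random.default_rng(seed))
    )
    rows = []
    for a, b, i in spans:
        genome[a:b] = list(features[i][0])
        rows.append((a, b, f"feature_{i}"))
    return "".join(genome), rows


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------


@dataclass
class BisulfiteSimSpec:
    """Per-group bisulfite clone simulation.

    ``methylation_prob`` maps group name to either a scalar or a per-CpG-site
    vector of methylation probabilities.  ``variant_prob`` is the chance that
    a clone carries a CpG-destroying substitution at a site (C replaced by A
    or G, so the site is unambiguously non-CpG after conversion).
    ``conversion_efficiency`` is the probability that an unmethylated C reads
    as T.
    """

    reference_region: str
    methylation_prob: Mapping[str, float | np.ndarray]
    clones_per_group: int
    variant_prob: float = 0.0
    conversion_efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.reference_region) > 0, "reference_region", "must be non-empty")
        _check(self.clones_per_group >= 1, "clones_per_group", "must be >= 1")
        _check(0.0 <= self.variant_prob <= 1.0, "variant_prob", "must lie in [0, 1]")
        _check(
            0.0 <= self.conversion_efficiency <= 1.0,
            "conversion_efficiency",
            "must lie in [0, 1]",
        )
        n = self.cpg_positions.size
        for group, p in self.methylation_prob.items():
            vec = np.broadcast_to(np.asarray(p, dtype=float), (n,))
            _check(
                bool(np.all((vec >= 0) & (vec <= 1))),
                "methylation_prob",
                f"group {group!r} probabilities must lie in [0, 1]",
            )

    @property
    def cpg_positions(self) -> np.ndarray:
        return cpg_sites(self.reference_region)


@dataclass
class SimClone:
    clone_id: str
    group: str
    sequence: str
    truth_states: list[str]  # one of M / U / - per reference CpG


def simulate_bisulfite_clones(spec: BisulfiteSimSpec) -> dict[str, list[SimClone]]:
    """Simulate bisulfite-converted clone sequences per group.

    At each reference CpG a clone either carries a CpG-destroying variant
    (state ``-``), retains C (methylated, ``M``) or converts C->T
    (unmethylated, ``U``).  Every other (non-CpG) cytosine converts to T
    with probability ``conversion_efficiency``.
    """
    ref = spec.reference_region
    sites = spec.cpg_positions
    if sites.size == 0:
        raise ValueError("reference_region: contains no CpG site")
    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    non_cpg_c = np.setdiff1d(np.flatnonzero(ref_arr == ord("C")), sites)

    groups = list(spec.methylation_prob)
    streams = np.random.SeedSequence(spec.seed).spawn(len(groups))
    out: dict[str, list[SimClone]] = {}
    for group, stream in zip(groups, streams):
        rng = np.random.default_rng(stream)
        probs = np.broadcast_to(
            np.asarray(spec.methylation_prob[group], dtype=float), (sites.size,)
        )
        clones = []
        for i in range(spec.clones_per_group):
            arr = ref_arr.copy()
            # non-CpG cytosines: bisulfite conversion
            conv = non_cpg_c[rng.random(non_cpg_c.size) < spec.conversion_efficiency]
            arr[conv] = ord("T")
            states = []
            for pos, p in zip(sites, probs):
                if rng.random() < spec.variant_prob:
                    arr[pos] = ord("AG"[rng.integers(0, 2)])
                    states.append(ABSENT)
                elif rng.random() < p:
                    states.append(METHYLATED)  # C retained
                else:
                    states.append(UNMETHYLATED)
                    if rng.random() < spec.conversion_efficiency:
                        arr[pos] = ord("T")
            clones.append(
                SimClone(f"{group}_clone_{i}", group, arr.tobytes().decode(), states)
            )
        out[group] = clones
    return out


# ---------------------------------------------------------------------------
# allele-specific reads
# ---------------------------------------------------------------------------


@dataclass
class AllelicSimSpec:
    """Reads drawn from two haplotypes differing at known SNPs."""

    reference: str
    snp_table: Sequence[tuple[int, str, str]]  # (position, allele_A, allele_B)
    allelic_ratio: float
    read_length: int
    n_reads: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(0.0 <= self.allelic_ratio <= 1.0, "allelic_ratio", "must lie in [0, 1]")
        _check(0.0 <= self.error_rate <= 1.0, "error_rate", "must lie in [0, 1]")
        _check(
            self.read_length <= len(self.reference),
            "read_length",
            "must not exceed reference length",
        )
        positions = [p for p, _, _ in self.snp_table]
        _check(
            len(set(positions)) == len(positions),
            "snp_table",
            "SNP positions must be unique",
        )
        for pos, a, b in self.snp_table:
            _check(0 <= pos < len(self.reference), "snp_table", f"position {pos} outside reference")
            _check(a != b, "snp_table", f"alleles at {pos} must differ")
            _check(
                self.reference[pos] in (a, b),
                "snp_table",
                f"reference base at {pos} matches neither allele",
            )

    def haplotypes(self) -> tuple[str, str]:
        hap_a = list(self.reference)
        hap_b = list(self.reference)
        for pos, a, b in self.snp_table:
            hap_a[pos] = a
            hap_b[pos] = b
        return "".join(hap_a), "".join(hap_b)


@dataclass
class SimRead:
    read_id: str
    sequence: str
    start: int
    truth_label: str  # "A" or "B"


def simulate_allelic_reads(spec: AllelicSimSpec) -> tuple[str, str, list[SimRead]]:
    """Uniform-start error-bearing substrings of the two haplotypes.

    Returns ``(haplotype_A, haplotype_B, reads)``; each read records its
    source haplotype and start position.
    """
    hap_a, hap_b = spec.haplotypes()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    max_start = len(spec.reference) - spec.read_length
    reads = []
    labels = np.where(rng.random(spec.n_reads) < spec.allelic_ratio, "A", "B")
    starts = rng.integers(0, max_start + 1, size=spec.n_reads)
    for i, (label, start) in enumerate(zip(labels, starts)):
        src = hap_a if label == "A" else hap_b
        read = src[start : start + spec.read_length]
        if spec.error_rate > 0:
            read, _ = substitute(read, spec.error_rate, rng)
        reads.append(SimRead(f"read_{i}", read, int(start), str(label)))
    return hap_a, hap_b, reads


# ---------------------------------------------------------------------------
# cross-species monomers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSimSpec:
    """Species set sharing an invariant core in an otherwise diverged region.

    ``per_species_divergence`` default 0.30 emulates deep eutherian
    divergence of unconstrained sequence; the ``conserved_interval`` is
    copied verbatim into every species.
    """

    ancestral_monomer: str
    n_species: int = 25
    per_species_divergence: float = 0.30
    conserved_interval: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.conserved_interval
        _check(
            0 <= a <= b <= len(self.ancestral_monomer),
            "conserved_interval",
            "must lie within the ancestral monomer",
        )
        _check(
            0.0 <= self.per_species_divergence <= 1.0,
            "per_species_divergence",
            "must lie in [0, 1]",
        )
        _check(self.n_species >= 2, "n_species", "need at least two species")


def simulate_species_monomers(spec: SpeciesSimSpec) -> list[tuple[str, str]]:
    """Each species is the ancestor mutated per base outside the conserved core."""
    a, b = spec.conserved_interval
    core = spec.ancestral_monomer[a:b]
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_species)
    out = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        mutated, _ = substitute(
            spec.ancestral_monomer, spec.per_species_divergence, rng
        )
        seq = mutated[:a] + core + mutated[b:]
        out.append((f"species_{i:02d}", seq))
    return out
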