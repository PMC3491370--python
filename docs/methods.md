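# Methods

This note records the models, algorithms, parameter choices and known
limitations of the package, module by module.

## Synthetic data model (`seqsim`)

The generators produce every input the pipeline consumes, with exact planted
truth, so recovery can be measured rather than assumed.

**Tandem array.** A monomer template of length L (default study condition:
3,800 bp) carries one copy of a VNTR unit (default 900 bp) at a fixed
offset (default 900).  Monomer *i* is the template with the unit expanded to
c_i adjacent copies (default copy vector [2,1,3,2,1,2,3] over 7 monomers,
giving a ~33-kb array whose units run 3.8–5.6 kb), then mutated
independently of the other monomers.  The `divergence` parameter d (default
0.05) is the *expected pairwise divergence between monomers*; each monomer is
substituted at rate d/2 per base, since two independently mutated copies
differ at ≈ 2·(d/2)·(1−d/2).  Substitutions always change the base
(uniform over the other three).  Indels are off by default so that length
arithmetic — and hence interval truth — is exact; when enabled they are
geometric (p = 0.5) capped at `max_indel_len`.

**Background.** `plant_features` embeds sequences verbatim in an i.i.d.
uniform background, so any false repeat call is attributable to the caller,
not to simulated repeat structure.  Uniform DNA is, however, *not*
CpG-depleted (obs/exp ≈ 1) and so behaves unlike genomic DNA for
composition-sensitive analyses; `biased_dna` therefore provides a
first-order model with a target GC fraction and a CpG suppression factor
(P(G | previous C) scaled by `cpg_factor`, default 0.2, matching the ~0.2
CpG obs/exp of mammalian DNA).  The analysis scripts use biased composition
for the demonstration locus; the recovery and calibration tests keep the
uniform model.

**Bisulfite clones.** Per clone and per reference CpG: with probability
`variant_prob` the C is replaced by A or G (a CpG-destroying variant,
unambiguously non-CpG after conversion — truth state *absent*); otherwise
the site is methylated with its site/group probability (C retained) or
unmethylated.  Unmethylated cytosines — at CpGs and elsewhere — read T with
probability `conversion_efficiency` (default 1.0); incomplete conversion
therefore produces spurious C calls, which is exactly what the caller's
conversion-QC statistic measures.

**Allelic reads.** Two haplotypes are built by applying SNP alleles to a
reference (default region scale 232 bp, five SNPs, mirroring a
clone-sequenced PCR fragment); reads are uniform-start substrings (default
100 bp) of haplotype A with probability `allelic_ratio`, with i.i.d.
substitution errors.

**Species sets.** Each of `n_species` (default 25) sequences is the
ancestral monomer fragment (default 143 bp, the scale of the conserved
region of a monomer) mutated at `per_species_divergence` per base outside a
protected core (default 34 bp at positions 59–93).  The default divergence
is 0.30: across a deep eutherian panel, unconstrained sequence is expected
to differ from the consensus at roughly this order, and the chance that a
flank column is identical in all 25 species is then 0.7²⁵ ≈ 1.3·10⁻⁴, so
the invariant-column window is dominated by the planted core.  At much
lower divergence (e.g. 0.15) chance-invariant flank columns become common
(0.85²⁵ ≈ 0.017 per column) and the window genuinely over-extends — a
property of the statistic, not a failure of the extractor.

**Determinism.** Every generator takes one seed; per-monomer/clone/read
sub-streams are spawned from it (`numpy.random.SeedSequence`), so identical
specs give byte-identical output.

What the simulations do *not* model: read quality profiles, PCR duplicates,
paired-end geometry, repeat-structured background, CpG-island methylation
gradients, indel SNPs.  Passing tests show the algorithms recover what was
planted under these idealized conditions; they do not certify performance
on real libraries.

## Self-alignment and repeat calling (`tandemscan`)

`self_matches` reports **all maximal exact matches** of length ≥
`min_segment` (default 25) between distinct positions of the sequence
(forward) and between the sequence and its reverse complement (reverse).  A
maximal exact run of length ℓ on a dotplot diagonal contains exactly
ℓ−k+1 consecutive exact k-mer seeds, so merging consecutive seed hits per
diagonal reconstructs every run exactly — the enumeration is exhaustive for
runs ≥ k, with no extension heuristic to tune.  Defaults k = 13,
`min_segment` = 25: monomers at ~5% pairwise divergence share abundant
clean 25-mers (the expected clean-run length at 5% mismatch density is ~20
bp, and ≥25-bp runs cover ~2/3 of homologous sequence), while a 200-kb
uniform background yields essentially no 13-mer collisions
(C(2·10⁵,2)/4¹³ ≈ 300 seed pairs, virtually none extending to 25 bp).

**Periodicity.** Within a segment cluster, diagonal offsets are grouped
into families at 10% relative tolerance.  Matches between units *k* periods
apart tile (most of) the array for every small *k*, so all unit-multiple
families have comparable dotplot footprint; an internal sub-repeat (the
VNTR) instead covers only its own sub-region.  The unit family is therefore
the smallest-offset family whose footprint is ≥ 60% of the best; families
whose offset rounds to one unit are pooled (VNTR expansion spreads
adjacent-unit offsets across 3.8–5.6 kb), multiples fold out, and the unit
period is the length-weighted median of the pooled offsets.
`copy_estimate` = cluster span / period.  `period_stats` reports
(min, weighted median, max) over the pooled unit family.

**Calls.** Clusters are built by footprint overlap with gaps ≤ `max_gap`
(default 2 kb, bridging VNTR-induced breaks); a call requires span ≥
`min_span` (default 10 kb) and ≥ `min_copies` (default 3) implied units.
Inverted repeats cluster reverse segments whose left interval precedes the
right; arms are the cluster's union footprints, calls with arm lengths
differing by >20% or spacer > `max_spacer` are dropped.  The windowed
survey scans fixed windows (default 500 kb stepped 250 kb), pools calls
across windows (de-duplicating >50% reciprocal overlaps), and reports per
window the largest call overlapping it by ≥50% of the call's span.  The
dotplot is a diagnostic TSV artifact only.

## Monomer structure (`monomerstruct`)

**Anchor segmentation.** Fixed-period cutting fails when the VNTR makes
monomer length non-constant, so the array is cut at an *anchor*: the k-mer
(default k = 16) maximizing the number of occurrences whose neighbouring
spacings lie within 40% of that k-mer's own median spacing — the signature
of once-per-unit recurrence.  Ties go to the earliest first occurrence
(this puts the cut register near the unit start, ahead of the internal
VNTR, so each segment carries its own VNTR block), then lexicographic.
The chosen anchor is re-located with a Hamming allowance of k/5 so units
carrying a point mutation inside the anchor are still cut; near-duplicate
hits within half the median spacing keep the closest match.  The register
of the resulting tiling is arbitrary — a tandem repeat is circularly
permutable — so the VNTR copy vector is compared to truth as a circular
word, and the segment before the first anchor is reported as flank, not
monomer.

**Divergence.** Pairwise global alignment with affine gap penalties
(match 0, mismatch −1, open −3, extend −0.5; Biopython `PairwiseAligner`);
divergence = substituted columns / aligned (match+mismatch) columns × 100,
gap columns excluded.  Two numerical points drove this design.  (i) Under
unit-cost edit distance a mismatch column and an insertion+deletion pair
cost the same, so optimal paths between monomers differing by VNTR copies
are massively degenerate and percent identity ill-determined (observed
spread 2.5–13.8% for truly ~5%-diverged pairs); affine scoring keeps the
VNTR length difference in one contiguous gap block and makes
substitution-only paths strictly optimal for equal-length inputs, where the
statistic then equals the Hamming distance exactly.  (ii) Excluding gap
columns keeps the statistic a description of point divergence, unaffected
by copy-number length differences.

**VNTR.** Within each monomer, forward self-matches at small offsets mark
the internal repeat (k = 11, `min_segment` 25 — copies are ~5% mutually
diverged, same seed statistics as above).  The dominant offset family gives
the per-monomer unit estimate; the across-monomer median is the unit
length, and monomers whose own estimate deviates >20% are treated as
single-copy.  Copy number = round(span of internal matches / unit), minimum
1 — the *span* (first to last matched base), not the coverage union, since
mutation gaps shrink the union by ~30% and would bias the count down by one.
The unit interval is reported on the monomer with the strongest internal
signal, where the unit is directly observable (a single-copy monomer has no
internal self-match to locate it by).

## CpG metrics and islands (`cpgmetrics`)

GC fraction and obs/exp exclude ambiguity codes from numerator and
denominator; a CpG spanning an ambiguous base is not counted.  Island
calling uses the classical thresholds (window 200 bp, GC ≥ 0.5, obs/exp ≥
0.6), evaluated for every 1-bp-stepped window with rolling counts;
overlapping qualifying windows merge, and an island is the union of its
qualifying windows with metrics recomputed on the merged interval.  This
union definition over-extends a compact island by up to a window width on
either side when flanking windows still qualify partially — visible in the
worked example, where a planted 333-bp island is reported as ~530 bp with
the correct 40 CpGs.  All thresholds are arguments; no hidden-state or
Takai–Jones style caller is provided.

## Bisulfite methylation (`bisulfite`)

Clones are mapped to the reference by global alignment with C/T treated as
equal (conversion is not a mismatch; edlib, with a direct positional path
for length-preserved clones); identity < 80% under that equivalence is an
error.  At each reference CpG: C → methylated, T → unmethylated, anything
else or a deletion → absent.  Conversion QC is the fraction of non-CpG
reference cytosines reading T; clones below 0.95 are flagged, not dropped.
The unit of analysis is per-clone percent methylation,
100·M/(M+U) with absent sites excluded; clones with no informative site are
dropped with a warning, and groups below nine clones draw a warning (the
conventional minimum for clone profiles) but are accepted.  Group
comparison is the two-tailed Welch t-test with Welch–Satterthwaite degrees
of freedom, implemented directly (scipy supplies only the t distribution);
the degenerate zero-variance cases return t = 0, p = 1 (equal means) or a
flagged p = 0 limit (unequal means).  No multiple-testing correction is
applied across regions; that matches how such clone profiles are
conventionally reported, and is the caller's responsibility otherwise.

## Allele-specific assignment (`allelic`)

SNP discovery: per position and strain, the consensus is the modal base
among alignable clones (< 80% identity clones are skipped with a warning);
a variant requires differing consensuses with both modal fractions ≥
`min_support` (default 0.9 — with ≥100 clones per strain, true fixed
differences have near-unanimous support while 0.5%-error noise does not).

Assignment implements a segment-identity rule: a read belongs to haplotype
A iff some *exact* substring match of ≥ `min_overlap` bp (default 30)
between read and haplotype A covers ≥1 discriminating site, and no such
qualifying match exists against B (symmetrically for B); everything else —
including reads matching both haplotypes or covering no site — is
uninformative.  Matches are found by the same exhaustive k-mer-run
machinery as the scanner with k = `min_overlap`/2 (any ≥30-bp exact run
contains an aligned exact 15-mer, so the search is complete).  Note the
rule is per matched segment, not per read: a sequencing error far from the
SNP leaves the read assignable, an error at the SNP makes it
uninformative, and only an error that converts one strain's allele into
the other's can misassign — bounding misassignment by ≈ error_rate/3 per
covered site.  Haplotypes must be equal length (substitution SNPs only);
mates of a pair are treated as independent reads.

## Conserved window and PWM (`motif`)

Inputs are pre-aligned equal-length homologs (alignment construction is
out of scope, keeping the window/PWM logic independently testable).  The
window is the minimal interval containing every invariant column; interior
columns need not be invariant, and no invariant column yields an empty,
flagged window.  The PWM counts bases per column (ambiguity codes excluded
with a warning), applies an optional pseudocount (default 0, the
sequence-logo convention, so identical inputs give exactly 2.0
bits/column), and reports IC_j = 2 + Σ_b f log₂ f with 0·log 0 = 0.
Consensus matching scans an IUPAC motif over the target at every offset
with ≥1 overlapping position on both strands (so motif orientation and
motif-longer-than-target cases need no special handling) and reports the
best count of positions whose target base belongs to the motif's class;
ties prefer the forward strand, then the smaller offset.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
the study-condition scales: 200-kb genomes with a ~33-kb planted array
(recovery over 3–5 replicates), 2-kb/5-kb sequences for brute-force oracle
comparisons (20 each), 1,000 null and 200 alternative Welch simulations
with 10 clones × 30 CpGs per group, 10,000 reads per error condition on a
232-bp five-SNP region, and 100 replicates of the 25-species window
recovery.

## Known limitations

* The scanner finds exact match runs only; at divergence well beyond ~10%
  per pair, seeds thin out and arrays fragment (by design — gapped
  extension is a non-goal).
* Anchor segmentation requires the anchor to survive in (nearly) every
  monomer; very small arrays (2–3 units) at high divergence may segment
  short.
* The copy-number estimator assumes adjacent-unit offsets dominate the
  dotplot; exotic higher-order repeat structure (e.g. interleaved
  sub-arrays) is not modeled.
* Island calls over-extend compact islands by up to one window width per
  side (union-of-windows definition).
* Read assignment handles substitution SNPs only, and reads are treated as
  error-free *segments*; indel-bearing strains need an aligner upstream.
* The Welch test is applied per region with no cross-region correction.
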