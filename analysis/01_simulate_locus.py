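#!/usr/bin/env python
"""Simulate the study locus: a macrosatellite array in unique background.

Builds a 200-kb synthetic chromosome segment containing, in order: a
7-monomer tandem array (3.8-kb template, 900-bp internal VNTR at copies
[2,1,3,2,1,2,3], ~5% inter-monomer divergence), a 333-bp CpG island with
40 CpGs planted 5 kb downstream of the array (emulating a downstream
CGI), and a 2-kb-arm inverted repeat further downstream (emulating the
downstream satellite's mid-locus inversion).

Unlike the uniform-composition sequences used by the recovery and
negative-control tests, this locus uses genome-like composition — AT-rich
CpG-depleted background (42% GC, CpG obs/exp ~0.2) and a ~53%-GC,
CpG-depleted monomer template — so that composition-sensitive stages
(CpG-island calling) behave as they would on real DNA.  Writes the genome
FASTA and the ground-truth BED used by the later scripts.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from macrosat import seqsim
from macrosat.io import write_bed, write_fasta

OUT = Path("results/synthetic")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    # monomer template at paper-like composition (GC-rich but CpG-depleted)
    trng = np.random.default_rng(args.seed + 10)
    unit = seqsim.biased_dna(900, trng, gc=0.534, cpg_factor=0.15)
    template = (
        seqsim.biased_dna(900, trng, gc=0.534, cpg_factor=0.15)
        + unit
        + seqsim.biased_dna(2000, trng, gc=0.534, cpg_factor=0.15)
    )
    spec = seqsim.ArraySpec(
        monomer_template=template,
        copy_count=7,
        vntr_unit=unit,
        vntr_insert_position=900,
        vntr_copies=[2, 1, 3, 2, 1, 2, 3],
        divergence=0.05,
        seed=args.seed,
    )
    array, truth = seqsim.generate_array(spec)

    rng = np.random.default_rng(args.seed + 1)
    cgi = seqsim.design_cgi_fragment(333, 40, 0.62, rng)
    ir, ir_arms = seqsim.generate_inverted_repeat(2000, 500, seed=args.seed + 2)

    array_at = 60_000
    cgi_at = array_at + len(array) + 5_000
    ir_at = cgi_at + 10_000
    background = seqsim.biased_dna(
        200_000, np.random.default_rng(args.seed + 3), gc=0.42, cpg_factor=0.2
    )
    genome, rows = seqsim.plant_features(
        200_000,
        [(array, array_at), (cgi, cgi_at), (ir, ir_at)],
        background=background,
    )

    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta(OUT / "genome.fasta", [("synthetic_locus", genome)])
    truth = truth.shifted(array_at)
    bed = (
        [(truth.array_interval[0], truth.array_interval[1], "array")]
        + [(a, b, f"monomer_{i}") for i, (a, b) in enumerate(truth.monomer_intervals)]
        + [(cgi_at, cgi_at + len(cgi), "downstream_cgi")]
        + [(ir_at + a, ir_at + b, f"inverted_arm_{i}") for i, (a, b) in enumerate(ir_arms)]
    )
    write_bed(OUT / "truth.bed", bed, chrom="synthetic_locus")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "array_interval": truth.array_interval,
                "monomer_intervals": truth.monomer_intervals,
                "vntr_copy_counts": truth.vntr_copy_counts,
                "cgi_interval": [cgi_at, cgi_at + len(cgi)],
                "inverted_arms": [[ir_at + a, ir_at + b] for a, b in ir_arms],
                "seed": args.seed,
            },
            indent=2,
        )
    )

    print(f"locus: 200 kb with array [{truth.array_interval[0]},{truth.array_interval[1]})"
          f" ({len(array)} bp, 7 monomers, VNTR copies {truth.vntr_copy_counts})")
    print(f"       CGI at [{cgi_at},{cgi_at + len(cgi)}), inverted repeat arms at "
          f"{[(ir_at + a, ir_at + b) for a, b in ir_arms]}")
    print(f"wrote {OUT}/genome.fasta, truth.bed, truth.json")


if __name__ == "__main__":
    main()
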