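#!/usr/bin/env python
"""Cross-species conserved window, PWM, and consensus-motif matching.

Simulates homologous monomer fragments from 25 species that share a
34-bp invariant core (planted at positions 59-93 of a 143-bp region)
inside otherwise deeply diverged sequence, extracts the minimal window
containing all invariant columns, builds the position weight matrix with
per-column information content, and scores the window consensus against
an IUPAC motif (a degenerate rendering of the planted core, standing in
for a transcription-factor consensus such as CTCF's).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from macrosat import motif, seqsim
from macrosat._seq import random_dna
from macrosat.io import write_fasta, write_tsv

OUT = Path("results")

CORE = (59, 93)  # 34-bp invariant interval inside the 143-bp fragment


def degenerate(core: str, rng: np.random.Generator, every: int = 4) -> str:
    """IUPAC motif derived from a core: every ``every``-th base widened to a
    two-letter class — an example consensus for the matcher."""
    two_letter = {"A": "R", "G": "R", "C": "Y", "T": "Y"}
    out = list(core)
    for i in range(0, len(out), every):
        out[i] = two_letter[out[i]]
    return "".join(out)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    ancestor = random_dna(143, rng)
    spec = seqsim.SpeciesSimSpec(ancestor, conserved_interval=CORE, seed=args.seed + 1)
    species = seqsim.simulate_species_monomers(spec)
    write_fasta(OUT / "species_monomers.fasta", species)

    seqs = [s for _, s in species]
    window = motif.conserved_window(seqs)
    print(f"conserved window [{window.start},{window.end}) width {window.width} "
          f"({window.invariant_columns.size} invariant columns; planted core "
          f"[{CORE[0]},{CORE[1]}), 34 bp)")

    restricted = [s[window.start : window.end] for s in seqs]
    pwm = motif.build_pwm(restricted)
    table = pd.DataFrame(pwm.frequencies, index=list("ACGT"))
    table.loc["IC_bits"] = np.round(pwm.information_content, 4)
    write_tsv(OUT / "conserved_pwm.tsv", table, index=True)
    core_cols = slice(CORE[0] - window.start, CORE[1] - window.start)
    print(f"information content: core mean "
          f"{pwm.information_content[core_cols].mean():.2f} bits/column, "
          f"window mean {pwm.information_content.mean():.2f} bits/column")

    consensus = pwm.consensus
    example_motif = degenerate(ancestor[CORE[0] : CORE[1]][:14], rng)
    hit = motif.consensus_match(consensus, example_motif)
    print(f"window consensus {consensus}")
    print(f"example IUPAC motif {example_motif}: "
          f"{hit.matched_positions}/{hit.consensus_length} positions matched "
          f"on strand {hit.strand} at offset {hit.offset}")
    write_tsv(
        OUT / "consensus_matches.tsv",
        pd.DataFrame([{"motif": example_motif, **hit.__dict__}]),
    )


if __name__ == "__main__":
    main()
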