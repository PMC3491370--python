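#!/usr/bin/env python
"""Bisulfite clone methylation: sexes compared with the Welch t-test.

Simulates bisulfite clone sets for a 30-CpG promoter-scale region under a
male-like model (all clones heavily methylated) and a female-like model
(a mixture of heavily and lightly methylated clones, as expected when the
inactive X contributes hypomethylated alleles), calls per-CpG states for
every clone, writes the lollipop-style state matrix, and compares percent
methylation between the groups with the unequal-variance t-test.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from macrosat import bisulfite, seqsim
from macrosat._seq import random_dna
from macrosat.io import write_tsv

OUT = Path("results")


def make_reference(n_sites: int, rng: np.random.Generator) -> str:
    parts = []
    for _ in range(n_sites):
        parts.append(random_dna(6, rng).replace("CG", "CA") + "CG")
    parts.append(random_dna(6, rng).replace("CG", "CA"))
    return "".join(parts)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--clones", type=int, default=10)
    args = parser.parse_args()

    ref = make_reference(30, np.random.default_rng(args.seed))

    male = seqsim.simulate_bisulfite_clones(
        seqsim.BisulfiteSimSpec(
            ref, {"male": 0.85}, clones_per_group=args.clones,
            variant_prob=0.05, seed=args.seed + 1,
        )
    )["male"]
    half = args.clones // 2
    female = (
        seqsim.simulate_bisulfite_clones(
            seqsim.BisulfiteSimSpec(ref, {"female": 0.85}, clones_per_group=half,
                                    variant_prob=0.05, seed=args.seed + 2)
        )["female"]
        + seqsim.simulate_bisulfite_clones(
            seqsim.BisulfiteSimSpec(ref, {"female": 0.15},
                                    clones_per_group=args.clones - half,
                                    variant_prob=0.05, seed=args.seed + 3)
        )["female"]
    )

    profiles = {}
    rows = []
    for group, clones in (("male", male), ("female", female)):
        profiles[group] = [
            bisulfite.call_clone_methylation(ref, c.sequence, c.clone_id)
            for c in clones
        ]
        for p in profiles[group]:
            rows.append(
                {"clone": p.clone_id, "group": group,
                 "percent": round(bisulfite.percent_methylation(p), 1),
                 **{f"cpg_{i:02d}": s for i, s in enumerate(p.site_states)}}
            )
    write_tsv(OUT / "methylation_states.tsv", pd.DataFrame(rows))

    cmp = bisulfite.compare_groups(profiles["male"], profiles["female"])
    write_tsv(OUT / "methylation_comparison.tsv", pd.DataFrame([cmp.__dict__]))
    print(f"male:   {cmp.mean1:5.1f}% +/- {cmp.sd1:.1f} (n={cmp.n1})")
    print(f"female: {cmp.mean2:5.1f}% +/- {cmp.sd2:.1f} (n={cmp.n2})")
    print(f"Welch two-tailed t-test: t={cmp.t:.3f}, dof={cmp.dof:.1f}, P={cmp.p:.4g}")
    print("state matrix (rows = clones, columns = CpGs, M/U/-) in "
          f"{OUT}/methylation_states.tsv")


if __name__ == "__main__":
    main()
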