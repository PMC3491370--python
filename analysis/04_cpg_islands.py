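#!/usr/bin/env python
"""CpG metrics of the monomers and CpG-island calls on the locus.

Computes GC fraction, CpG count and CpG observed/expected for every
monomer of the called array (the smallest monomer is the natural
reference unit), then scans the whole locus for CpG islands and checks
the planted downstream island is recovered.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from macrosat import cpgmetrics, monomerstruct, tandemscan
from macrosat.io import read_fasta, write_bed, write_tsv

OUT = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    args = parser.parse_args()

    genome = read_fasta(OUT / "synthetic/genome.fasta")["synthetic_locus"]
    truth = json.loads((OUT / "synthetic/truth.json").read_text())

    call = tandemscan.call_tandem_arrays(tandemscan.self_matches(genome))[0]
    sub = genome[call.interval[0] : call.interval[1]]
    _, positions = monomerstruct.find_anchor(sub)
    monomers = monomerstruct.segment_monomers(sub, positions).sequences(sub)

    rows = [
        {
            "monomer": i,
            "length_bp": len(m),
            "gc_pct": round(100 * cpgmetrics.gc_fraction(m), 1),
            "cpg_count": cpgmetrics.cpg_count(m),
            "cpg_obs_exp": round(cpgmetrics.cpg_obs_exp(m), 3),
        }
        for i, m in enumerate(monomers)
    ]
    write_tsv(OUT / "monomer_cpg_metrics.tsv", pd.DataFrame(rows))
    smallest = min(rows, key=lambda r: r["length_bp"])
    print(f"smallest monomer: {smallest['length_bp']} bp, {smallest['gc_pct']}% GC, "
          f"{smallest['cpg_count']} CpGs, obs/exp {smallest['cpg_obs_exp']}")

    islands = cpgmetrics.find_cgis(genome)
    write_bed(
        OUT / "cgi_calls.bed",
        [
            (c.interval[0], c.interval[1],
             f"CGI_{i}_len={c.length}_cpg={c.cpg_count}_gc={c.gc_fraction:.2f}")
            for i, c in enumerate(islands)
        ],
        chrom="synthetic_locus",
    )
    ca, cb = truth["cgi_interval"]
    recovered = [
        c for c in islands if c.interval[0] < cb and c.interval[1] > ca
    ]
    print(f"{len(islands)} CpG island(s) called on the locus")
    for c in recovered:
        print(f"planted downstream CGI recovered as [{c.interval[0]},{c.interval[1]}): "
              f"{c.length} bp, {c.cpg_count} CpGs, GC {100 * c.gc_fraction:.1f}%, "
              f"obs/exp {c.obs_exp:.2f} (planted: [{ca},{cb}), 333 bp, 40 CpGs)")


if __name__ == "__main__":
    main()
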