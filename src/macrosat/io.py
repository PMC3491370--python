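"""File I/O: FASTA via Bio.SeqIO, BED (0-based half-open) and TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """id -> upper-case sequence for every record in a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_bed(path, rows: Iterable[tuple], chrom: str = "synthetic") -> None:
    """Rows are (start, end, name[, score]) tuples on one chromosome."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in rows:
            start, end, name = row[0], row[1], row[2]
            rest = "\t".join(str(x) for x in row[3:])
            fh.write(f"{chrom}\t{start}\t{end}\t{name}" + (f"\t{rest}" if rest else "") + "\n")


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
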