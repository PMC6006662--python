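"""File input/output: FASTA sequences and the toolkit's tabular formats."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .repeat_scan import SequenceRecord, SSRLocus, loci_from_frame, loci_to_frame


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzip-compressed) multi-record FASTA; sequences are
    uppercased and must be over A/C/G/T/N."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_loci_tsv(loci: list[SSRLocus], path: str | Path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path: str | Path) -> list[SSRLocus]:
    return loci_from_frame(pd.read_csv(path, sep="\t"))
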