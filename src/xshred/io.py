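"""Thin FASTA/FASTQ/TSV helpers shared by the pipeline stages.

Sequence records are passed around as plain tuples — ``(id, seq)`` for FASTA
and ``(id, seq, qualities)`` for FASTQ, with qualities as a list of Phred
scores — so that every stage can consume either in-memory simulator output or
files parsed with Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FastaRecord = tuple[str, str]
FastqRecord = tuple[str, str, list[int]]


def read_fasta(path: str | os.PathLike) -> Iterator[FastaRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fasta(records: Iterable[FastaRecord], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> None:
    def _gen():
        for name, seq, quals in records:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            yield rec

    SeqIO.write(_gen(), str(path), "fastq")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def sequences(reads: Iterable) -> Iterator[str]:
    """Yield bare sequences from FASTA or FASTQ style record tuples."""
    for rec in reads:
        if isinstance(rec, str):
            yield rec
        else:
            yield rec[1]
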