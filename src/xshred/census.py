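"""k-mer census of sexed short-read sets.

Counts every k-length window of every read (canonically strand-merged by
default), removes mitochondrial signal by exact k-mer match against a
mitochondrial reference, and applies the minimum combined-abundance filter
(default: a k-mer must occur at least 4 times in male + female data
combined). Counts are also stored normalised per million read bases per sex,
the normalisation used by the chromosome quotient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._codec import (
    canonical_window_codes,
    decode_kmer,
    encode,
    window_codes,
)
from .io import sequences

DEFAULT_K = 25


@dataclass(frozen=True)
class CensusThresholds:
    min_combined_count: int = 4
    k: int = DEFAULT_K

    def __post_init__(self):
        if self.min_combined_count < 1:
            raise ValueError("min_combined_count must be >= 1")
        if self.k < 11:
            raise ValueError("k must be >= 11")


def _codes_of_reads(reads: Iterable, k: int, canonical: bool):
    """All (valid) window codes across reads, plus total read bases."""
    chunks = []
    total_bases = 0
    sep = np.array([-1], dtype=np.int8)
    buf = []
    for seq in sequences(reads):
        total_bases += len(seq)
        buf.append(encode(seq))
        buf.append(sep)
    if not buf:
        return np.empty(0, dtype=np.int64), 0
    concat = np.concatenate(buf)
    if canonical:
        codes, valid = canonical_window_codes(concat, k)
    else:
        codes, valid = window_codes(concat, k)
    chunks.append(codes[valid])
    return np.concatenate(chunks), total_bases


def count_kmers(reads: Iterable, k: int = DEFAULT_K, canonical: bool = True):
    """Count k-mers in one read set.

    Returns ``(series, total_bases)`` where the series maps k-mer sequence to
    its occurrence count. Windows containing non-ACGT characters are skipped;
    reads shorter than k contribute nothing. In canonical mode a k-mer and
    its reverse complement share one record, keyed by the lexicographically
    smaller of the two.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    codes, total_bases = _codes_of_reads(reads, k, canonical)
    if codes.size == 0:
        return pd.Series(dtype=np.int64, name="count"), total_bases
    uniq, counts = np.unique(codes, return_counts=True)
    index = [decode_kmer(int(c), k) for c in uniq]
    return pd.Series(counts, index=index, name="count"), total_bases


def mito_kmer_set(mito_seq: str, k: int = DEFAULT_K, canonical: bool = True) -> set[str]:
    """All k-mers of the mitochondrial reference (both strands collapse in canonical mode)."""
    if not mito_seq:
        raise ValueError("mitochondrial reference is empty")
    codes, valid = (
        canonical_window_codes(encode(mito_seq), k)
        if canonical
        else window_codes(encode(mito_seq), k)
    )
    out = {decode_kmer(int(c), k) for c in codes[valid]}
    if not canonical:
        from ._codec import revcomp

        rc_codes, rc_valid = window_codes(encode(revcomp(mito_seq)), k)
        out |= {decode_kmer(int(c), k) for c in rc_codes[rc_valid]}
    return out


class KmerCensus:
    """Joint male/female k-mer table with library-size normalisation.

    ``df`` is indexed by k-mer sequence with columns ``male_count``,
    ``female_count``, ``combined_count``, ``male_norm`` and ``female_norm``
    (counts per million read bases of the respective sex).
    """

    def __init__(self, df: pd.DataFrame, k: int, male_bases: int, female_bases: int,
                 canonical: bool = True):
        self.df = df
        self.k = k
        self.male_bases = male_bases
        self.female_bases = female_bases
        self.canonical = canonical

    @classmethod
    def from_read_sets(
        cls,
        male_reads: Iterable,
        female_reads: Iterable,
        k: int = DEFAULT_K,
        canonical: bool = True,
    ) -> "KmerCensus":
        male, male_bases = count_kmers(male_reads, k, canonical)
        female, female_bases = count_kmers(female_reads, k, canonical)
        df = pd.concat(
            [male.rename("male_count"), female.rename("female_count")], axis=1
        ).fillna(0)
        df = df.astype({"male_count": np.int64, "female_count": np.int64})
        df["combined_count"] = df["male_count"] + df["female_count"]
        df["male_norm"] = df["male_count"] / max(male_bases, 1) * 1e6
        df["female_norm"] = df["female_count"] / max(female_bases, 1) * 1e6
        df = df.sort_index()
        return cls(df, k, male_bases, female_bases, canonical)

    def filter_mitochondrial(self, mito_seq: str) -> tuple["KmerCensus", int]:
        """Drop k-mers exactly matching the mitochondrial reference on either strand."""
        mito = mito_kmer_set(mito_seq, self.k, self.canonical)
        keep = ~self.df.index.isin(mito)
        removed = int((~keep).sum())
        return (
            KmerCensus(
                self.df.loc[keep], self.k, self.male_bases, self.female_bases,
                self.canonical,
            ),
            removed,
        )

    def apply_min_count(self, thresholds: CensusThresholds | None = None) -> "KmerCensus":
        """Retain k-mers with combined count >= the minimum (default 4)."""
        thr = thresholds or CensusThresholds(k=self.k)
        keep = self.df["combined_count"] >= thr.min_combined_count
        return KmerCensus(
            self.df.loc[keep], self.k, self.male_bases, self.female_bases,
            self.canonical,
        )

    def __len__(self) -> int:
        return len(self.df)

    def code_index(self):
        """Sorted k-mer codes with aligned count arrays, for fast read scans.

        Returns ``(codes, male, female)`` where ``codes`` is sorted ascending
        and the count arrays are aligned with it. Cached on first use.
        """
        cached = getattr(self, "_code_index", None)
        if cached is not None:
            return cached
        from ._codec import kmer_to_code

        codes = np.fromiter(
            (kmer_to_code(k) for k in self.df.index), dtype=np.int64, count=len(self.df)
        )
        order = np.argsort(codes)
        out = (
            codes[order],
            self.df["male_count"].to_numpy()[order],
            self.df["female_count"].to_numpy()[order],
            self.df.index.to_numpy()[order],
        )
        self._code_index = out
        return out

    def to_tsv(self, path) -> None:
        self.df.rename_axis("kmer").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, k: int, male_bases: int, female_bases: int,
                 canonical: bool = True) -> "KmerCensus":
        df = pd.read_csv(path, sep="\t", index_col="kmer")
        return cls(df, k, male_bases, female_bases, canonical)
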