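"""Chromosome-quotient computation, long-read binning and X-kmer calling.

The chromosome quotient (CQ) of a sequence is the ratio of its normalised
female to male short-read evidence. With a hemizygous-male X it converges to
~2 for X-linked sequence, ~1 for autosomal and ~0 for Y-linked sequence.
Long reads (length-filtered to the configured window, 2-100 kb by default)
are binned X / autosomal / Y / ambiguous by the CQ of their summed
constituent k-mer counts; reads matching the mitochondrial reference are
binned mitochondrial regardless of CQ. A census k-mer is called a candidate
X-kmer when nearly all of its long-read hits fall on X-binned reads and its
own CQ lies in the X window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._codec import canonical_window_codes, encode, window_codes
from .census import KmerCensus, mito_kmer_set


@dataclass(frozen=True)
class LinkageThresholds:
    """Binning and candidate-calling cutoffs.

    The long-read length window follows the published 2 kb - 100 kb rule
    (both bounds inclusive). The CQ windows and the X-hit fraction are
    declared defaults, configurable because no printed values exist for them.
    """

    min_length: int = 2_000
    max_length: int = 100_000
    x_window: tuple[float, float] = (1.5, 2.5)
    autosome_window: tuple[float, float] = (0.7, 1.4)
    y_ceiling: float = 0.1
    x_hit_fraction: float = 0.99
    cq_cap: float = 10.0
    mito_kmer_fraction: float = 0.5

    def __post_init__(self):
        if self.min_length >= self.max_length:
            raise ValueError("length window requires min < max")
        if self.x_window[0] <= self.autosome_window[1]:
            raise ValueError("X and autosome CQ windows must be disjoint")
        if self.y_ceiling >= self.autosome_window[0]:
            raise ValueError("Y ceiling must sit below the autosome window")


@dataclass(frozen=True)
class CQValue:
    cq: float
    female_evidence: float
    male_evidence: float
    capped: bool = False
    undefined: bool = False


def compute_cq(
    female_evidence: float,
    male_evidence: float,
    female_norm: float = 1.0,
    male_norm: float = 1.0,
    cap: float = 10.0,
) -> CQValue:
    """CQ = (female evidence / female library size) / (male evidence / male library size).

    Zero male evidence with nonzero female evidence is capped (flagged) so
    downstream sorting stays total; zero evidence on both sides is an
    undefined sentinel (NaN), never a silent 0.
    """
    if female_evidence < 0 or male_evidence < 0:
        raise ValueError("evidence must be >= 0")
    if female_evidence == 0 and male_evidence == 0:
        return CQValue(math.nan, 0.0, 0.0, undefined=True)
    if male_evidence == 0:
        return CQValue(cap, female_evidence, 0.0, capped=True)
    cq = (female_evidence / female_norm) / (male_evidence / male_norm)
    return CQValue(cq, female_evidence, male_evidence)


def filter_long_reads(reads: Iterable, thresholds: LinkageThresholds | None = None):
    """Retain reads whose length lies inside the window (inclusive bounds).

    Returns ``(retained, rejection_log)``; the log is a DataFrame of the
    dropped reads with their lengths.
    """
    thr = thresholds or LinkageThresholds()
    retained, rejected = [], []
    for rec in reads:
        rid, seq = rec[0], rec[1]
        if thr.min_length <= len(seq) <= thr.max_length:
            retained.append((rid, seq))
        else:
            rejected.append({"read_id": rid, "length": len(seq)})
    return retained, pd.DataFrame(rejected, columns=["read_id", "length"])


def _read_codes(seq: str, k: int, canonical: bool) -> np.ndarray:
    """Valid (canonical) window codes of one read."""
    base = encode(seq)
    if canonical:
        codes, valid = canonical_window_codes(base, k)
    else:
        codes, valid = window_codes(base, k)
    return codes[valid]


def _mito_codes(mito_seq: str, k: int, canonical: bool) -> np.ndarray:
    from ._codec import kmer_to_code

    kmers = mito_kmer_set(mito_seq, k, canonical)
    return np.sort(
        np.fromiter((kmer_to_code(m) for m in kmers), dtype=np.int64, count=len(kmers))
    )


def _membership(sorted_codes: np.ndarray, codes: np.ndarray):
    """Boolean mask of which ``codes`` occur in ``sorted_codes`` + their positions."""
    if codes.size == 0 or sorted_codes.size == 0:
        return np.zeros(codes.size, dtype=bool), np.zeros(codes.size, dtype=np.intp)
    pos = np.searchsorted(sorted_codes, codes)
    pos_c = np.minimum(pos, sorted_codes.size - 1)
    return sorted_codes[pos_c] == codes, pos_c


def _assign_bin(cq: CQValue, thr: LinkageThresholds) -> str:
    if cq.undefined:
        return "ambiguous"
    if cq.capped:
        return "ambiguous"
    if cq.male_evidence > 0 and cq.cq <= thr.y_ceiling:
        return "Y"
    if thr.x_window[0] <= cq.cq <= thr.x_window[1]:
        return "X"
    if thr.autosome_window[0] <= cq.cq <= thr.autosome_window[1]:
        return "autosomal"
    return "ambiguous"


def bin_long_reads(
    reads: Iterable,
    census: KmerCensus,
    thresholds: LinkageThresholds | None = None,
    mito_seq: str | None = None,
) -> pd.DataFrame:
    """Assign each retained long read to {X, autosomal, Y, ambiguous, mitochondrial}.

    The read's CQ is computed from the summed normalised sex counts of its
    constituent census k-mers (abundant repeats weigh as the evidence they
    are). Reads with no countable k-mers are ambiguous.
    """
    thr = thresholds or LinkageThresholds()
    cens_codes, male_counts, female_counts, _ = census.code_index()
    mito = _mito_codes(mito_seq, census.k, census.canonical) if mito_seq else None
    rows = []
    for rec in reads:
        rid, seq = rec[0], rec[1]
        codes = _read_codes(seq, census.k, census.canonical)
        n_windows = codes.size
        hit, pos = _membership(cens_codes, codes)
        n_hit = int(hit.sum())
        m_sum = int(male_counts[pos[hit]].sum())
        f_sum = int(female_counts[pos[hit]].sum())
        n_mito = 0
        if mito is not None and n_windows:
            mhit, _ = _membership(mito, codes)
            n_mito = int(mhit.sum())
        if mito is not None and n_windows and n_mito / n_windows >= thr.mito_kmer_fraction:
            rows.append(
                {
                    "read_id": rid,
                    "length": len(seq),
                    "cq": math.nan,
                    "bin": "mitochondrial",
                    "kmers_hit": n_hit,
                }
            )
            continue
        if n_hit == 0:
            cq, bin_ = math.nan, "ambiguous"
        else:
            cqv = compute_cq(
                f_sum, m_sum, census.female_bases, census.male_bases, thr.cq_cap
            )
            cq, bin_ = cqv.cq, _assign_bin(cqv, thr)
        rows.append(
            {"read_id": rid, "length": len(seq), "cq": cq, "bin": bin_, "kmers_hit": n_hit}
        )
    return pd.DataFrame(
        rows, columns=["read_id", "length", "cq", "bin", "kmers_hit"]
    )


def kmer_cq_table(census: KmerCensus, cap: float = 10.0) -> pd.Series:
    """Per-kmer CQ from normalised census counts (capped where male count is 0)."""
    f = census.df["female_norm"].to_numpy()
    m = census.df["male_norm"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cq = f / m
    cq = np.where((m == 0) & (f > 0), cap, cq)
    cq = np.where((m == 0) & (f == 0), np.nan, cq)
    return pd.Series(cq, index=census.df.index, name="cq")


def call_x_kmers(
    census: KmerCensus,
    reads: Iterable,
    bins: pd.DataFrame,
    thresholds: LinkageThresholds | None = None,
) -> pd.DataFrame:
    """Flag candidate X-kmers.

    A k-mer is a candidate iff the fraction of its long-read window hits that
    fall on X-binned reads is >= ``x_hit_fraction`` and its own CQ lies in
    the X window. Returns the census table extended with hit tallies, CQ and
    the candidate flag.
    """
    thr = thresholds or LinkageThresholds()
    bin_of = dict(zip(bins["read_id"], bins["bin"]))
    cens_codes, _, _, names = census.code_index()
    x_hits = np.zeros(cens_codes.size, dtype=np.int64)
    total_hits = np.zeros(cens_codes.size, dtype=np.int64)
    for rec in reads:
        rid, seq = rec[0], rec[1]
        b = bin_of.get(rid)
        if b is None:
            continue
        codes = _read_codes(seq, census.k, census.canonical)
        hit, pos = _membership(cens_codes, codes)
        np.add.at(total_hits, pos[hit], 1)
        if b == "X":
            np.add.at(x_hits, pos[hit], 1)
    out = census.df.copy()
    out["x_hits"] = pd.Series(x_hits, index=names).reindex(out.index).astype(int)
    out["total_hits"] = pd.Series(total_hits, index=names).reindex(out.index).astype(int)
    out["cq"] = kmer_cq_table(census, thr.cq_cap)
    frac_ok = (out["total_hits"] > 0) & (
        out["x_hits"] / out["total_hits"].where(out["total_hits"] > 0) >= thr.x_hit_fraction
    )
    cq_ok = (out["cq"] >= thr.x_window[0]) & (out["cq"] <= thr.x_window[1])
    out["candidate"] = frac_ok & cq_ok
    return out
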