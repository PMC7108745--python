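"""Vectorised 2-bit nucleotide codec.

k-mers up to k=31 are packed into int64 codes (2 bits per base, A=0 C=1 G=2
T=3, first base in the highest bits). All window operations run as O(k)
whole-array numpy passes so that counting tens of millions of read windows
stays fast in pure Python.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case

_DECODE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved, N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes; non-ACGT positions become -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[c] for c in codes)


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_DECODE[(code >> shift) & 3])
    return "".join(out)


def window_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of every k-window of ``base_codes`` plus a validity mask.

    Windows containing any non-ACGT position (code -1) are flagged invalid;
    their code value is meaningless and must be ignored.
    """
    n = base_codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (base_codes < 0).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    b = np.where(base_codes < 0, 0, base_codes).astype(np.int64)
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | b[j : j + m]
    return codes, valid


def rc_window_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complement of every k-window (same indexing)."""
    n = base_codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    c = np.where(base_codes < 0, 3, 3 - base_codes).astype(np.int64)
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k - 1, -1, -1):
        codes = (codes << 2) | c[j : j + m]
    return codes


def canonical_window_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-merged window codes: min(code, revcomp code) per window."""
    fwd, valid = window_codes(base_codes, k)
    if fwd.size == 0:
        return fwd, valid
    rc = rc_window_codes(base_codes, k)
    return np.minimum(fwd, rc), valid


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_to_code(kmer: str) -> int:
    """Pack a (pure-ACGT) k-mer into its int64 code."""
    b = _LUT[np.frombuffer(kmer.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(b < 0):
        raise ValueError("k-mer contains non-ACGT characters")
    code = 0
    for v in b:
        code = (code << 2) | int(v)
    return code


def hamming_scan(text_codes: np.ndarray, query_codes: np.ndarray) -> np.ndarray:
    """Number of mismatches between ``query`` and every same-length window.

    Non-ACGT text positions always count as mismatches.
    """
    k = query_codes.size
    m = text_codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(m, dtype=np.int32)
    for j in range(k):
        mism += text_codes[j : j + m] != query_codes[j]
    return mism


def count_exact_occurrences(kmer: str, text: str, both_strands: bool = True) -> int:
    """Overlapping exact occurrences of ``kmer`` in ``text`` (optionally both strands)."""
    q = encode(kmer)
    if np.any(q < 0):
        return 0
    t = encode(text)
    n = int(np.count_nonzero(hamming_scan(t, q) == 0))
    if both_strands:
        qrc = encode(revcomp(kmer))
        # avoid double counting palindromes
        if not np.array_equal(q, qrc):
            n += int(np.count_nonzero(hamming_scan(t, qrc) == 0))
    return n
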