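"""gRNA target vetting of candidate X-kmers.

Each candidate k-mer is scanned on both strands for [20-nt spacer][NGG PAM]
placements; placements are screened for off-targets against the autosomal-
and Y-binned long reads (Hamming distance on the protospacer with the PAM
required to stay NGG), annotated with repeat-abundance metrics, and passed
through the shortlist cutoffs: combined-Illumina coverage > 10^2, PacBio
coverage > 10^1 (both as raw occurrence counts, log10-scaled), maximum k-mer
hits per long read strictly > 7.5, at least 5 perfect hits to an optional
assembly, and no off-target hits. Candidates are finally re-assembled into
higher-order repeat contigs by greedy exact-overlap merging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._codec import encode, hamming_scan, revcomp
from .census import KmerCensus

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN


class IncompleteRecordError(ValueError):
    """A selection criterion was evaluated before its metric was populated."""


@dataclass(frozen=True)
class SelectionThresholds:
    illumina_log10_coverage: float = 2.0
    pacbio_log10_coverage: float = 1.0
    max_hits_per_read: float = 7.5  # strict >
    min_perfect_hits: int = 5
    max_offtargets: int = 0
    offtarget_mismatches: int = 4

    def __post_init__(self):
        for v in (
            self.illumina_log10_coverage,
            self.pacbio_log10_coverage,
            self.max_hits_per_read,
            self.min_perfect_hits,
            self.max_offtargets,
            self.offtarget_mismatches,
        ):
            if v < 0:
                raise ValueError("all cutoffs must be >= 0")


@dataclass
class CandidateTarget:
    """One spacer+PAM placement extracted from a candidate k-mer."""

    kmer: str
    spacer: str
    pam: str
    strand: str  # orientation of extraction relative to the k-mer as given
    offset: int  # spacer start on the extraction strand
    offtarget_hits: int | None = None
    max_hits_per_read: float | None = None
    n_reads_with_hit: int | None = None
    illumina_log10_coverage: float | None = None
    pacbio_log10_coverage: float | None = None
    perfect_assembly_hits: int | None = None
    verdict: dict = field(default_factory=dict)

    @property
    def site(self) -> str:
        return self.spacer + self.pam


def scan_pam_sites(kmer: str) -> list[CandidateTarget]:
    """All [spacer(20)][NGG] placements on either strand of the k-mer."""
    kmer = kmer.upper()
    if len(kmer) < SITE_LEN:
        raise ValueError(f"k-mer shorter than {SITE_LEN} nt cannot hold a target site")
    out = []
    for strand, seq in (("+", kmer), ("-", revcomp(kmer))):
        for i in range(len(seq) - SITE_LEN + 1):
            pam = seq[i + SPACER_LEN : i + SITE_LEN]
            if pam[1:] == "GG":
                out.append(
                    CandidateTarget(
                        kmer=kmer,
                        spacer=seq[i : i + SPACER_LEN],
                        pam=pam,
                        strand=strand,
                        offset=i,
                    )
                )
    return out


def count_offtargets(
    spacer: str,
    reference: Sequence,
    max_mismatches: int = 4,
) -> int:
    """PAM-adjacent near-matches of the protospacer in the off-target reference.

    Counts windows on either strand of any reference read where the 20-nt
    protospacer matches with <= ``max_mismatches`` Hamming mismatches and the
    adjacent PAM is still NGG. The reference is normally the autosomal- and
    Y-binned long reads.
    """
    refs = list(reference)
    if not refs:
        warnings.warn("empty off-target reference: reporting 0 hits")
        return 0
    q = encode(spacer.upper())
    g = encode("G")[0]
    hits = 0
    for rec in refs:
        seq = rec if isinstance(rec, str) else rec[1]
        for text in (seq, revcomp(seq)):
            t = encode(text)
            if t.size < SITE_LEN:
                continue
            mism = hamming_scan(t, q)
            m = mism.size
            # window i has PAM at i+20..i+23; require GG at positions 21, 22
            pam_ok = np.zeros(m, dtype=bool)
            upper = t.size - SITE_LEN + 1
            if upper > 0:
                pam_ok[:upper] = (t[SPACER_LEN + 1 : SPACER_LEN + 1 + upper] == g) & (
                    t[SPACER_LEN + 2 : SPACER_LEN + 2 + upper] == g
                )
            hits += int(np.count_nonzero((mism <= max_mismatches) & pam_ok))
    return hits


def count_perfect_hits(kmer: str, assembly: Sequence) -> int:
    """Exact occurrences of the k-mer (both strands) across assembly sequences."""
    from ._codec import count_exact_occurrences

    total = 0
    for rec in assembly:
        seq = rec if isinstance(rec, str) else rec[1]
        total += count_exact_occurrences(kmer.upper(), seq, both_strands=True)
    return total


def compute_abundance_metrics(
    kmer: str,
    long_reads: Sequence,
    census: KmerCensus,
) -> dict:
    """Repeat-abundance metrics for a k-mer.

    ``max_hits_per_read`` (exact occurrences on both strands, maximised over
    long reads) estimates the size of the repeat array; ``n_reads_with_hit``
    estimates its abundance across the chromosome. The log10 coverages are
    raw occurrence counts: combined male+female short-read count for
    Illumina, total occurrences across retained long reads for PacBio.
    """
    from ._codec import count_exact_occurrences

    kmer = kmer.upper()
    max_hits = 0
    n_reads = 0
    total_occ = 0
    for rec in long_reads:
        seq = rec if isinstance(rec, str) else rec[1]
        n = count_exact_occurrences(kmer, seq, both_strands=True)
        if n > 0:
            n_reads += 1
            total_occ += n
            max_hits = max(max_hits, n)
    key = kmer
    if census.canonical:
        from ._codec import canonical_kmer

        key = canonical_kmer(kmer)
    combined = (
        int(census.df.loc[key, "combined_count"]) if key in census.df.index else 0
    )
    return {
        "max_hits_per_read": float(max_hits),
        "n_reads_with_hit": n_reads,
        "illumina_log10_coverage": math.log10(combined) if combined > 0 else -math.inf,
        "pacbio_log10_coverage": math.log10(total_occ) if total_occ > 0 else -math.inf,
    }


def annotate_target(
    target: CandidateTarget,
    offtarget_reference: Sequence,
    long_reads: Sequence,
    census: KmerCensus,
    assembly: Sequence | None = None,
    thresholds: SelectionThresholds | None = None,
) -> CandidateTarget:
    """Populate off-target count, abundance metrics and perfect assembly hits."""
    thr = thresholds or SelectionThresholds()
    metrics = compute_abundance_metrics(target.kmer, long_reads, census)
    return replace(
        target,
        offtarget_hits=count_offtargets(
            target.spacer, offtarget_reference, thr.offtarget_mismatches
        ),
        perfect_assembly_hits=(
            count_perfect_hits(target.kmer, assembly) if assembly is not None else None
        ),
        **metrics,
    )


def apply_selection_filters(
    target: CandidateTarget, thresholds: SelectionThresholds | None = None
) -> dict:
    """Per-criterion booleans plus the overall verdict.

    ``illumina_coverage`` and ``pacbio_coverage`` are strict >, as is the
    7.5 maximum-hits-per-read cutoff; perfect assembly hits use >= and are
    marked not-evaluated (None) when no assembly was configured; off-target
    hits use <=. The verdict passes iff every evaluated criterion passes.
    """
    thr = thresholds or SelectionThresholds()
    required = {
        "offtarget_hits": target.offtarget_hits,
        "max_hits_per_read": target.max_hits_per_read,
        "illumina_log10_coverage": target.illumina_log10_coverage,
        "pacbio_log10_coverage": target.pacbio_log10_coverage,
    }
    for name, value in required.items():
        if value is None:
            raise IncompleteRecordError(
                f"metric {name!r} not populated; run annotate_target first"
            )
    verdict = {
        "illumina_coverage": target.illumina_log10_coverage > thr.illumina_log10_coverage,
        "pacbio_coverage": target.pacbio_log10_coverage > thr.pacbio_log10_coverage,
        "max_hits_per_read": target.max_hits_per_read > thr.max_hits_per_read,
        "perfect_assembly_hits": (
            None
            if target.perfect_assembly_hits is None
            else target.perfect_assembly_hits >= thr.min_perfect_hits
        ),
        "offtargets": target.offtarget_hits <= thr.max_offtargets,
    }
    verdict["pass"] = all(v for v in verdict.values() if v is not None)
    target.verdict = verdict
    return verdict


class TargetAnnotator:
    """Batch annotation of many candidate targets against fixed references.

    Precomputes, once: a per-k-mer occurrence index over the long reads
    (canonical window codes, giving max-hits-per-read / reads-with-hit /
    total occurrences), the encoded off-target texts (both strands) and the
    assembly's k-mer occurrence counts. Produces the same numbers as
    ``annotate_target`` but amortises the scans over thousands of k-mers.
    """

    def __init__(
        self,
        offtarget_reference: Sequence,
        long_reads: Sequence,
        census: KmerCensus,
        assembly: Sequence | None = None,
        thresholds: SelectionThresholds | None = None,
    ):
        from ._codec import canonical_window_codes, kmer_to_code

        self.census = census
        self.thresholds = thresholds or SelectionThresholds()
        self._kmer_to_code = kmer_to_code
        k = census.k

        self._max_hits: dict[int, int] = {}
        self._n_reads: dict[int, int] = {}
        self._total: dict[int, int] = {}
        for rec in long_reads:
            seq = rec if isinstance(rec, str) else rec[1]
            codes, valid = canonical_window_codes(encode(seq), k)
            uniq, counts = np.unique(codes[valid], return_counts=True)
            for c, n in zip(uniq.tolist(), counts.tolist()):
                self._max_hits[c] = max(self._max_hits.get(c, 0), n)
                self._n_reads[c] = self._n_reads.get(c, 0) + 1
                self._total[c] = self._total.get(c, 0) + n

        self._off_texts: list[np.ndarray] = []
        self._off_empty = True
        for rec in offtarget_reference:
            seq = rec if isinstance(rec, str) else rec[1]
            self._off_texts.append(encode(seq))
            self._off_texts.append(encode(revcomp(seq)))
            self._off_empty = False
        self._off_cache: dict[str, int] = {}

        self._asm_counts: dict[int, int] | None = None
        if assembly is not None:
            self._asm_counts = {}
            for rec in assembly:
                seq = rec if isinstance(rec, str) else rec[1]
                codes, valid = canonical_window_codes(encode(seq), k)
                uniq, counts = np.unique(codes[valid], return_counts=True)
                for c, n in zip(uniq.tolist(), counts.tolist()):
                    self._asm_counts[c] = self._asm_counts.get(c, 0) + n

    def _offtargets(self, spacer: str) -> int:
        cached = self._off_cache.get(spacer)
        if cached is not None:
            return cached
        if self._off_empty:
            warnings.warn("empty off-target reference: reporting 0 hits")
            self._off_cache[spacer] = 0
            return 0
        q = encode(spacer)
        g = encode("G")[0]
        mm = self.thresholds.offtarget_mismatches
        hits = 0
        for t in self._off_texts:
            if t.size < SITE_LEN:
                continue
            mism = hamming_scan(t, q)
            upper = t.size - SITE_LEN + 1
            pam_ok = (t[SPACER_LEN + 1 : SPACER_LEN + 1 + upper] == g) & (
                t[SPACER_LEN + 2 : SPACER_LEN + 2 + upper] == g
            )
            hits += int(np.count_nonzero((mism[:upper] <= mm) & pam_ok))
        self._off_cache[spacer] = hits
        return hits

    def annotate(
        self, target: CandidateTarget, skip_offtargets: bool = False
    ) -> CandidateTarget:
        from ._codec import canonical_kmer

        code = self._kmer_to_code(canonical_kmer(target.kmer))
        total_occ = self._total.get(code, 0)
        key = canonical_kmer(target.kmer) if self.census.canonical else target.kmer
        combined = (
            int(self.census.df.loc[key, "combined_count"])
            if key in self.census.df.index
            else 0
        )
        annotated = replace(
            target,
            offtarget_hits=(
                None if skip_offtargets else self._offtargets(target.spacer)
            ),
            max_hits_per_read=float(self._max_hits.get(code, 0)),
            n_reads_with_hit=self._n_reads.get(code, 0),
            illumina_log10_coverage=(
                math.log10(combined) if combined > 0 else -math.inf
            ),
            pacbio_log10_coverage=(
                math.log10(total_occ) if total_occ > 0 else -math.inf
            ),
            perfect_assembly_hits=(
                self._asm_counts.get(code, 0) if self._asm_counts is not None else None
            ),
        )
        return annotated


# ---------------------------------------------------------------------------
# contig reassembly
# ---------------------------------------------------------------------------


@dataclass
class RepeatContig:
    sequence: str
    members: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap (>= min_overlap, else 0)."""
    best = 0
    limit = min(len(a), len(b))
    for o in range(limit, min_overlap - 1, -1):
        if a[-o:] == b[:o]:
            return o
    return best


def assemble_contigs(
    kmers: Iterable[str], min_overlap: int = 10
) -> list[RepeatContig]:
    """Greedy zero-mismatch overlap assembly of a k-mer set into contigs.

    Repeatedly merges the pair with the longest exact suffix/prefix overlap;
    ties break toward the lexicographically smaller merged sequence. Every
    input k-mer ends up in exactly one contig (singletons allowed). Forward
    strand only.
    """
    contigs = [RepeatContig(sequence=k.upper(), members=(k.upper(),)) for k in dict.fromkeys(kmers)]
    if contigs and min_overlap > len(contigs[0].sequence):
        pass  # overlaps simply cannot occur; all singletons
    while len(contigs) > 1:
        best: tuple[int, str, int, int] | None = None  # (-overlap, merged, i, j)
        for i, a in enumerate(contigs):
            for j, b in enumerate(contigs):
                if i == j:
                    continue
                o = _best_overlap(a.sequence, b.sequence, min_overlap)
                if o:
                    merged = a.sequence + b.sequence[o:]
                    key = (-o, merged, i, j)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        o, merged, i, j = -best[0], best[1], best[2], best[3]
        a, b = contigs[i], contigs[j]
        new = RepeatContig(sequence=merged, members=a.members + b.members)
        contigs = [c for idx, c in enumerate(contigs) if idx not in (i, j)]
        contigs.append(new)
    return sorted(contigs, key=lambda c: (-c.length, c.sequence))


def targets_table(targets: Sequence[CandidateTarget]) -> pd.DataFrame:
    """One row per placement with metrics and per-criterion verdicts."""
    rows = []
    for t in targets:
        row = {
            "kmer": t.kmer,
            "spacer": t.spacer,
            "pam": t.pam,
            "strand": t.strand,
            "offset": t.offset,
            "offtarget_hits": t.offtarget_hits,
            "max_hits_per_read": t.max_hits_per_read,
            "n_reads_with_hit": t.n_reads_with_hit,
            "illumina_log10_coverage": t.illumina_log10_coverage,
            "pacbio_log10_coverage": t.pacbio_log10_coverage,
            "perfect_assembly_hits": t.perfect_assembly_hits,
        }
        for name, v in t.verdict.items():
            row[f"criterion_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
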