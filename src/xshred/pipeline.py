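"""End-to-end target discovery: census -> linkage binning -> target vetting.

Chains the pipeline stages on in-memory read sets and returns every
intermediate product, so a complete discovery run on raw sexed reads plus
long reads is a single call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .census import CensusThresholds, KmerCensus
from .targets import (
    CandidateTarget,
    SelectionThresholds,
    TargetAnnotator,
    apply_selection_filters,
    scan_pam_sites,
    targets_table,
)
from .xlinkage import LinkageThresholds, bin_long_reads, call_x_kmers, filter_long_reads


@dataclass
class DiscoveryResult:
    census: KmerCensus
    mito_removed: int
    long_read_bins: pd.DataFrame
    x_kmers: pd.DataFrame
    targets: list[CandidateTarget] = field(default_factory=list)

    @property
    def candidate_kmers(self) -> pd.Index:
        return self.x_kmers.index[self.x_kmers["candidate"]]

    @property
    def passing_targets(self) -> list[CandidateTarget]:
        return [t for t in self.targets if t.verdict.get("pass")]

    def targets_table(self) -> pd.DataFrame:
        return targets_table(self.targets)


def run_discovery(
    male_reads: Sequence,
    female_reads: Sequence,
    long_reads: Sequence,
    mito_seq: str,
    assembly: Sequence | None = None,
    k: int = 25,
    canonical: bool = True,
    census_thresholds: CensusThresholds | None = None,
    linkage_thresholds: LinkageThresholds | None = None,
    selection_thresholds: SelectionThresholds | None = None,
    offtarget_scope: str = "shortlist",
) -> DiscoveryResult:
    """Run the whole discovery pipeline on raw reads.

    Steps: joint sexed k-mer census; mitochondrial and minimum-abundance
    filtering; long-read length filtering and CQ binning; candidate X-kmer
    calling; PAM scanning of candidates; off-target screening against the
    autosomal/Y long-read bins; abundance metrics and shortlist filters
    (perfect-hit validation only when an assembly is supplied).

    ``offtarget_scope``: "shortlist" (default) screens off-targets only for
    placements already passing the abundance cutoffs — others fail anyway
    and carry ``offtarget_hits=None``; "all" screens every placement.
    """
    if offtarget_scope not in ("shortlist", "all"):
        raise ValueError("offtarget_scope must be 'shortlist' or 'all'")
    cthr = census_thresholds or CensusThresholds(k=k)
    lthr = linkage_thresholds or LinkageThresholds()
    sthr = selection_thresholds or SelectionThresholds()

    census = KmerCensus.from_read_sets(male_reads, female_reads, k=k, canonical=canonical)
    census, mito_removed = census.filter_mitochondrial(mito_seq)
    census = census.apply_min_count(cthr)

    retained, _ = filter_long_reads(long_reads, lthr)
    bins = bin_long_reads(retained, census, lthr, mito_seq)
    x_kmers = call_x_kmers(census, retained, bins, lthr)

    offtarget_ref = [
        (rid, seq)
        for (rid, seq), b in zip(retained, bins["bin"])
        if b in ("autosomal", "Y")
    ]
    annotator = TargetAnnotator(offtarget_ref, retained, census, assembly, sthr)
    targets: list[CandidateTarget] = []
    for kmer in x_kmers.index[x_kmers["candidate"]]:
        for stub in scan_pam_sites(kmer):
            t = annotator.annotate(stub, skip_offtargets=True)
            abundance_ok = (
                t.illumina_log10_coverage > sthr.illumina_log10_coverage
                and t.pacbio_log10_coverage > sthr.pacbio_log10_coverage
                and t.max_hits_per_read > sthr.max_hits_per_read
            )
            if offtarget_scope == "all" or abundance_ok:
                # screen only the abundance shortlist by default: the vast
                # majority of candidate X-kmers are single-copy background
                # that the coverage cutoffs already exclude
                t = replace(t, offtarget_hits=annotator._offtargets(t.spacer))
                apply_selection_filters(t, sthr)
            else:
                t.verdict = {
                    "illumina_coverage": t.illumina_log10_coverage
                    > sthr.illumina_log10_coverage,
                    "pacbio_coverage": t.pacbio_log10_coverage
                    > sthr.pacbio_log10_coverage,
                    "max_hits_per_read": t.max_hits_per_read > sthr.max_hits_per_read,
                    "perfect_assembly_hits": (
                        None
                        if t.perfect_assembly_hits is None
                        else t.perfect_assembly_hits >= sthr.min_perfect_hits
                    ),
                    "offtargets": None,
                    "pass": False,
                }
            targets.append(t)
    targets.sort(
        key=lambda t: (
            t.offtarget_hits if t.offtarget_hits is not None else 10**9,
            t.kmer,
            t.strand,
            t.offset,
        )
    )
    return DiscoveryResult(
        census=census,
        mito_removed=mito_removed,
        long_read_bins=bins,
        x_kmers=x_kmers,
        targets=targets,
    )
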