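"""Editing-outcome quantification from amplicon deep sequencing.

Reads are mean-quality filtered (Phred+33, default minimum 30), globally
aligned to the reference amplicon with affine gap penalties, and reduced to
an allele: the aligned slice over the target window (20-nt protospacer +
NGG PAM), with deletions as gaps and insertions left-aligned so that
equivalent indel representations collapse to one allele. On top of the
per-sample allele tables the module computes the intact-target fraction,
unique-allele censuses (>=1% frequency / >=10 reads), pre-existing versus
de-novo classification against control samples, cleavage-resistance calls
(mutated PAM, seed substitutions, or indels), median allele frequencies
across experimental samples, linked-marker dissociation and, for coding
targets, frameshift / in-frame / missense calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

SPACER_LEN = 20
PAM_LEN = 3
WINDOW_LEN = SPACER_LEN + PAM_LEN

_GAP_COMPLEMENT = str.maketrans("ACGT-", "TGCA-")


def _revcomp_gapped(s: str) -> str:
    return s.translate(_GAP_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Marker:
    """A linked polymorphism inside the amplicon (e.g. a 6-bp indel upstream
    of the target); ``alt_allele`` may be empty for a pure deletion."""

    offset: int
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon plus target-window geometry.

    ``window_start`` is the protospacer start in reference coordinates; on
    the '+' strand the PAM occupies the last 3 window positions, on the '-'
    strand the first 3 (guide on the reverse strand). The cut sits between
    protospacer positions ``cut_offset`` and ``cut_offset``+1 (default 17|18,
    3 bp 5' of the PAM). ``frame`` gives the codon phase for coding targets:
    the first complete codon starts at reference position ``frame``.
    """

    reference: str
    window_start: int
    strand: str = "+"
    cut_offset: int = 17
    frame: int | None = None
    marker: Marker | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.window_start <= len(self.reference) - WINDOW_LEN:
            raise ValueError("target window must lie inside the amplicon")
        if not 0 < self.cut_offset < SPACER_LEN:
            raise ValueError("cut offset must fall inside the protospacer")
        if self.marker is not None:
            m = self.marker
            if m.offset < 0 or m.offset + len(m.ref_allele) > len(self.reference):
                raise ValueError("marker locus falls outside the amplicon")

    @property
    def window_end(self) -> int:
        return self.window_start + WINDOW_LEN

    @property
    def window(self) -> str:
        return self.reference[self.window_start : self.window_end]

    @property
    def cut_position(self) -> int:
        """Reference coordinate of the cut (between this position and the previous)."""
        if self.strand == "+":
            return self.window_start + self.cut_offset
        return self.window_start + WINDOW_LEN - self.cut_offset

    def guide_window(self, window_seq: str | None = None) -> str:
        """The window in guide orientation: spacer(20) then PAM(3)."""
        w = self.window if window_seq is None else window_seq
        return w if self.strand == "+" else _revcomp_gapped(w)


@dataclass(frozen=True)
class AlleleThresholds:
    min_mean_quality: float = 30.0
    census_min_frequency: float = 0.01
    census_min_reads: int = 10
    noise_min_reads: int = 2
    noise_min_frequency: float = 0.001
    min_flank_identity: float = 0.8

    def __post_init__(self):
        if self.min_mean_quality < 0 or self.census_min_reads < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class Allele:
    """A target-window allele relative to the reference.

    ``window`` holds the read bases aligned to each reference window
    position ('-' where deleted); ``insertions`` are (window offset,
    sequence) pairs for bases inserted strictly inside the window.
    """

    window: str
    insertions: tuple[tuple[int, str], ...] = ()

    @property
    def key(self) -> str:
        ins = "".join(f"+{p}:{s}" for p, s in self.insertions)
        return self.window + ins

    @property
    def has_indel(self) -> bool:
        return "-" in self.window or bool(self.insertions)

    @property
    def net_indel(self) -> int:
        return sum(len(s) for _, s in self.insertions) - self.window.count("-")

    def sequence(self) -> str:
        """The degapped window sequence with insertions spliced in."""
        parts = []
        ins = dict(self.insertions)
        for i, base in enumerate(self.window):
            if i in ins:
                parts.append(ins[i])
            if base != "-":
                parts.append(base)
        if len(self.window) in ins:
            parts.append(ins[len(self.window)])
        return "".join(parts)

    def is_intact(self, spec: AmpliconSpec) -> bool:
        return not self.insertions and self.window == spec.window


# ---------------------------------------------------------------------------
# quality filtering and alignment
# ---------------------------------------------------------------------------


def quality_filter(
    reads: Iterable, thresholds: AlleleThresholds | None = None
) -> tuple[list, int]:
    """Keep reads whose mean Phred quality is >= the minimum (inclusive)."""
    thr = thresholds or AlleleThresholds()
    kept, dropped = [], 0
    for rec in reads:
        quals = rec[2]
        if quals and float(np.mean(quals)) >= thr.min_mean_quality:
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def _alignment_maps(ref: str, read: str, aligner: Align.PairwiseAligner):
    """Per-reference-position read bases plus insertion positions.

    Returns ``(ref_map, insertions)`` where ``ref_map[i]`` is the read base
    aligned to reference position i ('-' when deleted) and ``insertions``
    maps a reference position p to the read bases inserted between p-1 and p.
    """
    aln = aligner.align(ref, read)[0]
    t_blocks, q_blocks = aln.aligned
    ref_map = ["-"] * len(ref)
    insertions: dict[int, str] = {}
    prev_t_end = prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q_end:  # unaligned read bases -> insertion before ts
            insertions[ts] = insertions.get(ts, "") + read[prev_q_end:qs]
        for i in range(ts, te):
            ref_map[i] = read[qs + (i - ts)]
        prev_t_end, prev_q_end = te, qe
    if prev_q_end < len(read):
        insertions[len(ref)] = insertions.get(len(ref), "") + read[prev_q_end:]
    return ref_map, insertions


def _left_align(ref: str, ref_map: list[str], insertions: dict[int, str]):
    """Shift indels left where flanking bases permit, for representation-
    invariant allele identity (VCF-style normalisation)."""
    # deletions: runs of '-' in ref_map
    changed = True
    while changed:
        changed = False
        i = 0
        n = len(ref)
        while i < n:
            if ref_map[i] == "-":
                j = i
                while j < n and ref_map[j] == "-":
                    j += 1
                # run [i, j); shift left if ref[i-1] == ref[j-1] and position
                # i-1 is a matching base
                if (
                    i > 0
                    and ref_map[i - 1] == ref[i - 1]
                    and ref[i - 1] == ref[j - 1]
                    and (i - 1) not in insertions
                    and i not in insertions
                ):
                    ref_map[j - 1] = ref_map[i - 1]
                    ref_map[i - 1] = "-"
                    changed = True
                i = j
            else:
                i += 1
        for p in sorted(list(insertions)):
            s = insertions[p]
            if (
                p > 0
                and ref_map[p - 1] == ref[p - 1]
                and s[-1] == ref[p - 1]
                and (p - 1) not in insertions
            ):
                del insertions[p]
                insertions[p - 1] = s[-1] + s[:-1]
                changed = True
    return ref_map, insertions


def extract_allele(
    read: str | tuple,
    spec: AmpliconSpec,
    thresholds: AlleleThresholds | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> Allele | None:
    """Align one read to the reference amplicon and slice the target window.

    Returns ``None`` (unalignable) when the flanks outside the window align
    below the identity threshold; such reads are excluded from denominators.
    """
    thr = thresholds or AlleleThresholds()
    seq = read if isinstance(read, str) else read[1]
    if seq == spec.reference:  # overwhelmingly common fast path
        return Allele(window=spec.window)
    al = aligner or _make_aligner()
    ref = spec.reference
    ref_map, insertions = _alignment_maps(ref, seq, al)
    ref_map, insertions = _left_align(ref, ref_map, insertions)
    ws, we = spec.window_start, spec.window_end
    flank_positions = [i for i in range(len(ref)) if i < ws or i >= we]
    matches = sum(1 for i in flank_positions if ref_map[i] == ref[i])
    if flank_positions and matches / len(flank_positions) < thr.min_flank_identity:
        return None
    window = "".join(ref_map[ws:we])
    ins = tuple(
        (p - ws, insertions[p]) for p in sorted(insertions) if ws < p < we
    )
    return Allele(window=window, insertions=ins)


def _marker_call(ref_map, insertions, spec: AmpliconSpec) -> str:
    m = spec.marker
    a, b = m.offset, m.offset + len(m.ref_allele)
    parts = []
    for i in range(a, b):
        if i in insertions and i > a:
            parts.append(insertions[i])
        if ref_map[i] != "-":
            parts.append(ref_map[i])
    seq = "".join(parts)
    if seq == m.ref_allele:
        return "ref"
    if seq == m.alt_allele:
        return "alt"
    return "other"


# ---------------------------------------------------------------------------
# per-sample allele tables
# ---------------------------------------------------------------------------


def build_allele_table(
    reads: Iterable,
    spec: AmpliconSpec,
    thresholds: AlleleThresholds | None = None,
    apply_quality_filter: bool = True,
) -> pd.DataFrame:
    """Quality-filter, align and tally one sample's reads into an allele table.

    The table is indexed by allele key with columns ``window``,
    ``insertions``, ``reads``, ``frequency`` (over alignable reads) and
    ``intact``; counts of dropped/unalignable reads are kept in ``attrs``.
    Alignment results are memoised per distinct read sequence.
    """
    thr = thresholds or AlleleThresholds()
    reads = list(reads)
    n_quality_dropped = 0
    if apply_quality_filter and reads and not isinstance(reads[0], str) and len(reads[0]) > 2:
        reads, n_quality_dropped = quality_filter(reads, thr)
    aligner = _make_aligner()
    cache: dict[str, Allele | None] = {}
    counts: dict[str, int] = {}
    alleles: dict[str, Allele] = {}
    n_unalignable = 0
    for rec in reads:
        seq = rec if isinstance(rec, str) else rec[1]
        if seq in cache:
            allele = cache[seq]
        else:
            allele = extract_allele(seq, spec, thr, aligner)
            cache[seq] = allele
        if allele is None:
            n_unalignable += 1
            continue
        counts[allele.key] = counts.get(allele.key, 0) + 1
        alleles[allele.key] = allele
    total = sum(counts.values())
    rows = []
    for key, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        a = alleles[key]
        rows.append(
            {
                "allele": key,
                "window": a.window,
                "insertions": ";".join(f"{p}:{s}" for p, s in a.insertions),
                "reads": n,
                "frequency": n / total if total else math.nan,
                "intact": a.is_intact(spec),
            }
        )
    df = pd.DataFrame(
        rows, columns=["allele", "window", "insertions", "reads", "frequency", "intact"]
    ).set_index("allele")
    df.attrs["n_alignable"] = total
    df.attrs["n_unalignable"] = n_unalignable
    df.attrs["n_quality_dropped"] = n_quality_dropped
    return df


def allele_from_key(key: str) -> Allele:
    """Inverse of ``Allele.key``."""
    if "+" in key:
        window, _, rest = key.partition("+")
        ins = []
        for part in ("+" + rest).split("+")[1:]:
            p, _, s = part.partition(":")
            ins.append((int(p), s))
        return Allele(window=window, insertions=tuple(ins))
    return Allele(window=key)


def intact_fraction(table: pd.DataFrame) -> float:
    """Fraction of alignable reads whose window matches the reference exactly."""
    total = int(table["reads"].sum())
    if total == 0:
        return math.nan
    return int(table.loc[table["intact"], "reads"].sum()) / total


def census_alleles(
    table: pd.DataFrame, thresholds: AlleleThresholds | None = None
) -> dict:
    """Unique-allele counts under the frequency (>=1%) and read (>=10) criteria,
    reported with and without the wild-type allele."""
    thr = thresholds or AlleleThresholds()
    by_freq = table["frequency"] >= thr.census_min_frequency
    by_reads = table["reads"] >= thr.census_min_reads
    wt = table["intact"]
    return {
        "freq_criterion": int(by_freq.sum()),
        "reads_criterion": int(by_reads.sum()),
        "freq_criterion_excl_wt": int((by_freq & ~wt).sum()),
        "reads_criterion_excl_wt": int((by_reads & ~wt).sum()),
    }


def _present(table: pd.DataFrame, key: str, thr: AlleleThresholds) -> bool:
    if key not in table.index:
        return False
    row = table.loc[key]
    return (
        row["reads"] >= thr.noise_min_reads
        and row["frequency"] >= thr.noise_min_frequency
    )


def classify_alleles(
    tables: Mapping[str, pd.DataFrame],
    control_ids: Sequence[str],
    thresholds: AlleleThresholds | None = None,
) -> pd.DataFrame:
    """Classify every allele as intact / pre-existing / de-novo.

    An allele present (above the noise floor) in *all* control samples is
    pre-existing; one absent from every control is de-novo; one seen in some
    but not all controls is ambiguous. The reference window is class intact.
    """
    if not control_ids:
        raise ValueError("at least one control sample must be designated")
    missing = [c for c in control_ids if c not in tables]
    if missing:
        raise ValueError(f"control sample(s) not in tables: {missing}")
    thr = thresholds or AlleleThresholds()
    all_keys: dict[str, bool] = {}
    for name, table in tables.items():
        for key in table.index:
            if _present(table, key, thr):
                all_keys.setdefault(key, False)
    rows = []
    for key in sorted(all_keys):
        intact = any(
            key in t.index and bool(t.loc[key, "intact"]) for t in tables.values()
        )
        in_controls = [_present(tables[c], key, thr) for c in control_ids]
        if intact:
            cls = "intact"
        elif all(in_controls):
            cls = "pre-existing"
        elif not any(in_controls):
            cls = "de-novo"
        else:
            cls = "ambiguous"
        rows.append({"allele": key, "class": cls, "n_controls_present": sum(in_controls)})
    return pd.DataFrame(rows, columns=["allele", "class", "n_controls_present"]).set_index(
        "allele"
    )


# ---------------------------------------------------------------------------
# resistance, frequencies, linkage, coding effects
# ---------------------------------------------------------------------------


def flag_resistant(
    allele: Allele | str,
    spec: AmpliconSpec,
    seed_length: int = 10,
) -> tuple[bool, dict]:
    """Is this allele predicted cleavage-resistant?

    Resistant if the PAM is no longer NGG, if any substitution falls in the
    PAM-proximal seed (last ``seed_length`` protospacer positions), or if
    the window carries an indel. Returns the call plus per-feature evidence.
    """
    if isinstance(allele, str):
        allele = allele_from_key(allele)
    if allele.has_indel:
        return True, {"indel": True, "pam_mutated": False, "seed_substitutions": []}
    guide = spec.guide_window(allele.window)
    spacer, pam = guide[:SPACER_LEN], guide[SPACER_LEN:]
    ref_guide = spec.guide_window()
    ref_spacer = ref_guide[:SPACER_LEN]
    pam_mutated = pam[1:] != "GG"
    subs = [i for i in range(SPACER_LEN) if spacer[i] != ref_spacer[i]]
    seed_subs = [i for i in subs if i >= SPACER_LEN - seed_length]
    evidence = {
        "indel": False,
        "pam_mutated": pam_mutated,
        "seed_substitutions": seed_subs,
        "distal_substitutions": [i for i in subs if i < SPACER_LEN - seed_length],
    }
    return pam_mutated or bool(seed_subs), evidence


def allele_frequency_summary(
    tables: Mapping[str, pd.DataFrame],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-sample allele frequencies plus the median across experimental samples.

    Controls are reported as separate columns and excluded from the median.
    """
    experimental = [s for s in tables if s not in set(control_ids)]
    keys = sorted({k for t in tables.values() for k in t.index})
    data = {}
    for name, table in tables.items():
        freq = table["frequency"].reindex(keys).fillna(0.0)
        data[name] = freq
    df = pd.DataFrame(data, index=keys)
    df["median_experimental"] = df[experimental].median(axis=1)
    return df


def linked_marker_dissociation(
    reads: Iterable,
    spec: AmpliconSpec,
    is_resistant: Callable[[Allele], bool] | None = None,
    null_dissociation_rate: float | None = None,
    error_rate: float = 0.001,
    alpha: float = 0.01,
    thresholds: AlleleThresholds | None = None,
) -> dict:
    """Joint genotype of target window x linked marker, per read.

    Dissociation (gene conversion) is reported when resistant-allele reads
    carrying the *reference* marker form exceed what sequencing error alone
    would produce; the verdict includes the exact binomial tail probability.
    """
    if spec.marker is None:
        raise ValueError("no linked marker defined in the amplicon spec")
    thr = thresholds or AlleleThresholds()
    if is_resistant is None:
        is_resistant = lambda a: flag_resistant(a, spec)[0]  # noqa: E731
    if null_dissociation_rate is None:
        null_dissociation_rate = error_rate * len(spec.marker.ref_allele)
    aligner = _make_aligner()
    cache: dict[str, tuple[Allele | None, str]] = {}
    table = {("resistant", "alt"): 0, ("resistant", "ref"): 0,
             ("resistant", "other"): 0, ("susceptible", "alt"): 0,
             ("susceptible", "ref"): 0, ("susceptible", "other"): 0}
    for rec in reads:
        seq = rec if isinstance(rec, str) else rec[1]
        if seq in cache:
            allele, marker = cache[seq]
        else:
            ref_map, insertions = _alignment_maps(spec.reference, seq, aligner)
            ref_map, insertions = _left_align(spec.reference, ref_map, insertions)
            ws, we = spec.window_start, spec.window_end
            window = "".join(ref_map[ws:we])
            ins = tuple((p - ws, insertions[p]) for p in sorted(insertions) if ws < p < we)
            allele = Allele(window=window, insertions=ins)
            marker = _marker_call(ref_map, insertions, spec)
            cache[seq] = (allele, marker)
        row = "resistant" if is_resistant(allele) else "susceptible"
        table[(row, marker)] += 1
    n_resistant = sum(v for (r, _), v in table.items() if r == "resistant")
    dissociated = table[("resistant", "ref")]
    if n_resistant == 0:
        p_value = math.nan
        detected = False
    else:
        p_value = float(
            stats.binom.sf(dissociated - 1, n_resistant, null_dissociation_rate)
        )
        detected = dissociated > 0 and p_value < alpha
    return {
        "contingency": table,
        "n_resistant_reads": n_resistant,
        "n_dissociated": dissociated,
        "null_rate": null_dissociation_rate,
        "p_value": p_value,
        "dissociation_detected": detected,
    }


@dataclass(frozen=True)
class CodingEffect:
    kind: str  # none | synonymous | missense | in-frame indel | frameshift
    protein_change: str | None = None
    net_indel: int = 0


def classify_coding_effect(allele: Allele | str, spec: AmpliconSpec) -> CodingEffect:
    """Predict the coding consequence of an allele for an in-frame target.

    Net indel length not divisible by 3 is a frameshift; divisible (nonzero
    change) an in-frame indel; substitutions are translated codon-by-codon
    and reported as amino-acid changes (e.g. ``K5>N``, 1-based codon index
    within the amplicon's reading frame).
    """
    if isinstance(allele, str):
        allele = allele_from_key(allele)
    if spec.frame is None:
        warnings.warn("no reading frame defined; coding effect not evaluated")
        return CodingEffect(kind="none")
    if allele.has_indel:
        net = allele.net_indel
        kind = "frameshift" if net % 3 else "in-frame indel"
        return CodingEffect(kind=kind, net_indel=net)
    edited = (
        spec.reference[: spec.window_start]
        + allele.sequence()
        + spec.reference[spec.window_end :]
    )
    f = spec.frame
    n_codons = (len(spec.reference) - f) // 3
    ref_aa = str(Seq(spec.reference[f : f + 3 * n_codons]).translate())
    alt_aa = str(Seq(edited[f : f + 3 * n_codons]).translate())
    changes = [
        f"{r}{i + 1}>{a}" for i, (r, a) in enumerate(zip(ref_aa, alt_aa)) if r != a
    ]
    if allele.window == spec.window:
        return CodingEffect(kind="none")
    if changes:
        return CodingEffect(kind="missense", protein_change=",".join(changes))
    return CodingEffect(kind="synonymous")
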