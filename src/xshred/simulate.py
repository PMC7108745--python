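"""Synthetic genomes, sexed read sets, repeat-cluster editing and amplicon reads.

The generator emulates the data a sex-distorter design study works from:

* a toy genome with a hemizygous-male X, at least one autosome, a Y and a
  mitochondrion, carrying X-linked tandem-repeat clusters in which every
  repeat unit holds one copy of a Cas9 target site (20-nt protospacer + NGG
  PAM), optionally with one designated cleavage-resistant unit whose target
  window carries protospacer and PAM substitutions and which can be linked to
  a 6-bp deletion marker 53 bp upstream of the target;
* sexed Illumina-like short reads whose per-base coverage is proportional to
  chromosome copy number (females 2X:2A, males 1X:2A:1Y), the signal the
  chromosome quotient reads out;
* length-distributed PacBio-like long reads with a provenance truth table;
* germline editing of a cluster as sequential cut-repair cycles (meiotic =
  one/few cycles, pre-meiotic = many), with per-cycle cleavage of intact
  targets, disrupting-indel versus faithful repair, and optional unit-granular
  collapse of units between two simultaneous cuts;
* amplicon reads drawn multinomially from the surviving repeat units so that
  read proportions mirror surviving unit copies.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codec import encode, revcomp

TARGET_LEN = 23  # 20-nt protospacer + 3-nt PAM
SPACER_LEN = 20
CUT_OFFSET = 17  # blunt cut between protospacer positions 17|18, 3 bp 5' of the PAM
MARKER_LEN = 6
MARKER_GAP = 53  # bp between marker end and target start
DEFAULT_AMPLICON_LEN = 153

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatClusterSpec:
    """An X-linked (or decoy) tandem repeat cluster.

    ``substitution_rate`` is the per-base probability that a unit copy differs
    from the cluster consensus outside the target window and marker span,
    modelling the natural heterogeneity of repeat clusters. ``resistant_unit``
    designates one unit as a pre-existing cleavage-resistant allele: its
    window carries ≥1 protospacer and ≥1 PAM substitution, and when
    ``resistant_marker`` is set it additionally carries a linked 6-bp deletion
    53 bp upstream of the target site.
    """

    chrom: str = "X"
    start: int = 10_000
    unit_length: int = 271
    unit_count: int = 12
    substitution_rate: float = 0.01
    resistant_unit: int | None = None
    resistant_marker: bool = True
    carries_target: bool = True  # False: decoy repeat without the gRNA site

    def __post_init__(self):
        if self.unit_length < 30:
            raise ValueError("repeat unit length must be >= 30 bp")
        if self.unit_count < 2:
            raise ValueError("repeat unit count must be >= 2")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution rate must be in [0, 1)")
        if self.resistant_unit is not None and not (
            0 <= self.resistant_unit < self.unit_count
        ):
            raise ValueError("resistant unit index out of range")

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.unit_count


@dataclass(frozen=True)
class CodingLocusSpec:
    """A single-copy coding locus (toy essential gene) carrying the target in frame."""

    chrom: str = "X"
    start: int = 200_000
    cds_length: int = 300
    amplicon_length: int = 234

    def __post_init__(self):
        if self.cds_length % 3:
            raise ValueError("CDS length must be a multiple of 3")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, repeat clusters and embedded loci of the toy genome.

    Defaults keep a full discovery-to-amplicon run at desk scale: 500 kb X,
    300 kb autosome, 500 kb Y, 16 kb mitochondrion. The Y matches the X in
    size so the male and female genomes are equal in length: with counts
    normalised per million read bases that calibrates the chromosome
    quotient of X-linked sequence at exactly 2 (it otherwise converges to
    2 x male/female genome size).
    """

    x_length: int = 500_000
    autosome_lengths: tuple[int, ...] = (300_000,)
    y_length: int = 500_000
    mito_length: int = 16_000
    clusters: tuple[RepeatClusterSpec, ...] = ()
    coding_loci: tuple[CodingLocusSpec, ...] = ()
    target_site: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.autosome_lengths:
            raise ValueError("at least one autosome is required")
        if self.target_site is not None:
            site = self.target_site.upper()
            if len(site) != TARGET_LEN or site[-2:] != "GG":
                raise ValueError("target site must be 23 nt ending in an NGG PAM")
        lengths = self.chromosome_lengths()
        for cl in self.clusters:
            if cl.chrom not in lengths:
                raise ValueError(f"cluster chromosome {cl.chrom!r} not in genome")
            if cl.start < 0 or cl.end > lengths[cl.chrom]:
                raise ValueError("cluster coordinates fall outside the chromosome")
        by_chrom: dict[str, list[RepeatClusterSpec]] = {}
        for cl in self.clusters:
            for other in by_chrom.get(cl.chrom, []):
                if cl.start < other.end and other.start < cl.end:
                    raise ValueError(
                        f"overlapping repeat clusters on {cl.chrom}: "
                        f"[{other.start},{other.end}) and [{cl.start},{cl.end})"
                    )
            by_chrom.setdefault(cl.chrom, []).append(cl)

    def chromosome_lengths(self) -> dict[str, int]:
        lengths = {"X": self.x_length}
        for i, L in enumerate(self.autosome_lengths):
            lengths[str(i + 2)] = L
        lengths["Y"] = self.y_length
        lengths["MT"] = self.mito_length
        return lengths

    def autosome_names(self) -> list[str]:
        return [str(i + 2) for i in range(len(self.autosome_lengths))]


@dataclass(frozen=True)
class ReadSimSpec:
    """Read-simulation parameters.

    ``depth`` is the mean coverage contributed by a single chromosome copy, so
    an autosomal position in either sex is covered ~2x``depth``. The long-read
    length window defaults to 2-20 kb: the 2-100 kb window the linkage filter
    uses, truncated at the top because toy chromosomes are only hundreds of
    kb long.
    """

    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.001
    long_read_count: int = 200
    long_read_min: int = 2_000
    long_read_max: int = 20_000
    long_read_error_rate: float = 0.001
    quality: int = 38

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.long_read_min >= self.long_read_max:
            raise ValueError("long-read length window requires min < max")
        if not 0 <= self.error_rate < 1 or not 0 <= self.long_read_error_rate < 1:
            raise ValueError("error rates must be in [0, 1)")


@dataclass(frozen=True)
class EditingModel:
    """Sequential cut-repair model of germline cluster editing.

    Each cycle, every intact (non-resistant, non-disrupted, non-deleted) unit
    is cleaved with probability ``cleavage_prob``; a cleaved unit is repaired
    to a disrupting indel with probability ``disrupting_repair_prob`` and
    restored faithfully otherwise (and can then be re-cut in a later cycle).
    When two units are cut in the same cycle with no cut between them,
    ``intercut_deletion_prob`` is the chance that all units strictly between
    the pair collapse (whole-unit deletion). A designated resistant unit is
    never cleaved.
    """

    cycles: int = 1
    cleavage_prob: float = 0.5
    disrupting_repair_prob: float = 0.9
    indel_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    indel_size_probs: tuple[float, ...] = (0.30, 0.25, 0.17, 0.12, 0.09, 0.07)
    insertion_prob: float = 0.15
    intercut_deletion_prob: float = 0.0

    def __post_init__(self):
        for p in (
            self.cleavage_prob,
            self.disrupting_repair_prob,
            self.insertion_prob,
            self.intercut_deletion_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if any(s < 1 for s in self.indel_sizes):
            raise ValueError("indel sizes must be >= 1")
        if len(self.indel_sizes) != len(self.indel_size_probs):
            raise ValueError("indel size spectrum and probabilities differ in length")
        if abs(sum(self.indel_size_probs) - 1.0) > 1e-9:
            raise ValueError("indel size probabilities must sum to 1")

    def expected_intact_fraction(self, n_units: int, n_resistant: int = 0) -> float:
        """Closed-form expected fraction of units left intact (no inter-cut deletions).

        A non-resistant unit stays intact through one cycle unless it is cut
        and repaired disruptively, so P(intact) = (1 - p_cut * p_disrupt)^cycles.
        """
        if self.intercut_deletion_prob > 0:
            raise ValueError(
                "closed form only valid without inter-cut deletions"
            )
        p_unit = (1.0 - self.cleavage_prob * self.disrupting_repair_prob) ** self.cycles
        return p_unit * (n_units - n_resistant) / n_units


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


@dataclass
class UnitTruth:
    index: int
    unit_seq: str
    amplicon_seq: str
    resistant: bool


@dataclass
class ClusterTruth:
    """Ground truth for one built repeat cluster."""

    spec: RepeatClusterSpec
    target_site: str
    target_offset: int  # target start within each (consensus-length) unit
    amp_start: int
    amp_end: int
    marker_span: tuple[int, int] | None  # within the reference amplicon
    reference_amplicon: str  # consensus unit's amplicon
    units: list[UnitTruth] = field(default_factory=list)

    @property
    def cut_position(self) -> int:
        """Cut coordinate within the reference amplicon."""
        return self.target_offset - self.amp_start + CUT_OFFSET

    @property
    def window_start(self) -> int:
        """Target-window start within the reference amplicon."""
        return self.target_offset - self.amp_start


@dataclass
class Genome:
    spec: GenomeSpec
    sequences: dict[str, str]
    clusters: list[ClusterTruth]
    coding_truth: list[dict]
    target_site: str

    @property
    def units(self) -> pd.DataFrame:
        """Per-unit truth annotation across clusters (target positions included)."""
        rows = []
        for ci, cl in enumerate(self.clusters):
            pos = cl.spec.start
            for u in cl.units:
                rows.append(
                    {
                        "cluster": ci,
                        "chrom": cl.spec.chrom,
                        "unit": u.index,
                        "start": pos,
                        "end": pos + len(u.unit_seq),
                        "target_pos": (
                            pos + cl.target_offset if cl.spec.carries_target else -1
                        ),
                        "resistant": u.resistant,
                    }
                )
                pos += len(u.unit_seq)
        return pd.DataFrame(rows)

    def to_fasta_records(self):
        return list(self.sequences.items())


def _mutate_outside(
    seq: str, rate: float, protected: list[tuple[int, int]], rng: np.random.Generator
) -> str:
    codes = encode(seq).copy()
    mask = rng.random(len(codes)) < rate
    for a, b in protected:
        mask[a:b] = False
    idx = np.flatnonzero(mask)
    if idx.size:
        codes[idx] = (codes[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return _BASES[codes].tobytes().decode()


def _patch_spurious(seq: str, site: str, keep_at: list[int], rng) -> str:
    """Destroy accidental occurrences of the target site (either strand)."""
    for probe in (site, revcomp(site)):
        start = 0
        while True:
            i = seq.find(probe, start)
            if i < 0:
                break
            if probe == site and i in keep_at:
                start = i + 1
                continue
            j = i + TARGET_LEN // 2
            old = seq[j]
            new = "ACGT"[(("ACGT".index(old)) + 1 + int(rng.integers(0, 3))) % 4]
            seq = seq[:j] + new + seq[j + 1 :]
            start = i + 1
    return seq


def build_genome(spec: GenomeSpec) -> Genome:
    """Materialise the toy genome and its truth annotation.

    Every repeat unit contains exactly one occurrence of the consensus target
    site unless designated resistant; accidental extra occurrences created by
    the random background are patched away.
    """
    rng = np.random.default_rng(spec.seed)
    site = spec.target_site.upper() if spec.target_site else _random_seq(rng, SPACER_LEN) + _random_seq(rng, 1) + "GG"

    lengths = spec.chromosome_lengths()
    sequences = {name: _random_seq(rng, L) for name, L in lengths.items()}

    clusters: list[ClusterTruth] = []
    for cl in spec.clusters:
        L = cl.unit_length
        target_offset = min(max(62, L // 2), L - TARGET_LEN)
        amp_start = max(0, target_offset - 70)
        amp_end = min(L, amp_start + DEFAULT_AMPLICON_LEN)
        consensus = _random_seq(rng, L)
        if cl.carries_target:
            consensus = (
                consensus[:target_offset] + site + consensus[target_offset + TARGET_LEN :]
            )
        marker_span = None
        m_start = target_offset - MARKER_GAP - MARKER_LEN
        if cl.resistant_unit is not None and cl.resistant_marker and m_start >= amp_start:
            marker_span = (m_start - amp_start, m_start - amp_start + MARKER_LEN)

        protected = [(target_offset, target_offset + TARGET_LEN)]
        if marker_span is not None:
            protected.append((m_start, m_start + MARKER_LEN))

        truth = ClusterTruth(
            spec=cl,
            target_site=site,
            target_offset=target_offset,
            amp_start=amp_start,
            amp_end=amp_end,
            marker_span=marker_span,
            reference_amplicon=consensus[amp_start:amp_end],
        )
        for i in range(cl.unit_count):
            unit = _mutate_outside(consensus, cl.substitution_rate, protected, rng)
            resistant = i == cl.resistant_unit and cl.carries_target
            if resistant:
                # >=1 protospacer substitution + >=1 PAM substitution
                w = target_offset
                codes = list(unit)
                spos = w + 4
                codes[spos] = "ACGT"[("ACGT".index(codes[spos]) + 1) % 4]
                codes[w + SPACER_LEN + 1] = "A"  # central PAM G -> A
                unit = "".join(codes)
                if marker_span is not None:
                    unit = unit[:m_start] + unit[m_start + MARKER_LEN :]
            amp = unit[amp_start : amp_end - (MARKER_LEN if resistant and marker_span else 0)]
            truth.units.append(
                UnitTruth(index=i, unit_seq=unit, amplicon_seq=amp, resistant=resistant)
            )
        clusters.append(truth)

    coding_truth: list[dict] = []
    for locus in spec.coding_loci:
        cds = _random_seq(rng, locus.cds_length)
        # plant the target in frame, one codon in from the CDS start region
        t_off = 3 * ((locus.cds_length // 2 - TARGET_LEN) // 3)
        cds = cds[:t_off] + site + cds[t_off + TARGET_LEN :]
        coding_truth.append(
            {
                "chrom": locus.chrom,
                "start": locus.start,
                "cds": cds,
                "target_offset": t_off,
                "amplicon_length": locus.amplicon_length,
            }
        )

    # splice clusters and loci into chromosomes
    for truth in clusters:
        chrom = truth.spec.chrom
        seq = sequences[chrom]
        block = "".join(u.unit_seq for u in truth.units)
        start = truth.spec.start
        sequences[chrom] = seq[:start] + block + seq[start + len(block) :]
    for ct in coding_truth:
        seq = sequences[ct["chrom"]]
        start = ct["start"]
        sequences[ct["chrom"]] = seq[:start] + ct["cds"] + seq[start + len(ct["cds"]) :]

    # remove spurious target occurrences outside the planted ones
    genome = Genome(spec, sequences, clusters, coding_truth, site)
    planted: dict[str, list[int]] = {name: [] for name in sequences}
    for _, row in genome.units.iterrows():
        if not row["resistant"] and row["target_pos"] >= 0:
            planted[row["chrom"]].append(int(row["target_pos"]))
    for ct in coding_truth:
        planted[ct["chrom"]].append(ct["start"] + ct["target_offset"])
    for name in sequences:
        sequences[name] = _patch_spurious(sequences[name], site, planted[name], rng)

    return genome


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_FEMALE_COPIES = {"X": 2, "Y": 0, "MT": 1}
_MALE_COPIES = {"X": 1, "Y": 1, "MT": 1}


def _chrom_copies(genome: Genome, sex: str) -> dict[str, int]:
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    base = _MALE_COPIES if sex == "male" else _FEMALE_COPIES
    copies = dict(base)
    for name in genome.spec.autosome_names():
        copies[name] = 2
    return copies


def _sample_reads_from(
    seq_codes: np.ndarray,
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    L = seq_codes.size
    if n_reads <= 0 or L < read_length:
        return []
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    mat = seq_codes[starts[:, None] + np.arange(read_length)[None, :]].astype(np.int8)
    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
        mat = np.where(mask, (mat + shift) % 4, mat)
    flip = rng.random(n_reads) < 0.5
    mat[flip] = 3 - mat[flip, ::-1]
    byte = _BASES[mat]
    return [row.tobytes().decode() for row in byte]


def simulate_short_reads(genome: Genome, sex: str, spec: ReadSimSpec, seed=0):
    """Sexed short reads as FASTQ records (id, seq, qualities).

    Expected per-base coverage of each chromosome is ``depth`` x copy number
    for the given sex; read counts per chromosome are Poisson.
    """
    rng = _rng(seed)
    copies = _chrom_copies(genome, sex)
    if spec.depth == 0:
        warnings.warn("read depth is 0: producing an empty read set")
        return []
    records = []
    quals = [spec.quality] * spec.read_length
    for chrom, seq in genome.sequences.items():
        c = copies.get(chrom, 0)
        if c == 0 or len(seq) < spec.read_length:
            continue
        mean = spec.depth * c * len(seq) / spec.read_length
        n = int(rng.poisson(mean))
        codes = encode(seq)
        for i, s in enumerate(
            _sample_reads_from(codes, n, spec.read_length, spec.error_rate, rng)
        ):
            records.append((f"{sex}_{chrom}_{i}", s, quals))
    return records


def simulate_long_reads(genome: Genome, spec: ReadSimSpec, seed=0):
    """Long reads (FASTA records) plus a provenance truth table.

    Reads are drawn from chromosomes proportionally to chromosome length,
    with lengths uniform on the configured window (clipped to the chromosome).
    """
    rng = _rng(seed)
    names = list(genome.sequences)
    lengths = np.array([len(genome.sequences[n]) for n in names], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=spec.long_read_count, p=probs)
    records, rows = [], []
    for i, ci in enumerate(chrom_idx):
        chrom = names[ci]
        seq = genome.sequences[chrom]
        read_len = int(rng.integers(spec.long_read_min, spec.long_read_max + 1))
        read_len = min(read_len, len(seq))
        start = int(rng.integers(0, len(seq) - read_len + 1))
        codes = encode(seq[start : start + read_len]).astype(np.int8)
        if spec.long_read_error_rate > 0:
            mask = rng.random(codes.size) < spec.long_read_error_rate
            shift = rng.integers(1, 4, size=codes.size, dtype=np.int8)
            codes = np.where(mask, (codes + shift) % 4, codes)
        rid = f"long_{i}"
        records.append((rid, _BASES[codes].tobytes().decode()))
        rows.append({"read_id": rid, "chrom": chrom, "start": start, "length": read_len})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# editing and amplicons
# ---------------------------------------------------------------------------


@dataclass
class UnitOutcome:
    index: int
    state: str  # intact | disrupted | deleted | resistant
    amplicon: str | None


@dataclass
class Haplotype:
    individual: int
    units: list[UnitOutcome]

    def surviving_amplicons(self) -> list[str]:
        return [u.amplicon for u in self.units if u.state != "deleted"]

    def state_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for u in self.units:
            out[u.state] = out.get(u.state, 0) + 1
        return out


def _apply_indel(amplicon: str, cut: int, model: EditingModel, rng) -> str:
    size = int(rng.choice(model.indel_sizes, p=model.indel_size_probs))
    if rng.random() < model.insertion_prob:
        ins = _random_seq(rng, size)
        return amplicon[:cut] + ins + amplicon[cut:]
    a = max(0, cut - (size + 1) // 2)
    b = min(len(amplicon), a + size)
    return amplicon[:a] + amplicon[b:]


def simulate_editing(
    cluster: ClusterTruth, model: EditingModel, n_individuals: int, seed=0
):
    """Edit the cluster in ``n_individuals`` germlines.

    Returns the per-individual haplotypes and an event log (one row per
    cut/repair/deletion event) from which expected outcome fractions can be
    recomputed.
    """
    rng = _rng(seed)
    haplotypes: list[Haplotype] = []
    log_rows: list[dict] = []
    cut_pos = cluster.cut_position
    for ind in range(n_individuals):
        states = [
            "resistant" if u.resistant else "intact" for u in cluster.units
        ]
        amps: list[str | None] = [u.amplicon_seq for u in cluster.units]
        for cycle in range(model.cycles):
            cut = [
                s == "intact" and rng.random() < model.cleavage_prob for s in states
            ]
            cut_idx = [i for i, c in enumerate(cut) if c]
            for i in cut_idx:
                log_rows.append(
                    {"individual": ind, "cycle": cycle, "unit": i, "event": "cut"}
                )
            # unit-granular collapse between adjacent simultaneous cuts
            if model.intercut_deletion_prob > 0:
                for a, b in zip(cut_idx, cut_idx[1:]):
                    if b - a > 1 and rng.random() < model.intercut_deletion_prob:
                        for j in range(a + 1, b):
                            if states[j] != "deleted":
                                states[j] = "deleted"
                                amps[j] = None
                                log_rows.append(
                                    {
                                        "individual": ind,
                                        "cycle": cycle,
                                        "unit": j,
                                        "event": "deleted",
                                    }
                                )
            for i in cut_idx:
                if states[i] == "deleted":
                    continue
                if rng.random() < model.disrupting_repair_prob:
                    states[i] = "disrupted"
                    amps[i] = _apply_indel(amps[i], cut_pos, model, rng)
                    log_rows.append(
                        {
                            "individual": ind,
                            "cycle": cycle,
                            "unit": i,
                            "event": "disrupted",
                        }
                    )
                else:
                    log_rows.append(
                        {
                            "individual": ind,
                            "cycle": cycle,
                            "unit": i,
                            "event": "restored",
                        }
                    )
        haplotypes.append(
            Haplotype(
                individual=ind,
                units=[
                    UnitOutcome(index=i, state=s, amplicon=a)
                    for i, (s, a) in enumerate(zip(states, amps))
                ],
            )
        )
    log = pd.DataFrame(log_rows, columns=["individual", "cycle", "unit", "event"])
    return haplotypes, log


def simulate_amplicon_reads(
    haplotype: Haplotype,
    depth: int = 5_000,
    error_rate: float = 0.001,
    quality: int = 38,
    seed=0,
    sample_id: str = "sample",
):
    """Amplicon FASTQ reads from a haplotype's surviving repeat units.

    Read counts per unit are multinomial with equal probability per surviving
    unit copy (a limiting, proportion-preserving PCR); deleted units yield no
    reads. Base-call errors are uniform substitutions at ``error_rate`` with a
    constant Phred quality.
    """
    rng = _rng(seed)
    amps = haplotype.surviving_amplicons()
    if not amps:
        return []
    counts = rng.multinomial(depth, np.full(len(amps), 1.0 / len(amps)))
    records = []
    r = 0
    for amp, n in zip(amps, counts):
        codes = encode(amp).astype(np.int8)
        for _ in range(int(n)):
            c = codes
            if error_rate > 0:
                mask = rng.random(c.size) < error_rate
                if mask.any():
                    shift = rng.integers(1, 4, size=c.size, dtype=np.int8)
                    c = np.where(mask, (c + shift) % 4, c)
            records.append(
                (f"{sample_id}_r{r}", _BASES[c].tobytes().decode(), [quality] * c.size)
            )
            r += 1
    return records


def unedited_haplotype(cluster: ClusterTruth) -> Haplotype:
    """The pre-editing haplotype (all units in their built state)."""
    return Haplotype(
        individual=-1,
        units=[
            UnitOutcome(
                index=u.index,
                state="resistant" if u.resistant else "intact",
                amplicon=u.amplicon_seq,
            )
            for u in cluster.units
        ],
    )
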