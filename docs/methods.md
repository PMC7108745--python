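# Methods

## The discovery model

The discovery pipeline identifies abundant X-linked repeats suitable for
Cas9 X-shredding using nothing but raw reads: male and female short-read
sets, a male long-read set, and a mitochondrial reference. Its central
statistic is the chromosome quotient

CQ = (F / B_F) / (M / B_M),

where F and M are a k-mer's (or a long read's summed k-mer) occurrence
counts in the female and male short-read sets and B_F, B_M the library sizes
in read bases. In a hemizygous-male system, X-linked sequence is present in
two copies in females and one in males, so CQ → 2·(G_M/G_F) where G_M, G_F
are the male and female genome sizes; autosomal sequence gives G_M/G_F and
Y-linked sequence gives ≈0. When the sex genomes are close in size — the
regime the statistic was designed for — the landmarks are 2 / 1 / 0.

Assumptions: unbiased uniform sequencing of both sexes; no large shared
X/Y homologous blocks; k = 25 long enough that most k-mers are effectively
locus-specific. Counting is canonical (strand-merged, keyed by the
lexicographically smaller of k-mer and reverse complement) by default, with
a stranded mode exposed because either convention is defensible for
unstranded sequencing.

### Stage parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k | 25 | nt | long enough to contain a 20-nt spacer + NGG PAM |
| minimum combined count | 4 | occurrences | removes sequencing-error k-mers |
| long-read length window | [2000, 100000] | bp | short reads carry too few k-mers for a stable read CQ; both bounds inclusive (documented choice, configurable) |
| CQ windows | X [1.5, 2.5], autosomal [0.7, 1.4], Y ≤ 0.1 | — | declared defaults centred on the landmarks; no published values exist |
| CQ cap (male evidence 0) | 10.0 | — | keeps sorting total without fabricating infinities; capped reads bin ambiguous |
| X-hit fraction for candidate k-mers | 0.99 | — | a candidate's long-read evidence must be essentially all X-binned |
| off-target mismatch tolerance | 4 | nt | common Cas9 screening practice; PAM must remain NGG |
| Illumina coverage cutoff | count > 10² | occurrences | shortlist filter on combined male+female raw count, log10-scaled |
| long-read coverage cutoff | count > 10¹ | occurrences | as above, total occurrences in retained long reads |
| max k-mer hits per long read | > 7.5 (strict) | occurrences | proxy for tandem-array size |
| perfect assembly hits | ≥ 5 | occurrences | optional validation when an assembly exists |

The two coverage cutoffs are interpreted as **raw occurrence counts** on a
log10 scale. Interpreting them on per-million normalised counts would make
them unsatisfiable for any realistic repeat (a multi-hundred-copy 25-mer in
a >100 Mb genome normalises to order 1 per million read bases), whereas raw
counts put a ~100-copy repeat at log10 ≈ 3–4, comfortably above the cutoff,
and match the magnitudes of the companion cutoffs (7.5 hits per read, 5
assembly hits). Both cutoffs and the normalisation are configurable.

Off-target screening in the end-to-end runner defaults to the abundance
shortlist: placements that already fail the coverage/abundance cutoffs are
not Hamming-screened (they cannot pass regardless and carry
`offtarget_hits=None`); `offtarget_scope="all"` screens every placement.
The strict per-target operation (`apply_selection_filters`) refuses
incomplete records rather than failing silently.

Contig reassembly of candidate k-mers uses greedy longest-exact-overlap
merging (minimum overlap 10 nt, zero mismatches), with ties broken toward
the lexicographically smaller merged sequence for determinism. It operates
on the forward strand only; reverse-complement-aware assembly is out of
scope because the step is a qualitative check for higher-order repeat
structure, not a quantified result.

## The amplicon model

Editing outcomes are read off amplicon deep sequencing of the repeat
cluster. Reads with mean Phred quality < 30 (Phred+33) are dropped. Each
read is globally aligned to the reference amplicon (match +2, mismatch −3,
gap open −10, extend −1) and reduced to its **allele**: the aligned slice
over the 23-nt target window (protospacer + PAM), deletions as gaps,
insertions kept only when strictly inside the window. Indels are
left-aligned (VCF-style) so equivalent representations collapse to one
allele; the simulator places indels at the Cas9 cut (between protospacer
positions 17|18, 3 bp 5′ of the PAM), and left-alignment makes allele
identity independent of the aligner's arbitrary gap placement. Reads whose
flanks (outside the window) align below 80% identity are unalignable and
excluded from all denominators — the intact-target fraction is therefore
reported over alignable reads, and the unalignable count is kept alongside.

Derived statistics:

* **intact fraction** — reads whose window matches the reference exactly,
  over alignable reads;
* **allele censuses** — unique alleles at ≥1% frequency and at ≥10 reads,
  reported with and without the wild type;
* **classification** — an allele present above a noise floor (≥2 reads and
  ≥0.1% of sample reads) in *all* designated controls is pre-existing;
  absent from every control, de-novo; present in some controls only,
  ambiguous. At least one control is required; the noise floor separates
  sequencing error from real low-frequency alleles at ~0.1% base error;
* **resistance** — an allele is predicted cleavage-resistant if its PAM is
  no longer NGG, if it carries a substitution in the PAM-proximal 10-nt seed
  (configurable), or if it carries any indel in the window. PAM-distal
  substitutions alone do not confer resistance under this rule;
* **linked-marker dissociation** — per-read joint genotype of the target
  window and a linked marker (e.g. a 6-bp indel 53 bp upstream of the
  target). Resistant-window reads carrying the *reference* marker form are
  gene-conversion candidates; they are tested against a null rate
  (default: base error × marker length) with an exact binomial tail at
  α = 0.01;
* **coding effects** — net indel length mod 3 ≠ 0 is a frameshift, = 0 an
  in-frame indel; substitution-only alleles are translated codon-by-codon
  (standard code) and reported as amino-acid changes.

"Normalised reads" across samples is implemented as per-sample frequencies
(scaling every sample to equal effective depth); raw counts are always
retained. Median allele frequencies are taken over experimental samples
only, controls reported separately.

## Cross statistics

The replicate unit is the single-male cross; pools contribute one
observation and are never inflated to per-fly observations. Male fractions
carry exact 95% Clopper–Pearson intervals (small brood sizes make the
normal approximation poor). Genotypes are compared with Welch's
unequal-variance *t*-test on per-replicate fractions (the choice of
fractions over counts is a documented decision; Satterthwaite degrees of
freedom; two identical zero-variance groups are defined as t = 0, p = 1).
Developmental survival is reported stage-wise: embryo→pupa, pupa→adult, and
adult sex fractions, with structural invariants (hatched ≤ embryos,
adults ≤ pupae) enforced at construction.

## The synthetic-data generator

The generator emulates the statistical structure every stage consumes:

* **genome** — X and Y of 500 kb, one 300 kb autosome and a 16 kb
  mitochondrion by default, i.i.d. uniform background. X-linked clusters are
  tandem arrays (default 12 units × 271 bp) whose every unit carries exactly
  one copy of a consensus target site (accidental background occurrences are
  patched out); per-unit substitutions (default 1% per base outside the
  target window and marker) model natural repeat heterogeneity. One unit may
  be designated cleavage-resistant: ≥1 protospacer and ≥1 PAM substitution,
  optionally linked to a 6-bp deletion 53 bp upstream of the target. The Y
  default equals the X in size so the male and female genomes are equal in
  length, which pins the CQ landmarks at exactly 2/1/0 under library-size
  normalisation (insect Y chromosomes are routinely as large as the X);
  with unequal sex genomes the landmarks shift by G_M/G_F, which the toy
  scale would otherwise exaggerate far beyond anything a real genome shows.
* **short reads** — 100-bp reads, uniform positions and strands, coverage =
  depth × copy number per sex (females 2X:2A:1MT, males 1X:2A:1Y:1MT),
  Poisson read counts, uniform substitution errors (default 0.1%), constant
  Q38 — the simplest quality model that still exercises the mean-Q30 filter.
* **long reads** — count and length window configurable (default 200 reads,
  2–20 kb: the 2–100 kb analysis window truncated to toy chromosome sizes),
  drawn from chromosomes proportional to length, with a provenance truth
  table.
* **editing** — per germline, sequential cut–repair cycles: each intact unit
  is cleaved with probability p per cycle; a cleaved unit acquires a
  disrupting indel at the cut with probability d (indel sizes 1–6, 15%
  insertions) or is restored faithfully and can be re-cut. Without inter-cut
  deletions the expected intact fraction is (1 − p·d)^cycles, the closed
  form the tests check. Two simultaneous cuts may collapse the units
  strictly between them (whole-unit granularity keeps truth bookkeeping
  exact while capturing cluster collapse). A resistant unit is never
  cleaved. One cycle with strong cleavage models meiotic editing; several
  cycles model pre-meiotic editing.
* **amplicons** — one amplicon per surviving unit, read counts multinomial
  with equal weight per surviving copy (a limiting, proportion-preserving
  PCR), deleted units yield nothing; default 5,000 reads per male — the
  study design leaves per-male depth unstated, and 5,000 is a typical
  order for single-locus amplicon runs.

Not emulated (hence not validated by passing tests): PCR amplification bias
and chimeras, quality-score decay along reads, indel sequencing errors,
structural variation outside the clusters, diploid phasing of female
samples, and alignment of reads from loci unrelated to the amplicon.
Passing tests show the pipeline's statistics are correct when reads arise
from the assumed generative process; real amplicon data can violate these
assumptions (primer bias in collapsed clusters most of all).

## Numerical and testing choices

Counting uses a 2-bit packed k-mer codec (int64 codes, vectorised window
passes) so the default-scale census stays in seconds. Alignment results are
memoised per distinct read sequence — amplicon samples contain few distinct
sequences. Binomial envelopes in tests are exact (scipy), with Bonferroni
correction across cells and an allowance matching the envelope's nominal
failure rate; pooled-CQ checks use delta-method errors at read granularity,
since the k-mer counts within one read are fully correlated. Test and
validation runs use a 40 kb X / 30 kb autosome / 40 kb Y genome at 30×
depth with 150 long reads, and the editing-regime checks use 200 simulated
males at 300 reads per male: sizes chosen so the Monte-Carlo standard error
of each checked quantity is small relative to its assertion margin.

Known limitations: read-level CQ sums constituent k-mer counts, so a long
read spanning an X/autosome boundary (or a chimeric read) receives a blended
CQ; off-target counting is Hamming-based and blind to bulged (gapped)
off-target sites; contig assembly is forward-strand; coding-effect calls
for compound substitution+indel alleles report the indel consequence only.
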