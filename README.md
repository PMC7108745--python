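# xshred

Design and evaluation toolkit for CRISPR/Cas9 **X-chromosome sex distorters**
in species with hemizygous males (XY). A synthetic sex distorter expresses
Cas9 with a gRNA against X-linked repeats during spermatogenesis: cleaving
the X either removes X-bearing sperm from the gamete pool (*X-shredding*,
pre-zygotic male bias) or transmits damaged X chromosomes whose daughters die
during development (*X-poisoning*, post-zygotic). Building one requires two
computational workflows, both implemented here for researchers working from
raw sequencing data alone — no genome assembly needed:

1. **Target discovery** from sexed short reads and male long reads:
   - a 25-mer census of male and female Illumina-type reads, with
     mitochondrial filtering and a minimum combined abundance of 4;
   - the **chromosome quotient** CQ = (female count / female library size) /
     (male count / male library size), which converges to ≈2 for X-linked
     sequence, ≈1 for autosomal and ≈0 for Y-linked sequence, used to bin
     2–100 kb long reads into X / autosomal / Y / ambiguous classes;
   - candidate X-kmer calling (X-binned long-read hits + CQ), PAM scanning
     ([20-nt spacer][NGG] on both strands), off-target screening against the
     autosomal/Y long-read bins (Hamming ≤4 with an intact NGG), repeat
     abundance metrics, shortlist cutoffs (combined Illumina count > 10²,
     long-read occurrences > 10¹, max k-mer hits per long read > 7.5, ≥5
     perfect assembly hits, zero off-targets), and greedy exact-overlap
     contig reassembly of candidates into higher-order repeats.
2. **Editing-outcome quantification** from amplicon deep sequencing of the
   targeted repeat cluster: mean-quality ≥30 read filtering, affine-gap
   global alignment to the reference amplicon with left-aligned indel
   normalisation, per-allele tables, the intact-target fraction, unique-
   allele censuses (≥1% frequency / ≥10 reads), pre-existing vs de-novo
   classification against control samples, cleavage-resistance calls
   (mutated PAM, seed substitutions or indels), median allele frequencies
   across males, linked-marker dissociation (gene-conversion detection with
   an exact binomial test) and frameshift/missense calls for coding targets.

A third module computes the genetics statistics of distorter crosses: male
fractions with exact Clopper–Pearson intervals, Welch's unequal-variance
*t*-test between genotypes, and stage-wise developmental survival.

Because real sexed read sets are large, the package ships a first-class
**synthetic-data generator**: a seeded toy genome (X and Y of 500 kb,
300 kb autosome, 16 kb mitochondrion by default) carrying X-linked tandem
repeat clusters whose every unit holds one target site, sexed reads with
copy-number-faithful coverage, length-distributed long reads with truth
tables, a sequential cut–repair editing model (meiotic = one cycle,
pre-meiotic = many) with an optional never-cleaved resistant unit, and
proportion-preserving multinomial amplicon sequencing.

## Worked example

```python
from xshred import simulate as sim
from xshred.pipeline import run_discovery
from xshred.benchmark import editing_regime_reduction

spec = sim.GenomeSpec(
    x_length=40_000, autosome_lengths=(30_000,), y_length=40_000,
    mito_length=2_000,
    clusters=(sim.RepeatClusterSpec(chrom="X", start=5_000,
                                    unit_count=12, resistant_unit=11),),
    seed=7,
)
genome = sim.build_genome(spec)
reads = sim.ReadSimSpec(depth=30, long_read_count=150,
                        long_read_min=2_000, long_read_max=8_000)
male = sim.simulate_short_reads(genome, "male", reads, seed=11)
female = sim.simulate_short_reads(genome, "female", reads, seed=12)
long_reads, _ = sim.simulate_long_reads(genome, reads, seed=13)

result = run_discovery(male, female, long_reads, genome.sequences["MT"],
                       assembly=genome.to_fasta_records())
out = editing_regime_reduction(cycles=1, cleavage_prob=0.5,
                               disrupting_repair_prob=0.9, seed=1)
```

prints (via the obvious `print` calls on `result` and `out`):

```
census k-mers after filters: 107,529
long-read bins: {'Y': 54, 'autosomal': 49, 'X': 43, 'mitochondrial': 4}
candidate X-kmers: 23,875
targets passing all filters: 86
best target: AAAAAGGTGCACTTCTACCT PAM AGG (max hits/read 11, off-targets 0)
meiotic regime: 51.9% mean intact-site reduction (analytic expectation 45.0%)
```

Reading this: the census retained ~108k distinct 25-mers; every long read
was binned onto the correct chromosome class; ~24k k-mers are X-linked
candidates, of which 86 placements — all from the planted 12-unit repeat
cluster — clear every shortlist cutoff with zero off-target hits. Under one
cut–repair cycle at 50% cleavage and 90% disrupting repair, the amplicon
pipeline measures a ~52% loss of intact target sites against unedited
controls in this seeded draw (closed form: 1 − (1 − 0.5·0.9) = 45%).

The same stages are exposed on the command line (`xshred simulate`,
`census`, `select`, `alleles`, `crosses`); see `xshred --help`.

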