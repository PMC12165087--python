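# introkit

Bidirectional introgression inference from phased SNP panels, with a bundled
forward-time simulator that records admixture truth tracts.

The toolkit implements the full scan pipeline:

- **simdata** — forward Wright–Fisher simulator of five populations (two
  focal "domestic" populations, their wild background populations, and a
  distant outgroup) with dated admixture pulses whose donor-derived
  chromosome segments are tracked exactly; also simulates stratified SV
  genotype tables. Emits phased VCF, SV VCF, truth-tract BED and a
  population map.
- **genio** — the haplotype/genotype data model, VCF/BED/pop-map readers and
  writers, and the sliding-window engine (50 kb windows, 25 kb step by
  default).
- **ibdscan** — deterministic seed-and-extend haplotype identity matching
  (a GERMLINE-style substitute for HMM IBD callers) and the windowed
  rIBD statistic: `rIBD = nIBD(recipient, donor) − nIBD(recipient,
  background)` with `nIBD = cIBD / tIBD` over cross-group haplotype pairs.
- **fstats** — windowed Patterson's D and f_d from population allele
  frequencies (f_d zeroed where D < 0), weighted block-jackknife Z,
  f4-ratio admixture proportion, Weir–Cockerham (1984) F_ST, and maximum
  SV–SNP r² tagging within a 50 kb flank.
- **introcall** — top-quantile rIBD candidate windows, f_d confirmation,
  flow-direction inference from the two population arrangements, segment
  merging and extension, bidirectional intersection, genome fractions, and
  base-level recovery scoring against truth tracts.
- **svintro** — population-specific SV detection (single-locus WC84 F_ST,
  permutation empirical P with the add-one estimator, top-5% /
  P < 0.05 / missingness < 0.1 / MAF > 0.01 conjunction) and introgression
  classification by overlap with inferred segments.
- **hapnet** — haplotype classes over a region, per-population frequency
  tables, minimum-spanning haplotype networks with equal-weight alternative
  edges, and a two-haplogroup bipartition.
- **pipeline / cli** — the end-to-end driver shared by the command line,
  the test-suite and the acceptance report.

## Command line

Every subcommand takes explicit input/output paths and an explicit `--seed`
where randomness is involved; identical seeds reproduce outputs byte for
byte.

```sh
# simulate a 5 Mb panel with a 20% pulse from P_A into P_B 30 generations ago
introkit simulate --seed 1 --out-prefix sim --length 5000000 \
    --pulse 30:P_A:P_B:0.2 --n-svs 200 --stratified-fraction 0.04

# windowed rIBD scan
introkit ribd --vcf sim.snps.vcf --popmap sim.popmap.tsv \
    --recipient P_B --donor P_A --background W_B \
    --chrom-length 5000000 --out ribd.tsv

# windowed D / f_d for one arrangement
introkit dstats --vcf sim.snps.vcf --popmap sim.popmap.tsv \
    --p1 W_B --p2 P_B --p3 P_A --outgroup OUT \
    --chrom-length 5000000 --out dstats.tsv

# call segments in both directions and intersect them
introkit call --vcf sim.snps.vcf --popmap sim.popmap.tsv \
    --pop-a P_A --pop-b P_B --background-a W_A --background-b W_B \
    --outgroup OUT --chrom-length 5000000 --out-prefix calls

# population-specific / introgressed SVs
introkit svintro --sv-vcf sim.svs.vcf --popmap sim.popmap.tsv \
    --group-a P_A --group-b P_B --segments calls.segments.into_b.tsv \
    --seed 1 --out sv_calls.tsv

# haplotype classes and network for a locus
introkit hapnet --vcf sim.snps.vcf --popmap sim.popmap.tsv \
    --region chr1:1500000-1700000 --out-prefix locus

# everything at once, with a JSON summary
introkit pipeline --seed 1 --out-dir run1 --pulse 30:P_A:P_B:0.2
```

## Conventions

- VCF positions are 1-based; BED intervals, windows and segments are
  0-based half-open.
- All randomness flows from explicit seeds; there is no unseeded entropy.
- Missing data: `-1` in allele/dosage matrices, `NA` in tables.
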