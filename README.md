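# sbg — sequence-based genotyping for mapping populations

`sbg` is a self-contained Python implementation of a sequence-based
genotyping (SBG) workflow for plant mapping populations: restriction-enzyme
complexity reduction with inline-tagged adapters, multiplexed short-read
sequencing, de-novo reference construction by read clustering, co-dominant
SNP genotyping, parent-based A/B/H scoring, frequency-based SNP filtering,
and de-novo linkage-map construction. It is aimed at people who want to
study, teach or stress-test this class of genotyping-by-sequencing pipeline
— every stage is reimplemented natively (no aligner or external caller) and
a first-class simulator generates populations with full truth tables, so
each stage's behaviour can be verified against known genotypes.

## The workflow

1. **Simulation** (`sbg.simgen`): two founder genomes differing at known SNP
   positions; BC1 or selfed-RIL populations with Haldane (no-interference)
   meiosis — crossovers per chromosome ~ Poisson(L/100), positions uniform
   in cM; an in-silico digest keeping only rare–frequent cutter fragments
   (EcoRI/MseI, or PstI/TaqI with an MseI excluder) within a 200–1000 bp
   size window; multiplexed FASTQ reads `[5-nt tag][remnant][fragment]` with
   configurable depth and per-base error.
2. **Demultiplexing** (`sbg.demux`): tags designed at pairwise Hamming
   distance ≥ 2, exact matching (no single-error rescue), then fixed-order
   read QC: remnant check, N count, homopolymer run, mean Phred, optional
   blocklist k-mers. Every read lands in exactly one accounting category.
3. **Reference building** (`sbg.refbuild`): 100 %-identity clustering of
   full-length reads = exact deduplication with counts; unique reads seen
   fewer than `lower` times (default: the number of samples) or more than
   100,000 times are discarded; the survivors become contigs.
4. **Genotype calling** (`sbg.aligncall`): ungapped best-Hamming read
   assignment (ties discarded), allelic contigs merged per locus, and a
   flat-prior diploid likelihood model: for a read base *b* with error
   probability *e*, P(b|hom-X) = 1−e if b = X else e/3, and
   P(b|het) = ½P(b|allele 1) + ½P(b|allele 2). Phred-scaled PLs are
   normalised to min 0, GQ is the second-smallest PL (cap 99), and site
   quality SNPQ is the summed evidence against the all-major-homozygote
   configuration. Default validity thresholds: depth ≥ 7×, GQ ≥ 20,
   SNPQ ≥ 30.
5. **Parent-based scoring** (`sbg.parentgeno`): SNPs kept only where both
   parents are called homozygous for alternate alleles; offspring become
   A (parent-1 allele), B (parent-2 allele) or H (heterozygous). In a BC1
   with parent 2 recurrent, freq(A) is a direct genotyping-error proxy.
6. **SNP filtering** (`sbg.snpfilter`): drop SNPs with > 60 % missing
   genotypes or class frequencies outside the population's expected bands
   (BC1: B, H within 25–75 %, A ≤ 3 % — guaranteeing ≥ 97 % A-proxy
   accuracy; RIL: A, B within 25–75 %, H ≤ 15 %).
7. **Linkage mapping** (`sbg.linkmap`): pairwise recombination fractions
   (BC1: discordance among {B,H} pairs; RIL: homozygote discordance with
   the selfing correction r = R̂/(2(1−R̂))) and binomial LOD scores; weak
   estimates (r̂ > 0.4) re-estimated by shortest paths over Haldane
   distances; single-linkage grouping (rf ≤ 0.4, LOD ≥ 4), optional
   two-step anchored grouping under heavy missingness; 150 seeded
   multi-start greedy + 2-opt candidate orders per group, best order by
   minimal sum of adjacent recombination fractions (SARF, ties by maximal
   adjacent LOD); Haldane cM positions and per-marker order stability.

## Worked example

```python
from sbg.pipeline import RunConfig, run_all

cfg = RunConfig(out_dir="sbg_demo", seed=42, population="bc1",
                n_offspring=96, n_chrom=3, chrom_bp=400_000, chrom_cm=90.0,
                mean_depth=12.0, error_rate=0.001, n_orders=60)
res = run_all(cfg)
```

This simulates a 96-offspring BC1 on three 400-kb chromosomes (90 cM each),
sequences every rare–frequent fragment at ~12× with Q30 errors, and runs all
downstream stages. The run prints/reports:

```
reads simulated  : 276376
reads assigned   : 99.0%
reference contigs: 357
SNP sites called : 172
informative SNPs : 131
class freqs      : A=0.000 B=0.471 H=0.529
SNPs after filter: 131
linkage groups   : 3 [50, 44, 37]
group lengths cM : [82.0, 75.9, 104.7]
```

Reading the numbers: ~1 % of reads are rejected by QC (mostly reads whose
error hit the tag or remnant); the 357 contigs include separate contigs for
the two alleles of polymorphic fragments (they are merged again during
calling); 131 SNPs have both parents fixed for alternate alleles; the A
class is empty — in this BC1 design A is pedigree-impossible, so its
frequency estimates the genotyping error rate; B/H sit near the expected
1:1; and the three simulated chromosomes are recovered as three linkage
groups with cM lengths near the simulated 90 cM.

The same stages are available as a CLI (`sbg simulate | demux | refbuild |
call | parentgeno | filter | map | all`); each subcommand consumes the
previous stage's plain-text artifacts (FASTQ/FASTA/TSV/JSON), e.g.

```bash
sbg all --out-dir demo --seed 42 --population bc1 --n-offspring 48
sbg filter --abh demo/abh.tsv --preset bc1 --out demo/abh_filtered.tsv
sbg map --abh demo/abh_filtered.tsv --out demo/map.tsv
```

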