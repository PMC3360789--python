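# Methods

This note documents the models, parameter choices and numerical conventions
behind `sbg`, and what the bundled simulations can and cannot establish.

## Simulator

**Founder genomes.** `make_founders` draws i.i.d. background sequence at a
configurable GC fraction (default 0.5, i.e. uniform composition) and places
SNPs uniformly at `snp_density` per kb (default 10/kb on the default
5 × 1 Mb fixture — a deliberately marker-dense founder pair so that several
hundred SNPs land inside sequenced fragment windows). Each SNP's alternate
allele is *motif-neutral*: a substitution is accepted only if it neither
destroys nor creates an occurrence of the restriction-site motifs in use
(EcoRI, MseI, PstI, TaqI by default). Consequence: both founders produce
byte-identical digests, every fragment is present in every individual, and
polymorphism appears only as sequence variation within fragments — the
regime the downstream clustering/calling model assumes. Real data violate
this (restriction-site SNPs cause presence/absence markers); such dominant
markers are deliberately out of scope.

**Meiosis.** Haldane model throughout: per chromosome of genetic length
L cM, crossover counts are Poisson(L/100) with positions uniform in cM and
no interference, and the bp→cM map is linear. BC1 offspring are an F1
gamete over a recurrent-parent (founder-2) gamete, so hom-founder-1
genotypes are impossible by construction; selfed RILs iterate
`generations − 1` rounds of selfing from the F1, leaving residual
heterozygosity 0.5^(g−1) (0.78 % at F8). Using Haldane both here and in the
mapping functions makes map-length recovery unbiased in expectation.

**Digestion and library selection.** All cut sites of the rare, frequent
and (optional) excluder enzyme are found on the forward strand (all
supported sites are palindromic); fragments between adjacent cuts keep the
filled-in overhang at both ends, so the read off either end begins with the
enzyme's AFLP-style remnant (EcoRI `AATTC`, MseI `TAA`, PstI `TGCAG`, TaqI
`CGA`). Only rare–frequent fragments are retained — they alone carry both
adapter types and amplify — and fragments outside [200, 1000] bp are
removed, mirroring post-ligation size selection; an excluding enzyme (MseI
in the three-enzyme scheme) cuts too, so no surviving fragment contains its
site.

**Reads.** Read 1 is `[5-nt tag][remnant][fragment bases]` to the cycle
count (default 76 nt single-end; 100 nt paired mode reads the frequent end
without a tag). One size window is applied to the library as a whole, also
in paired mode. Per read, a fair coin picks the haplotype, so a
heterozygote's allele counts are Binomial(d, ½) — the property that makes
low-coverage allele dropout (rate 2·0.5^d) real in the simulator and
motivates the 7× depth threshold. Depth per fragment per individual is
Poisson(`mean_depth`) by default; negative-binomial is available to stress
thresholds, and `depth_dist="fixed"` gives exact coverage. Substitution
errors are i.i.d. per base at `error_rate`, and the quality string is the
constant Phred score matching that rate (capped Q41; no position-dependent
decay — the simplest model that exercises the caller; real instrument
profiles are not emulated). Truth tables (SNPs, per-individual genotypes,
fragments) are TSVs; per-read provenance is encoded in the read id
(`sample|c<chrom>:<start>-<end>|h<hap>|<serial>`).

**The noise-free configuration** used by the headline BC1 experiment is
zero error rate *and* exact (fixed) 20× coverage, isolating meiotic
randomness. With Poisson coverage a faithful caller would still emit a
handful of allele-dropout homozygote calls among ~7 × 10⁴ heterozygote
genotypes (expected rate E[2·0.5^d | d ≥ 7] ≈ 9 × 10⁻⁵), which would
contaminate the pedigree-impossible A class; at fixed 20× the expected
count is ~0.05 per run. Binomial haplotype sampling itself is retained, so
an exceptional A call remains possible in principle.

## Demultiplexing

Tags are designed greedily over the shuffled 4^5 code (seeded), keeping
candidates at pairwise Hamming ≥ 2; if the shuffled pass cannot reach the
requested count, a second greedy pass over the plain lexicographic order is
used, which for distance 2 recovers the full 256-word parity lexicode.
Distance-2 codes cannot correct single errors unambiguously, so matching is
exact and a read with any tag error is rejected, never rescued. The QC
chain runs in a fixed order (tag → remnant → Ns → homopolymer → mean
quality → blocklist) and the first failure labels the read, making the
report an exact partition of the input. Defaults — homopolymer run ≤ 10,
N count 0, mean Phred ≥ 20, blocklist k = 31 — are this implementation's
declared values (exposed in config and logged), not literature
reproductions. The tag is trimmed; the remnant is retained so reference
contigs keep their restriction-site context.

## Reference construction

Clustering trimmed full-length reads at 100 % identity is implemented as
exact deduplication with counts: each unique sequence is its own cluster
and representative, which is deterministic and makes the abundance window
(`lower` ≤ count ≤ `upper`) exact. `lower` defaults to the number of
samples (an approximation of the population size) and `upper` to 100,000
(repeat guard). "Full length" means trimmed length equal to the configured
cycle count minus the tag. Allelic variants of one locus intentionally form
separate contigs; the caller's merge pass reunites them.

## Genotype calling

Reads are assigned by ungapped Hamming distance against every contig
(fixed fragment starts and uniform lengths make gapped alignment
unnecessary at this scale); a read needs a unique best contig within
`max_mm` (default 3) mismatches — ties are discarded to avoid paralog
conflation. Contigs within `max_mm` of each other are merged into one locus
with the most abundant contig as reference, so an allele split across two
contigs cannot hide its SNP.

The diploid model uses a flat genotype prior, keeping GQ interpretable and
directly checkable against a brute-force per-read product. Phred qualities
are floored at an error probability of 10⁻⁴ so Q41 bases cannot produce
infinite log-likelihood ratios. Genotypes are argmax-likelihood over
(hom-major, het, hom-minor); the informative depth (major + minor reads) is
the depth compared against the 7× threshold; bases other than the two site
alleles are treated as noise, and sites with a third allele above 5 % of
the pileup are dropped. SNPQ is defined constructively as the sum over
samples of the PL of the all-major-homozygote genotype (capped 9999): it is
zero exactly when the data are consistent with an invariant site, and the
default threshold 30 plays the role of a site-quality cutoff. Calls are
aggregated by (sequence, quality-string) pairs — exact under the
simulator's constant quality profiles and lossless for the model, which
only needs per-base Phred values.

## Parent-based scoring and filtering

A is anchored to the parent listed first; this is a labelling convention,
not inferable from data. Class frequencies (and the filter's denominators)
are computed over non-missing *offspring* calls: the parents are carried in
the matrix (coded A and B throughout) but excluded from frequencies, which
would otherwise contain one guaranteed A and B per SNP and break the
freq(A)-as-error-rate interpretation. "More than" thresholds are strict
(exactly 60 % missing or exactly 3 % A is retained); the 25–75 % band
bounds are inclusive. Because every retained BC1 SNP satisfies
freq(A) ≤ 3 %, the per-SNP accuracy under the A-proxy is ≥ 97 % by
construction — the acceptance experiment verifies this with 5 % injected
random genotype errors. Germplasm mode (no parents) skips the informative
-site selection and exports raw biallelic genotypes unlabelled.

## Linkage mapping

BC1 recombination fractions are the discordance R/N over jointly
non-missing {B,H} pairs, capped at 0.4999; LOD is the binomial likelihood
ratio against r = 0.5 evaluated at the *uncapped* discordance clipped to
[0, 0.5], so LOD is exactly 0 at 50 % discordance. RIL estimates treat H as
missing (residual heterozygotes carry no phase information), and map the
observed homozygote discordance R̂ through r = R̂/(2(1−R̂)), the standard
correction for recombination accumulated over repeated selfing (treating F8
as fully inbred). Pairs with fewer than two informative individuals are
flagged uninformative (rf 0.5, LOD 0).

Weak estimates (r̂ > 0.4) are re-estimated by Dijkstra shortest paths over
the graph of confident pairs with Haldane-cM weights (d = −50 ln(1−2r)),
mapping path length back through the inverse Haldane function; unreachable
pairs stay at 0.5. Grouping is single linkage over edges with r̂ ≤ 0.4 and
LOD ≥ 4 (the LOD default is this package's choice, exposed in config). The
group-merge/split step is pragmatic: grouping is re-run at the configured
LOD ± 1 and the partition with the highest mean within-group LOD is kept
and logged. Two-step mode groups markers with ≤ 30 % missing data first and
anchors 30–60 %-missing markers to the group with the unambiguously best
(minimum) rf — assignment requires the margin to the second-best group to
be ≥ 0.10.

Ordering generates `n_orders` (default 150) candidates per group: greedy
nearest-neighbour chains from seeded random start markers, each refined by
vectorised 2-opt on a cycle closed through a zero-cost dummy depot (so
end-segment reversals are reachable). The best candidate minimises SARF
with ties broken by maximal adjacent LOD; orientation is normalised by
marker id. This multi-start heuristic stands in for the unpublished
algorithm portfolio of the original mapping software; the selection
criterion and the stability statistic are preserved. Stability is the
fraction of candidate orders (orientation-matched to the best) in which a
marker stays within one rank of its best-map position; exhaustive
enumeration confirms the heuristic reaches the SARF optimum for groups of
≤ 8 markers, and co-segregating markers are the expected source of low
stability. Positions accumulate Haldane distances along the best order.

## Orchestration and reproducibility

A single global seed fans out per stage as CRC32(`"<stage>|<seed>"`)
(kept below 2³¹), so stages are independently reproducible; identical
configurations give byte-identical FASTQ and ABH artifacts. Every threshold
actually applied is logged at INFO level and echoed in the run report,
whose per-stage counts chain (each stage's input equals the previous
stage's output). All artifacts are plain text (FASTQ, FASTA, VCF 4.2, TSV,
JSON).

## Problem sizes

The standard experiments use: the default fixture (5 × 1 Mb, 125 cM,
10 SNPs/kb) with 220 BC1 offspring at exact 20× for the end-to-end run
(~650 informative SNPs, ~4.7 M reads, ~1–2 min); 1000 truth-level SNPs ×
220 offspring for the filter experiment; n = 10,000 for the unlinked-marker
estimate; and 500 SNPs × 2,000 F8 RILs for the segregation check. The unit
suite runs on miniature fixtures (two 150–200 kb chromosomes, ≤ 100
offspring).

## Known limitations

No indels, PCR duplicates, adapter dimers, instrument error profiles, or
restriction-site polymorphism; no mismatch-tolerant clustering; no
multipoint (EM) recombination estimation or interference models (Kosambi);
no imputation. Passing simulations show the pipeline's threshold logic and
estimators behave as designed under their own generative model — they do
not certify performance on real libraries, where coverage is overdispersed,
error is context-dependent and loci can be absent for genomic reasons.
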