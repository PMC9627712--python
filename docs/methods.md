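# Methods

## Scope and data model

The package analyses diploid biallelic SNP genotypes from a small cohort
of individuals grouped into species/populations. Internally everything
is 0-based half-open; VCF (1-based) and GFF3 (1-based closed) are
converted at the I/O boundary. Genotypes are hard calls in
{HOM_REF, HET, HOM_ALT, MISSING}; missingness is a first-class state and
every denominator below counts non-missing calls explicitly.
Multiallelic records and indels are dropped at read time (the intended
input is an upstream biallelic-SNP call set), and genotype likelihoods
are not consumed — the HMM's error parameter absorbs call error instead.

## ROH inference

The detector is a two-state HMM per sample per contig. Observation at a
site is HET versus HOM (either homozygote); missing sites are skipped
but physical distance still accumulates across them.

Emissions:

* autozygous state: P(HET) = ε, default **0.005**. This is the rate at
  which genotyping error produces a heterozygous call inside a truly
  autozygous tract; 0.5 % suits typical short-read hard calls.
* non-autozygous state: P(HET) = 2p(1−p) under Hardy–Weinberg when an
  allele-frequency table is supplied (clipped to [1e−6, 1−1e−6]);
  otherwise the constant complement of `hom_emission_outside`, default
  **0.7**, appropriate for a cohort-segregating SNP panel where the
  expected heterozygosity at a variant site is ~0.25–0.35.

Transitions between adjacent sites d bp apart use the symmetric
two-state continuous-time chain, P(switch) = ½(1 − exp(−2rd)) with r the
`transition_rate` (default **0.1 state changes per Mb**). The naive
linear form r·d exceeds 1 for distant sites; the exponential form equals
r·d to first order and saturates at ½, so sites separated by much more
than 1/r carry no state information across the gap. The initial
distribution is the chain's stationary (½, ½). Decoding is exact Viterbi
(verified in tests against exhaustive path enumeration up to 15 sites).

Maximal autozygous runs are trimmed to their first/last supporting SNP
and reported if they contain at least `min_sites_per_tract` (default
**10**) sites; no length filter is applied at detection. Summaries apply
the length threshold: **F_ROH = Σ merged tract length ≥ 100 kb /
genome size**, and tract-length classes [0.1, 1), [1, 10), [10, ∞) Mb
(lower-closed bins, so an exactly-10 Mb tract counts as "≥ 10 Mb"; the
three class fractions partition F_ROH exactly). Overlapping segments of
one sample are merged before summing.

Resolution: with transition penalty 2·|log P(switch)| and per-site
emission advantage log((1−ε)/0.7) ≈ 0.35, the decoder cannot enter the
autozygous state for runs shorter than roughly 40–50 sites, and tract
boundaries extend to the nearest outside heterozygous site. Both effects
shrink with SNP density; at the densities used in the shipped cohorts
(400 SNPs/Mb) the detection floor is ≈ 0.12 Mb and the expected boundary
overshoot ≈ 10 kb per side.

## Tract dating

A tract of genetic length L cM descends unbroken from an ancestor g
generations back with recombination acting on 2g meioses, giving the
expectation **g = 100 / (2 L_cM)**. Physical length converts to genetic
length with a uniform rate, `recombination_rate(map_cM, genome_bp)` =
map_cM / (genome_bp/1e6); with a 5330 cM map on a 1.16 Gb genome this is
4.59 ≈ 4.6 cM/Mb, under which 1 Mb → 10.88 → 11 generations and 0.1 Mb →
108.8 → 109 generations. g is computed at full precision; rounding
(half-up) is display-only. Dating assumes a uniform recombination map —
no hotspot structure — and one year per generation if calendar ages are
wanted.

## Effect classification and polarization

A SNP in a CDS is located within its codon in transcription order
(strand-aware, phase-aware across exon junctions; one CDS chain per
gene, the longest transcript's). Reference and alternate codons are
translated with the standard nuclear code: same amino acid → SYN;
different, non-stop → NSYN; alternate codon is a stop while the
reference is not → LOF. LOF is deliberately **stop-gain only** —
stop-loss, splice and frameshift effects are excluded as more prone to
misannotation (stop-loss classifies as NSYN; stop-retained as SYN).
Sites in overlapping genes take the most severe class (LOF > NSYN >
SYN). Genes whose phase-adjusted CDS length is not a multiple of 3 are
flagged unusable and their sites report NONCODING. A SnpEff `ANN`
compatibility parser maps stop_gained/missense_variant/
synonymous_variant to the same three classes for pre-annotated VCFs.

Polarization uses the reference genome allele as the ancestral state
(the reference is an outgroup species), so HOM_REF ≡ homozygous
ancestral and HOM_ALT ≡ homozygous derived. This operational definition
mispolarizes sites where the outgroup itself carries the derived allele;
a per-site ancestral-allele override hook exists, and the simulator can
deliberately mispolarize a configurable fraction of sites to probe
sensitivity.

## Load statistics

Per sample and mutation class, load is the triple of proportions
(hom-ancestral, het, hom-derived) over that sample's **non-missing**
genotypes at class sites segregating across the full cohort. Proportions
per sample-class always sum to 1 (asserted); a class with zero
non-missing sites reports NaN, not zeros. Because each sample carries
its own denominator, the statistic is largely insensitive to coverage
and missingness differences (checked in tests by doubling the simulated
missing rate). Species summaries are mean ± 2 SE over member samples.
Species differences use one-way fixed-effects ANOVA (scipy) with Tukey
HSD (Tukey–Kramer for unequal n) on the same cells; groups of size 1
join the ANOVA but their pairwise contrasts are flagged low-power.

The LOF allele-frequency comparison retains variants with ≥ 4 genotyped
individuals in each of the three designated species ("present" meaning
derived frequency > 0 in ≥ 2 of 3), then compares per-variant species
frequencies by ANOVA. Both thresholds are parameters; the shipped
6-sample demo cohort uses min_genotyped = 2 since its groups have two
members.

LOF-in-ROH enrichment per individual is an exact binomial test:
successes k = genotyped LOF positions inside merged ROH ≥ 100 kb, trials
n = all genotyped LOF positions, null success probability = the
individual's F_ROH. The two-sided p-value uses the minimum-likelihood
rule (sum of all outcome probabilities ≤ the observed outcome's), which
is what `scipy.stats.binomtest` computes; a one-sided alternative is a
parameter. F_ROH ∈ {0, 1} makes the null degenerate and is reported NA
with a reason rather than a p-value.

## Private variation and population metrics

* **Fixed private LOF**: retain LOF sites where ≥ 1 focal sample is
  genotyped, every genotyped focal sample is homozygous-derived, and no
  genotyped background sample carries a derived allele. Missing focal
  calls are ignored rather than disqualifying the site.
* **Private deletions**: calls (BED with carrier lists, or SV-VCF where
  any non-reference genotype counts as carriage) present in **all**
  focal samples and absent from every background sample, annotated with
  distance to the nearest gene (0 if overlapping; ≤ 2 kb flagged
  proximal; a deletion exactly 2 kb away is flagged, 2001 bp is not).
  Calls longer than a configurable threshold (default 1 Mb) are flagged
  as probable artefacts — a deterministic stand-in for manual browser
  curation — but reported, never silently dropped.
* **F_st**: Weir & Cockerham (1984) per-site variance components
  (a, b, c) from genotype counts and observed heterozygosity, for two
  populations. Sites monomorphic overall or with < 2 genotyped
  individuals in either group are skipped (counted). The headline
  genome-wide value is the ratio of sums Σa/Σ(a+b+c) (the "weighted"
  convention); the mean of per-site ratios is reported alongside.
* **Effective population size**: per census season (spring/autumn),
  Ne = n / Σ(1/N_i) — the harmonic mean over years, which is dominated
  by bottleneck minima and hence ≤ the arithmetic mean. Counts must be
  ≥ 1. The shipped `data/census_synthetic.tsv` is a synthetic
  demonstration series; the published harmonic-mean Ne values for the
  real Devils Hole census (spring 122, autumn 209) cannot be recomputed
  here because the original count series is not redistributable with
  this package, and the corresponding acceptance test fails for exactly
  that reason rather than being skipped.

## Synthetic cohort generator

`simulate_cohort` builds, from one seed, a reference FASTA, gene models
(GFF3), a genotype VCF, deletion calls and exact truth tables. Identical
config + seed gives byte-identical files.

* **Autozygosity mosaics.** Tracts arrive uniformly over the genome with
  exponential lengths of mean 100/(2g) cM (g = `tract_age_g`) converted
  at `recomb_rate_cM_per_Mb` (default 4.6); overlapping tracts merge;
  laying stops when the covered fraction reaches `target_F`, the final
  tract being trimmed (by binary search on its end) so the realized
  fraction equals the target exactly at bp resolution. Inside a tract a
  single population allele is drawn at each site and duplicated,
  corrupted to HET with probability `het_error_inside_roh` (default
  0.001); outside, genotypes are Hardy–Weinberg draws at per-site
  alternate-allele frequencies from Beta(0.5, 0.5) (a U-shaped folded
  spectrum). Genotypes go missing independently at `missing_rate`
  (default 0.02).
* **Genes and planted variants.** Non-overlapping 1–2-exon genes on both
  strands receive stop-free random ORFs plus a terminal stop codon.
  Planted variants are found by searching codon positions for a
  substitution whose class (against the codon table) matches the
  request, so SYN/NSYN/LOF truth is guaranteed by construction; privacy
  patterns are `shared` (segregating, carried in ≥ 2 groups),
  `group_private` (derived alleles only in the focal group, not fixed
  there) and `fixed_in_group` (hom-derived in every focal sample, absent
  elsewhere). Planted genotypes respect each sample's tract state — an
  autozygous sample is never heterozygous at a planted site — but are
  exempt from the error/missingness corruption so the privacy patterns
  are exact truth. Background SNPs are placed outside CDS, making
  planted sites the only coding variation.
* **Deletions** are planted per pattern (`group_private`, `shared`,
  `partial_focal`) with placement cycling among gene-overlapping,
  near-gene (< 2 kb) and far positions.
* **Default density** is 400 SNPs/Mb — a ~13× thin-out of the ~5400
  SNPs/Mb of a real whole-genome call set, dense enough that the HMM's
  detection floor (~0.12 Mb) sits below essentially all simulated
  tracts. The standard cohorts use tract ages g = 4–8 (recent
  inbreeding, tracts ~1.4–2.7 Mb), which is the regime where F_ROH is an
  accurate estimator; cohorts dominated by very old, sub-0.1 Mb tracts
  would be under-called by any genotype-based HMM at these densities.

What the generator does **not** emulate: linkage disequilibrium beyond
the autozygosity mosaic itself, population differentiation at background
sites (all groups share one frequency spectrum, so simulated
between-group F_st is ~0 — the F_st estimator is validated on its exact
toy computation and its null), recombination-map heterogeneity,
selection, and read-level error structure. Passing truth-recovery tests
therefore demonstrates correctness of the inference machinery under the
model's assumptions, not robustness to every property of real data.

## Problem sizes and numerical choices

The shipped demo cohort is 8 Mb / 6 samples / ~3200 SNPs; the
truth-recovery benchmark is 20 Mb / 4 samples spanning target F of
0.1–0.8 at tract age g = 4. These sizes keep the full pipeline and test
suite in the minutes range while leaving every estimator's error well
inside its tolerance (|F̂_ROH − F| ≤ 0.02 per sample, base-level Jaccard
≥ 0.95 without het error). Viterbi works in log space; HWE
heterozygosity is clipped away from 0/1; proportion conservation is
asserted at 1e−12; rounding of tract ages is half-up and display-only.
Degenerate inputs (all-missing contigs, empty segment lists, zero-site
classes, F_ROH ∈ {0,1} nulls) return empty/NaN/NA results with logged
reasons instead of raising.

## Known limitations

* Hard genotypes only; no genotype-likelihood HMM.
* Stop-gain-only LOF undercounts true loss of function (splice,
  frameshift, stop-loss are out of scope by design).
* Reference-as-ancestral polarization misclassifies sites where the
  outgroup reference carries the derived allele.
* One CDS chain per gene: multi-isoform effects are resolved to the
  longest transcript.
* The deletion filter trusts its input calls; no breakpoint refinement
  or re-genotyping is attempted.
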