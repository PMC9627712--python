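#!/usr/bin/env python
"""Measure mutation load and its distribution across species.

Classifies coding SNPs (SYN/NSYN/stop-gain) against the emitted
reference+annotation, computes per-sample genotype-class load
proportions at segregating coding sites, compares species by ANOVA and
Tukey HSD, applies the well-genotyped LOF frequency filter, and runs the
per-individual binomial test of LOF enrichment inside ROH tracts.
"""

from pathlib import Path

import pupfishpop as pp
from pupfishpop import io as pio

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (COHORT / "roh_segments.bed").exists():
        raise SystemExit("run analysis/02_roh_inbreeding.py first")
    gm = pio.read_vcf(COHORT / "cohort.vcf")
    seqs = pio.read_fasta(COHORT / "reference.fa")
    genes = pio.read_gff3(COHORT / "genes.gff3")
    genome = pio.genome_from_sequences(seqs)
    table = pio.read_sample_table(COHORT / "sample_table.tsv")
    segments = pio.read_bed_segments(COHORT / "roh_segments.bed")

    effects = pp.classify_variants(gm.sites, genes, seqs)
    pio.write_tsv(effects, COHORT / "effects.tsv")
    coding = effects["effect"].value_counts().to_dict()
    print("site classification:", coding)

    profiles = pp.genotype_class_proportions(gm, effects)
    pio.write_tsv(profiles, RESULTS / "load_profiles.tsv")
    means = pp.group_mean_se(profiles, table)
    pio.write_tsv(means, RESULTS / "load_group_means.tsv")
    anova, tukey = pp.compare_load_groups(profiles, table)
    pio.write_tsv(anova, RESULTS / "load_anova.tsv")
    pio.write_tsv(tukey, RESULTS / "load_tukey.tsv")
    print("\nspecies mean homozygous-derived proportion per class:")
    der = means[means["category"] == "p_der"][["group", "cls", "mean", "se"]]
    print(der.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    species = tuple(table.group_labels())
    freq = pp.lof_frequency_filter(gm, effects, table, species, min_genotyped=2)
    pio.write_tsv(freq, RESULTS / "lof_frequencies.tsv")
    retained = freq[freq["retained"]]
    print(f"\nLOF frequency filter: {len(retained)}/{len(freq)} variants retained")
    if len(retained) >= 2:
        fa = pp.lof_frequency_anova(freq, species)
        print("LOF mean derived-allele frequency per species:",
              {k: round(v, 3) for k, v in fa.items() if k.startswith("mean")})

    results = []
    for sample in gm.samples:
        froh = pp.compute_froh([s for s in segments if s.sample == sample], genome)
        results.append(pp.roh_lof_enrichment(segments, gm, effects, froh, sample))
    enr = pp.enrichment_table(results)
    pio.write_tsv(enr, RESULTS / "lof_roh_enrichment.tsv")
    print("\nLOF-in-ROH binomial tests:")
    print(enr.to_string(index=False, float_format=lambda x: f"{x:.4f}"))


if __name__ == "__main__":
    main()
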