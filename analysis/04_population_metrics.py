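#!/usr/bin/env python
"""Population-level metrics: private variation, differentiation, Ne.

Filters LOF variants fixed homozygous-derived in the focal group and
absent elsewhere, filters deletions private to the focal samples with
gene-proximity annotation, estimates genome-wide Weir-Cockerham F_st
between the focal group and its closest relative, and computes
harmonic-mean effective population size from a seasonal census table
(the shipped census is a synthetic demo series, not the real counts).
"""

from pathlib import Path

import pandas as pd

import pupfishpop as pp
from pupfishpop import io as pio

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
FOCAL = "diabolis"


def main() -> None:
    if not (COHORT / "effects.tsv").exists():
        raise SystemExit("run analysis/03_mutation_load.py first")
    gm = pio.read_vcf(COHORT / "cohort.vcf")
    effects = pio.read_tsv(COHORT / "effects.tsv")
    table = pio.read_sample_table(COHORT / "sample_table.tsv")
    genes = pio.read_gff3(COHORT / "genes.gff3")
    deletions = pio.read_deletions_bed(COHORT / "deletions.bed")
    truth_vars = pio.read_tsv(COHORT / "truth_variants.tsv")

    focal = table.members(FOCAL)
    background = [s for s in gm.samples if s not in focal]

    uniq = pp.unique_fixed_lof(gm, effects, focal, background)
    pio.write_tsv(uniq, RESULTS / "unique_fixed_lof.tsv")
    planted = truth_vars.query("cls == 'LOF' and pattern == 'fixed_in_group'")
    print(f"unique fixed LOF variants: {len(uniq)} "
          f"(simulation planted {len(planted)}; "
          f"{'exact match' if len(uniq) == len(planted) else 'MISMATCH'})")

    dels = pp.unique_deletions(deletions, focal, background, genes)
    pio.write_tsv(dels, RESULTS / "unique_deletions.tsv")
    near = dels[dels["near_gene"]]
    print(f"private deletions: {len(dels)} total, {len(near)} within 2 kb of a gene")

    fst = pp.weir_cockerham_fst(gm, focal, table.members("nevadensis"))
    pio.write_tsv(pd.DataFrame([fst]), RESULTS / "fst.tsv")
    print(f"F_st({FOCAL} vs nevadensis): weighted={fst['fst_weighted']:.3f} "
          f"mean={fst['fst_mean']:.3f} over {fst['n_sites']} sites")

    census = pio.read_census_tsv(ROOT / "data" / "census_synthetic.tsv")
    ne = pp.harmonic_mean_ne(census)
    pio.write_tsv(ne, RESULTS / "effective_population_size.tsv")
    print("\nharmonic-mean Ne (synthetic demo census):")
    print(ne.to_string(index=False, float_format=lambda x: f"{x:.2f}"))


if __name__ == "__main__":
    main()
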