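"""Generator correctness: determinism, truth bookkeeping, planted-class
guarantees checked by an independent translation oracle on the emitted files."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import pupfishpop as pp
from pupfishpop import io as pio
from pupfishpop.model import HET, HOM_ALT, HOM_REF, MISSING, interval_total
from pupfishpop.simulate import (
    SampleSpec, SimulationConfig, cohort_digest, mean_tract_length_bp,
    sample_tract_lengths,
)


def small_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        contigs=(("c1", 3_000_000), ("c2", 2_000_000)),
        samples=(
            SampleSpec("A", "diabolis", 0.5, 4),
            SampleSpec("B", "diabolis", 0.3, 4),
            SampleSpec("C", "other", 0.1, 6),
            SampleSpec("D", "other", 0.0, 6),
        ),
        planted_variants={"SYN": {"shared": 2}, "LOF": {"fixed_in_group": 2}},
        planted_deletions={"group_private": 1, "shared": 1},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_same_seed_same_bytes(tmp_path):
    c1 = pp.simulate_cohort(small_config(seed=7))
    c2 = pp.simulate_cohort(small_config(seed=7))
    assert cohort_digest(c1) == cohort_digest(c2)
    p1 = c1.write(tmp_path / "a")
    p2 = c2.write(tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    assert cohort_digest(pp.simulate_cohort(small_config(seed=8))) != cohort_digest(c1)


def test_zero_target_f_means_no_tracts():
    co = pp.simulate_cohort(small_config())
    assert (co.truth.roh["sample"] == "D").sum() == 0
    assert co.truth.samples.set_index("sample").at["D", "realized_F"] == 0.0


def test_realized_f_matches_truth_intervals_exactly():
    cfg = SimulationConfig(
        seed=11, contigs=(("c1", 10_000_000),),
        samples=(SampleSpec("A", "g", 0.5, 4),),
        focal_group="g", planted_variants={}, planted_deletions={})
    co = pp.simulate_cohort(cfg)
    ivs = [(r.start, r.end) for r in co.truth.roh.itertuples()]
    realized = interval_total(ivs) / co.genome.total_size
    assert co.truth.samples.at[0, "realized_F"] == pytest.approx(realized, abs=0)
    assert 0.45 <= realized <= 0.55  # laid to hit the target exactly (bp rounding)
    assert realized == pytest.approx(0.5, abs=1e-6)


def test_truth_summary_bookkeeping(cohort):
    summ = pp.realized_truth_summary(cohort.truth, cohort.genome, cohort.gm)
    assert len(summ) == 6
    merged = summ.merge(cohort.truth.samples, on="sample")
    np.testing.assert_allclose(merged["true_F"], merged["realized_F"], atol=1e-12)
    # planted counts match config exactly
    counts = cohort.truth.variants.groupby("cls").size().to_dict()
    expected = {cls: sum(p.values()) for cls, p in cohort.config.planted_variants.items()}
    assert counts == expected


def test_single_tract_arithmetic():
    genome = pp.GenomeDescriptor((("c1", 10_000_000),))
    truth = pp.TruthTables(
        roh=pd.DataFrame([{"sample": "A", "contig": "c1", "start": 0, "end": 1_000_000}]),
        variants=pd.DataFrame(columns=["contig", "pos", "ref", "alt", "gene_id", "cls", "pattern"]),
        deletions=pd.DataFrame(),
        samples=pd.DataFrame([{"sample": "A", "group": "g", "target_F": 0.1,
                               "realized_F": 0.1, "n_tracts": 1}]))
    summ = pp.realized_truth_summary(truth, genome)
    assert summ.at[0, "true_F"] == pytest.approx(0.1)


def test_tract_length_distribution_mean():
    """Across 10 000 draws the mean tract length is within 5% of 100/(2g) cM."""
    rng = np.random.default_rng(123)
    for g in (4, 16, 50):
        draws = sample_tract_lengths(rng, g, 4.6, 10_000)
        assert np.mean(draws) == pytest.approx(mean_tract_length_bp(g, 4.6), rel=0.05)


def _oracle_effect_from_files(paths, contig, pos, ref, alt):
    """Independent translation oracle: rebuild every transcript from the
    emitted FASTA+GFF3, apply the substitution to the genome, translate
    before/after with Biopython, and classify from the amino-acid change."""
    seqs = pio.read_fasta(paths["fasta"])
    genes = pio.read_gff3(paths["gff3"])
    assert seqs[contig][pos] == ref
    mutated = dict(seqs)
    s = mutated[contig]
    mutated[contig] = s[:pos] + alt + s[pos + 1:]

    def translate_gene(gene, seqdict):
        parts = []
        for s0, e0, _ in sorted(gene.cds, key=lambda t: t[0]):
            parts.append(seqdict[gene.contig][s0:e0])
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    best = "NONCODING"
    rank = {"NONCODING": 0, "SYN": 1, "NSYN": 2, "LOF": 3}
    for gene in genes:
        lo, hi = gene.span
        if gene.contig != contig or not (lo <= pos < hi):
            continue
        if not any(s0 <= pos < e0 for s0, e0, _ in gene.cds):
            continue
        aa_ref = translate_gene(gene, seqs)
        aa_alt = translate_gene(gene, mutated)
        diffs = [i for i, (x, y) in enumerate(zip(aa_ref, aa_alt)) if x != y]
        if not diffs:
            eff = "SYN"
        elif aa_alt[diffs[0]] == "*" and aa_ref[diffs[0]] != "*":
            eff = "LOF"
        else:
            eff = "NSYN"
        if rank[eff] > rank[best]:
            best = eff
    return best


def test_planted_classes_verified_by_translation_oracle(cohort, cohort_files):
    """Every planted variant's class, recomputed from the emitted files by an
    independent codon-table oracle, matches the truth table with no mismatch."""
    mismatches = []
    for v in cohort.truth.variants.itertuples():
        got = _oracle_effect_from_files(cohort_files, v.contig, int(v.pos), v.ref, v.alt)
        if got != v.cls:
            mismatches.append((v.contig, v.pos, v.cls, got))
    assert mismatches == []


def test_planted_lof_is_premature_stop(cohort):
    """Mutated CDS of a planted stop-gain translates to a truncated protein."""
    lof = cohort.truth.variants[cohort.truth.variants["cls"] == "LOF"]
    assert len(lof) > 0
    genes = {g.gene_id: g for g in cohort.genes}
    from pupfishpop.effects import coding_index, transcript_sequence
    for v in lof.itertuples():
        gene = genes[v.gene_id]
        cds = transcript_sequence(gene, cohort.sequences)
        idx = coding_index(gene, int(v.pos))
        base = v.alt if gene.strand == "+" else str(Seq(v.alt).complement())
        mutated = cds[:idx] + base + cds[idx + 1:]
        aa = str(Seq(mutated).translate())
        assert "*" in aa[:-1], "no premature stop introduced"


def test_fixed_private_variants_homozygous_derived_in_all_focal(cohort):
    focal = [s.sample_id for s in cohort.config.samples
             if s.group == cohort.config.focal_group]
    fi = [cohort.gm.sample_index(s) for s in focal]
    key = cohort.gm.sites.set_index(["contig", "pos"]).index
    fixed = cohort.truth.variants[cohort.truth.variants["pattern"] == "fixed_in_group"]
    for v in fixed.itertuples():
        i = key.get_loc((v.contig, v.pos))
        assert np.all(cohort.gm.codes[i, fi] == HOM_ALT)
        others = np.delete(cohort.gm.codes[i], fi)
        assert np.all(others == HOM_REF)


def test_fully_autozygous_sites_are_never_het():
    cfg = SimulationConfig(
        seed=3, contigs=(("c1", 4_000_000),),
        samples=(SampleSpec("A", "g", 0.95, 4), SampleSpec("B", "g", 0.2, 4),
                 SampleSpec("C", "g", 0.2, 4)),
        focal_group="g", het_error_inside_roh=0.0, missing_rate=0.0,
        planted_variants={"SYN": {"shared": 4}, "LOF": {"shared": 4}},
        planted_deletions={})
    co = pp.simulate_cohort(cfg)
    tracts = co.truth.roh[co.truth.roh["sample"] == "A"]
    pos = co.gm.sites["pos"].to_numpy()
    inside = np.zeros(len(pos), dtype=bool)
    for t in tracts.itertuples():
        inside |= (pos >= t.start) & (pos < t.end)
    col = co.gm.column("A")
    assert not np.any(col[inside] == HET)


def test_config_validation_errors():
    with pytest.raises(pp.ConfigurationError):
        SampleSpec("A", "g", 1.0, 4)          # F must be < 1
    with pytest.raises(pp.ConfigurationError):
        SampleSpec("A", "g", 0.5, 0.5)        # age >= 1
    with pytest.raises(pp.ConfigurationError):
        small_config(samples=(SampleSpec("A", "g", 0.1, 4), SampleSpec("A", "g", 0.1, 4)))
    with pytest.raises(pp.ConfigurationError):
        small_config(planted_variants={"BAD": {"shared": 1}})
    with pytest.raises(pp.ConfigurationError):
        pp.simulate_cohort(small_config(samples=()))


def test_mispolarization_switch_flips_sites():
    base = small_config(seed=5, planted_variants={}, planted_deletions={})
    flipped = small_config(seed=5, planted_variants={}, planted_deletions={},
                           mispolarized_fraction=0.3)
    c0 = pp.simulate_cohort(base)
    c1 = pp.simulate_cohort(flipped)
    both = c0.gm.sites.merge(c1.gm.sites, on=["contig", "pos"], suffixes=("_0", "_1"))
    swapped = (both["ref_0"] == both["alt_1"]) & (both["alt_0"] == both["ref_1"])
    frac = swapped.mean()
    assert 0.2 < frac < 0.4
    # emitted reference sequence carries the new REF base at flipped sites
    for row in both[swapped].head(5).itertuples():
        assert c1.sequences[row.contig][row.pos] == row.ref_1
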