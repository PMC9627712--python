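"""Load proportions, group comparisons, LOF frequency filter, and the
exact binomial ROH-enrichment test (with brute-force oracles)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pupfishpop as pp
from pupfishpop.load import (
    compare_load_groups, exact_binomial_p, genotype_class_proportions,
    group_mean_se, lof_frequency_filter, roh_lof_enrichment,
)
from pupfishpop.model import HET, HOM_ALT, HOM_REF, LOF, MISSING, NSYN, SYN

from conftest import make_matrix


def effects_for(gm, effect=LOF):
    return pd.DataFrame({"contig": gm.sites["contig"], "pos": gm.sites["pos"],
                         "ref": gm.sites["ref"], "alt": gm.sites["alt"],
                         "effect": effect, "gene_id": "g"})


def test_proportion_arithmetic():
    codes = np.array([[HOM_REF, HET], [HOM_REF, HET], [HET, HET], [HOM_ALT, HET]])
    gm = make_matrix(codes, ["a", "b"])
    prof = genotype_class_proportions(gm, effects_for(gm), restrict_segregating=False)
    a = prof[(prof["sample"] == "a") & (prof["cls"] == LOF)].iloc[0]
    assert (a["p_anc"], a["p_het"], a["p_der"]) == (0.5, 0.25, 0.25)
    assert a["n_sites"] == 4


def test_zero_site_class_reported_absent_not_zero():
    codes = np.array([[MISSING, HOM_REF]])
    gm = make_matrix(codes, ["a", "b"])
    prof = genotype_class_proportions(gm, effects_for(gm, SYN), restrict_segregating=False)
    a = prof[(prof["sample"] == "a") & (prof["cls"] == SYN)].iloc[0]
    assert a["n_sites"] == 0 and np.isnan(a["p_anc"])


def test_proportions_match_naive_tally_oracle(cohort, effects_table):
    """Module output equals an independent per-site tally loop exactly."""
    prof = genotype_class_proportions(cohort.gm, effects_table)
    seg = cohort.gm.segregating_mask()
    eff = effects_table["effect"].to_numpy()
    for row in prof.itertuples():
        j = cohort.gm.sample_index(row.sample)
        counts = {HOM_REF: 0, HET: 0, HOM_ALT: 0}
        n = 0
        for i in range(len(cohort.gm)):
            if eff[i] != row.cls or not seg[i]:
                continue
            c = int(cohort.gm.codes[i, j])
            if c == MISSING:
                continue
            counts[c] += 1
            n += 1
        assert n == row.n_sites
        if n:
            assert row.p_anc == pytest.approx(counts[HOM_REF] / n, abs=0)
            assert row.p_het == pytest.approx(counts[HET] / n, abs=0)
            assert row.p_der == pytest.approx(counts[HOM_ALT] / n, abs=0)
        assert row.p_anc + row.p_het + row.p_der == pytest.approx(1.0, abs=1e-12) or n == 0


def test_missingness_robustness(effects_table):
    """Doubling the missing rate leaves expected proportions unchanged
    (within twice the Monte-Carlo standard error)."""
    lo = pp.simulate_cohort(pp.fixture_config())
    import dataclasses
    hi_cfg = dataclasses.replace(pp.fixture_config(), missing_rate=0.04)
    hi = pp.simulate_cohort(hi_cfg)
    for co in (lo, hi):
        assert co.gm.sites.equals(lo.gm.sites)  # same sites: same seed up to missingness
    eff = pp.classify_variants(lo.gm.sites, lo.genes, lo.sequences)
    p_lo = genotype_class_proportions(lo.gm, eff)
    p_hi = genotype_class_proportions(hi.gm, eff)
    m = p_lo.merge(p_hi, on=["sample", "cls"], suffixes=("_lo", "_hi"))
    for row in m.itertuples():
        for cat in ("p_anc", "p_het", "p_der"):
            a, b = getattr(row, f"{cat}_lo"), getattr(row, f"{cat}_hi")
            n1, n2 = row.n_sites_lo, row.n_sites_hi
            if n1 == 0 or n2 == 0:
                continue
            p = (a + b) / 2
            se = np.sqrt(max(p * (1 - p), 1e-6) * (1 / n1 + 1 / n2))
            assert abs(a - b) <= 2 * se + 1e-9


def test_anova_identical_groups():
    profiles = pd.DataFrame([
        {"sample": s, "cls": c, "p_anc": v, "p_het": 0.0, "p_der": 1 - v, "n_sites": 10}
        for c in (SYN,) for s, v in [("a1", .1), ("a2", .2), ("b1", .1), ("b2", .2)]
    ])
    table = pp.SampleTable({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    anova, _ = compare_load_groups(profiles, table)
    row = anova[(anova["cls"] == SYN) & (anova["category"] == "p_anc")].iloc[0]
    assert row["F"] == 0.0 and row["p"] == 1.0


def test_anova_matches_hand_calculation():
    """3 groups x 3 integer observations: F = (14/2)/(6/6) = 7 by hand."""
    vals = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [4, 5, 6]}
    rows, mapping = [], {}
    for g, xs in vals.items():
        for i, x in enumerate(xs):
            sid = f"{g}{i}"
            mapping[sid] = g
            rows.append({"sample": sid, "cls": SYN, "p_anc": x, "p_het": 0.0,
                         "p_der": 0.0, "n_sites": 1})
    anova, tukey = compare_load_groups(pd.DataFrame(rows), pp.SampleTable(mapping))
    row = anova[(anova["cls"] == SYN) & (anova["category"] == "p_anc")].iloc[0]
    assert row["F"] == pytest.approx(7.0)
    assert row["p"] == pytest.approx(stats.f.sf(7.0, 2, 6))
    assert len(tukey[(tukey["cls"] == SYN) & (tukey["category"] == "p_anc")]) == 3


def test_tukey_agrees_with_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    rng = np.random.default_rng(0)
    data = {g: rng.normal(loc, 1, size=6) for g, loc in [("A", 0), ("B", 0.5), ("C", 2)]}
    rows, mapping = [], {}
    for g, xs in data.items():
        for i, x in enumerate(xs):
            sid = f"{g}{i}"
            mapping[sid] = g
            rows.append({"sample": sid, "cls": SYN, "p_anc": x, "p_het": 0.0,
                         "p_der": 0.0, "n_sites": 1})
    _, tukey = compare_load_groups(pd.DataFrame(rows), pp.SampleTable(mapping))
    ours = tukey[(tukey["cls"] == SYN) & (tukey["category"] == "p_anc")]
    values = np.concatenate(list(data.values()))
    labels = np.repeat(list(data), 6)
    sm = pairwise_tukeyhsd(values, labels)
    sm_p = {(a, b): p for (a, b), p in zip(
        [(sm.groupsunique[i], sm.groupsunique[j]) for i, j in
         zip(*np.triu_indices(len(sm.groupsunique), 1))], sm.pvalues)}
    for row in ours.itertuples():
        assert row.p_adj == pytest.approx(sm_p[(row.group1, row.group2)], abs=1e-6)


def test_tukey_familywise_error_under_null():
    """Null calibration: family-wise error of the pairwise tests <= 0.07."""
    rng = np.random.default_rng(2024)
    n_rep, n, k = 1000, 5, 3
    fw = 0
    for _ in range(n_rep):
        arrays = [rng.normal(size=n) for _ in range(k)]
        res = stats.tukey_hsd(*arrays)
        if (res.pvalue[np.triu_indices(k, 1)] < 0.05).any():
            fw += 1
    assert fw / n_rep <= 0.07


def test_lof_frequency_filter_rules():
    # 12 samples: 4 per species; vary missingness to hit the boundary cases
    samples = [f"{sp}{i}" for sp in ("X", "Y", "Z") for i in range(4)]
    table = pp.SampleTable({s: s[0] for s in samples})
    v1 = [HOM_ALT, HET, HOM_REF, MISSING,     # X: 3 genotyped -> fails
          HET, HOM_REF, HOM_REF, HOM_REF,
          HOM_REF, HOM_REF, HOM_REF, HOM_REF]
    v2 = [HOM_REF] * 8 + [HET, HET, HOM_REF, HOM_REF]   # present in 1 species only
    v3 = [HET, HOM_REF, HOM_REF, HOM_REF,
          HOM_ALT, HET, HOM_REF, HOM_REF,
          HOM_REF] * 1 + [HOM_REF, HOM_REF, HOM_REF]    # present in 2, all genotyped
    gm = make_matrix(np.array([v1, v2, v3]), samples)
    out = lof_frequency_filter(gm, effects_for(gm), table, ("X", "Y", "Z"))
    assert out["retained"].tolist() == [False, False, True]
    row = out.iloc[2]
    assert row["freq_X"] == pytest.approx(1 / 8)
    assert row["freq_Y"] == pytest.approx(3 / 8)
    assert row["freq_Z"] == 0.0


def test_lof_frequency_filter_matches_recount_oracle(cohort, effects_table):
    """Retained set and frequencies equal an independent per-variant recount."""
    table = cohort.sample_table
    species = tuple(table.group_labels())
    out = lof_frequency_filter(cohort.gm, effects_table, table, species, min_genotyped=2)
    lof_idx = np.flatnonzero(effects_table["effect"].to_numpy() == LOF)
    assert len(out) == len(lof_idx)
    for row_i, i in enumerate(lof_idx):
        freqs, ns = {}, {}
        for sp in species:
            js = [cohort.gm.sample_index(s) for s in table.members(sp)]
            g = [int(cohort.gm.codes[i, j]) for j in js if cohort.gm.codes[i, j] != MISSING]
            ns[sp] = len(g)
            freqs[sp] = (sum(2 for x in g if x == HOM_ALT) + sum(1 for x in g if x == HET)) \
                / (2 * len(g)) if g else float("nan")
        expect = all(ns[sp] >= 2 for sp in species) and \
            sum(1 for sp in species if freqs[sp] > 0) >= 2
        got = out.iloc[row_i]
        assert bool(got["retained"]) == expect
        if expect:
            for sp in species:
                assert got[f"freq_{sp}"] == pytest.approx(freqs[sp], abs=0)


def test_binomial_closed_forms():
    assert exact_binomial_p(10, 10, 0.5) == pytest.approx(2 * 0.5 ** 10)
    assert exact_binomial_p(5, 10, 0.5) == pytest.approx(1.0)


def test_binomial_matches_pmf_sum_oracle():
    """Two-sided minlike p equals the brute-force pmf summation."""
    for p0 in (0.3, 0.5, 0.62):
        for n in range(1, 31):
            pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
            for k in range(n + 1):
                expected = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
                assert exact_binomial_p(k, n, p0) == pytest.approx(min(1.0, expected),
                                                                   rel=1e-9)


def test_enrichment_counting_and_direction():
    segs = [pp.ROHSegment("a", "c1", 0, 500_000),
            pp.ROHSegment("a", "c1", 600_000, 650_000)]  # second below min length
    codes = np.array([[HOM_ALT]] * 6)
    gm = make_matrix(codes, ["a"], start=100_000, spacing=100_000)
    # positions 100k..600k: 4 inside [0,500k), 1 at 500k outside, 600k in short seg
    res = roh_lof_enrichment(segs, gm, effects_for(gm), froh=0.3, sample="a")
    assert (res.k, res.n) == (4, 6)
    assert res.direction == "enriched"
    assert res.p_value == pytest.approx(exact_binomial_p(4, 6, 0.3))


def test_enrichment_degenerate_froh_is_na():
    gm = make_matrix(np.array([[HOM_ALT]]), ["a"])
    res = roh_lof_enrichment([], gm, effects_for(gm), froh=0.0, sample="a")
    assert res.p_value is None and res.direction == "NA"


def test_enrichment_type_one_error_calibrated():
    """Simulated null: rejection rate at alpha=0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(77)
    n, p0, reps = 200, 0.3, 2000
    pvals = np.array([exact_binomial_p(k, n, p0) for k in range(n + 1)])
    ks = rng.binomial(n, p0, size=reps)
    rate = float(np.mean(pvals[ks] <= 0.05))
    assert 0.03 <= rate <= 0.07


def test_enrichment_power_at_doubled_rate():
    """LOF sites inside ROH at twice the F_ROH rate: power >= 0.8 (n=200)."""
    rng = np.random.default_rng(88)
    n, froh, reps = 200, 0.25, 500
    pvals = np.array([exact_binomial_p(k, n, froh) for k in range(n + 1)])
    ks = rng.binomial(n, 2 * froh, size=reps)
    power = float(np.mean(pvals[ks] <= 0.05))
    assert power >= 0.8


def test_group_mean_se_matches_manual(cohort, effects_table):
    prof = genotype_class_proportions(cohort.gm, effects_table)
    table = cohort.sample_table
    out = group_mean_se(prof, table)
    row = out[(out["group"] == "diabolis") & (out["cls"] == LOF)
              & (out["category"] == "p_der")].iloc[0]
    vals = prof[(prof["cls"] == LOF) & (prof["sample"].isin(table.members("diabolis")))]
    vals = vals["p_der"].to_numpy()
    assert row["mean"] == pytest.approx(vals.mean())
    assert row["hi"] - row["lo"] == pytest.approx(4 * vals.std(ddof=1) / np.sqrt(len(vals)))
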