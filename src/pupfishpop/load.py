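"""Mutation-load statistics.

Direct counts of derived alleles are confounded by coverage and
missingness, so load is measured as per-sample *proportions* of
homozygous-ancestral, heterozygous and homozygous-derived genotypes at
segregating coding sites, separately for SYN, NSYN and LOF classes.
Each sample's denominator is its own non-missing call count at the
class's site set, which largely cancels missing-data effects.

Cross-species comparison uses one-way ANOVA plus Tukey's HSD
(Tukey–Kramer for unequal group sizes).  LOF allele-frequency
comparisons are restricted to variants genotyped in at least
``min_genotyped`` individuals of every focal species and present in at
least ``min_species_present`` of them, to control for unequal sampling.

Per-individual enrichment of LOF variants inside runs of homozygosity is
an exact two-sided binomial test: successes = LOF positions inside ROH,
trials = LOF positions genotyped, success probability = the sample's
F_ROH (the null that LOF positions fall into ROH at the genome-average
rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    LOF,
    MISSING,
    MUTATION_CLASSES,
    ConfigurationError,
    GenotypeMatrix,
    PupfishPopError,
    ROHSegment,
    SampleTable,
    merge_intervals,
)

log = logging.getLogger(__name__)

CATEGORIES = ("p_anc", "p_het", "p_der")


def genotype_class_proportions(gm: GenotypeMatrix, effects: pd.DataFrame,
                               restrict_segregating: bool = True) -> pd.DataFrame:
    """Per-sample genotype-class proportions per mutation class (long format).

    ``effects`` must align with ``gm.sites`` (columns ``effect``).  The
    site set defaults to sites segregating across all samples.  A
    (sample, class) cell with zero non-missing calls is reported with NaN
    proportions and ``n_sites`` 0, not as zeros.
    """
    if len(effects) != len(gm):
        raise ConfigurationError("effects table does not align with genotype matrix")
    seg = gm.segregating_mask() if restrict_segregating else np.ones(len(gm), bool)
    rows = []
    eff = effects["effect"].to_numpy()
    for cls in MUTATION_CLASSES:
        mask = (eff == cls) & seg
        sub = gm.codes[mask]
        for j, sample in enumerate(gm.samples):
            col = sub[:, j]
            n = int(np.sum(col != MISSING))
            if n == 0:
                p = (np.nan, np.nan, np.nan)
            else:
                p = (np.sum(col == HOM_REF) / n, np.sum(col == HET) / n,
                     np.sum(col == HOM_ALT) / n)
            rows.append({"sample": sample, "cls": cls, "p_anc": p[0], "p_het": p[1],
                         "p_der": p[2], "n_sites": n})
    out = pd.DataFrame(rows)
    good = out["n_sites"] > 0
    total = out.loc[good, ["p_anc", "p_het", "p_der"]].sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-12):
        raise PupfishPopError("genotype-class proportions do not sum to 1")
    return out


def group_mean_se(profiles: pd.DataFrame, table: SampleTable) -> pd.DataFrame:
    """Species-level mean and ±2 SE of each proportion (error-bar table)."""
    df = profiles.copy()
    df["group"] = df["sample"].map(table.groups)
    rows = []
    for (group, cls), sub in df.groupby(["group", "cls"], sort=False):
        for cat in CATEGORIES:
            vals = sub[cat].dropna().to_numpy()
            if len(vals) == 0:
                continue
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append({"group": group, "cls": cls, "category": cat, "mean": mean,
                         "se": se, "lo": mean - 2 * se, "hi": mean + 2 * se,
                         "n_samples": len(vals)})
    return pd.DataFrame(rows)


def compare_load_groups(profiles: pd.DataFrame, table: SampleTable,
                        alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA + Tukey HSD per (mutation class, genotype category).

    Returns ``(anova, tukey)`` tables.  Groups of size 1 participate in
    the ANOVA; their pairwise contrasts are flagged ``low_power`` rather
    than suppressed.
    """
    df = profiles.copy()
    df["group"] = df["sample"].map(table.groups)
    groups = [g for g in table.group_labels() if (df["group"] == g).any()]
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups for ANOVA")
    anova_rows, tukey_rows = [], []
    for cls in MUTATION_CLASSES:
        for cat in CATEGORIES:
            arrays = []
            labels = []
            for g in groups:
                vals = df.loc[(df["cls"] == cls) & (df["group"] == g), cat].dropna().to_numpy()
                if len(vals):
                    arrays.append(vals)
                    labels.append(g)
            if len(arrays) < 2:
                continue
            if all(len(a) == 1 for a in arrays):
                continue  # no within-group variance anywhere: F undefined
            grand = np.concatenate(arrays)
            if np.allclose(grand, grand[0]):
                f_stat, p_val = 0.0, 1.0
            else:
                f_stat, p_val = stats.f_oneway(*arrays)
            anova_rows.append({"cls": cls, "category": cat, "F": float(f_stat),
                               "p": float(p_val), "n_groups": len(arrays),
                               "n_samples": int(sum(len(a) for a in arrays))})
            if all(len(a) >= 1 for a in arrays) and sum(len(a) for a in arrays) > len(arrays):
                res = stats.tukey_hsd(*arrays)
                for i, j in combinations(range(len(arrays)), 2):
                    tukey_rows.append({
                        "cls": cls, "category": cat,
                        "group1": labels[i], "group2": labels[j],
                        "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                        "p_adj": float(res.pvalue[i, j]),
                        "low_power": len(arrays[i]) < 2 or len(arrays[j]) < 2,
                    })
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)


def lof_frequency_filter(gm: GenotypeMatrix, effects: pd.DataFrame, table: SampleTable,
                         focal_species: tuple[str, str, str] | None = None,
                         min_genotyped: int = 4,
                         min_species_present: int = 2) -> pd.DataFrame:
    """Derived-allele frequencies of well-genotyped LOF variants per species.

    A variant is retained when every focal species has at least
    ``min_genotyped`` non-missing individuals AND its derived allele is
    present (frequency > 0) in at least ``min_species_present`` species.
    """
    if focal_species is None:
        labels = table.group_labels()
        if len(labels) != 3:
            raise ConfigurationError(
                "exactly three focal species must be designated (got "
                f"{len(labels)} groups); pass focal_species explicitly")
        focal_species = tuple(labels)  # type: ignore[assignment]
    if len(focal_species) != 3:
        raise ConfigurationError("exactly three focal species required")
    lof_mask = (effects["effect"].to_numpy() == LOF)
    idx = np.flatnonzero(lof_mask)
    cols = {sp: [gm.sample_index(s) for s in table.members(sp)] for sp in focal_species}
    rows = []
    for i in idx:
        site = gm.codes[i]
        freqs, ns = {}, {}
        for sp, jidx in cols.items():
            g = site[jidx]
            nm = g[g != MISSING]
            ns[sp] = len(nm)
            freqs[sp] = (np.sum(nm == HOM_ALT) * 2 + np.sum(nm == HET)) / (2 * len(nm)) \
                if len(nm) else np.nan
        enough = all(ns[sp] >= min_genotyped for sp in focal_species)
        present = sum(1 for sp in focal_species if freqs[sp] and freqs[sp] > 0)
        row = {"contig": gm.sites.at[i, "contig"], "pos": int(gm.sites.at[i, "pos"]),
               "retained": bool(enough and present >= min_species_present),
               "n_species_present": present}
        for sp in focal_species:
            row[f"freq_{sp}"] = freqs[sp]
            row[f"n_{sp}"] = ns[sp]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        dropped = out.loc[~out["retained"], [c for c in out.columns if c.startswith("freq_")]]
        out.loc[~out["retained"], dropped.columns] = np.nan
    return out


def lof_frequency_anova(freq_table: pd.DataFrame,
                        focal_species: tuple[str, ...]) -> dict[str, float]:
    """ANOVA on per-variant species allele frequencies of the retained set."""
    retained = freq_table[freq_table["retained"]]
    arrays = [retained[f"freq_{sp}"].dropna().to_numpy() for sp in focal_species]
    if any(len(a) < 2 for a in arrays):
        raise ConfigurationError("too few retained variants for frequency ANOVA")
    f_stat, p = stats.f_oneway(*arrays)
    means = {f"mean_freq_{sp}": float(np.mean(a)) for sp, a in zip(focal_species, arrays)}
    return {"F": float(f_stat), "p": float(p), "n_variants": int(len(arrays[0])), **means}


@dataclass(frozen=True)
class EnrichmentResult:
    sample: str
    k: int
    n: int
    p0: float
    p_value: float | None
    direction: str
    reason: str = ""


def exact_binomial_p(k: int, n: int, p0: float, alternative: str = "two-sided") -> float:
    """Exact binomial p-value; two-sided by the minimum-likelihood rule
    (sum of all outcome probabilities no larger than the observed one)."""
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)


def roh_lof_enrichment(segments: list[ROHSegment], gm: GenotypeMatrix,
                       effects: pd.DataFrame, froh: float, sample: str,
                       min_length: int = 100_000,
                       alternative: str = "two-sided") -> EnrichmentResult:
    """Binomial test of LOF positions inside a sample's ROH tracts.

    Successes are LOF variant positions (non-missing in the sample)
    falling inside tracts at least ``min_length`` long; the null success
    probability is the sample's F_ROH.
    """
    j = gm.sample_index(sample)
    lof = (effects["effect"].to_numpy() == LOF) & (gm.codes[:, j] != MISSING)
    idx = np.flatnonzero(lof)
    n = len(idx)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if s.sample == sample and s.length >= min_length:
            by_contig.setdefault(s.contig, []).append((s.start, s.end))
    k = 0
    contigs = gm.sites["contig"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    for i in idx:
        ivs = by_contig.get(contigs[i])
        if ivs and any(s <= pos[i] < e for s, e in merge_intervals(ivs)):
            k += 1
    if n == 0:
        return EnrichmentResult(sample, 0, 0, froh, None, "NA", "no genotyped LOF positions")
    if not 0.0 < froh < 1.0:
        return EnrichmentResult(sample, k, n, froh, None, "NA",
                                f"F_ROH={froh}: binomial null degenerate")
    p = exact_binomial_p(k, n, froh, alternative)
    direction = "enriched" if k / n > froh else "depleted"
    return EnrichmentResult(sample, k, n, froh, p, direction)


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": r.sample, "k": r.k, "n": r.n, "F_ROH": r.p0,
        "p_value": r.p_value, "direction": r.direction, "reason": r.reason,
    } for r in results])
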